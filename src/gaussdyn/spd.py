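"""Symmetric positive-definite (SPD) matrix machinery.

Covariance matrices live on the SPD cone, which is a Riemannian manifold
rather than a vector space. This module collects the primitives the rest of
the package builds on:

* an unconstrained 6-vector -> 3x3 Cholesky factor map (softplus diagonal),
  so that a network can emit valid covariances at any weight setting;
* the principal matrix logarithm / exponential via symmetric
  eigendecomposition;
* the log-Euclidean (log-Frobenius) discrepancy used as the training loss;
* the Bures-Wasserstein (Gaussian 2-Wasserstein) distance, used as an
  evaluation metric only;
* Higham-style nearest-correlation repair for numerically indefinite
  correlation matrices.

All functions accept plain numpy arrays and support leading batch axes where
noted.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "softplus",
    "cholesky_from_raw",
    "compose_spd",
    "symmetrize",
    "add_jitter",
    "is_spd",
    "matrix_log",
    "matrix_exp",
    "matrix_sqrt",
    "log_frobenius_sq",
    "log_frobenius",
    "bures_w2",
    "nearest_correlation",
]

#: eigenvalue floor below which matrix_log refuses to operate
EIG_FLOOR = 1e-12

#: default diagonal jitter added before Cholesky / eigen steps on empirical
#: covariances
DEFAULT_JITTER = 1e-8


def softplus(x):
    """Numerically stable softplus ln(1 + e^x).

    Uses the identity softplus(x) = max(x, 0) + log1p(exp(-|x|)) so that
    large positive arguments do not overflow and large negative arguments do
    not underflow to -inf.
    """
    x = np.asarray(x, dtype=float)
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


# scatter masks for assembling a 3x3 lower-triangular factor from a raw
# 6-vector; diagonal slots get a softplus, off-diagonal slots stay raw
_TRIL_IDX = [(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]
_DIAG_SLOTS = (0, 2, 5)


def cholesky_from_raw(a: np.ndarray) -> np.ndarray:
    """Map unconstrained parameters to a valid 3x3 Cholesky factor.

    Parameters
    ----------
    a : array, shape (..., 6)
        Raw real parameters in row-major lower-triangle order
        ``(L00, L10, L11, L20, L21, L22)``. Diagonal slots pass through a
        softplus so the factor's diagonal is strictly positive; off-diagonal
        slots are used as-is.

    Returns
    -------
    L : array, shape (..., 3, 3)
        Lower-triangular with positive diagonal; ``L @ L.T`` is SPD for any
        finite input.
    """
    a = np.asarray(a, dtype=float)
    if a.shape[-1] != 6:
        raise ValueError(f"expected trailing dimension 6, got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite raw Cholesky parameters")
    L = np.zeros(a.shape[:-1] + (3, 3), dtype=float)
    for slot, (i, j) in enumerate(_TRIL_IDX):
        v = a[..., slot]
        L[..., i, j] = softplus(v) if slot in _DIAG_SLOTS else v
    return L


def compose_spd(L: np.ndarray) -> np.ndarray:
    """Return ``L @ L.T`` (batched) — SPD whenever L has positive diagonal."""
    L = np.asarray(L, dtype=float)
    return L @ np.swapaxes(L, -1, -2)


def symmetrize(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + np.swapaxes(np.asarray(M, dtype=float), -1, -2))


def add_jitter(M: np.ndarray, jitter: float = DEFAULT_JITTER) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    return M + jitter * np.eye(M.shape[-1])


def is_spd(M: np.ndarray, tol: float = 1e-8) -> bool:
    """True if M is symmetric (to ``tol``) with all eigenvalues > 0."""
    M = np.asarray(M, dtype=float)
    if M.shape[-1] != M.shape[-2]:
        return False
    if not np.allclose(M, np.swapaxes(M, -1, -2), atol=tol):
        return False
    w = np.linalg.eigvalsh(symmetrize(M))
    return bool(np.all(w > 0))


def _eigh_sym(M: np.ndarray):
    return np.linalg.eigh(symmetrize(M))


def matrix_log(M: np.ndarray) -> np.ndarray:
    """Principal logarithm of an SPD matrix via eigendecomposition.

    Inputs are symmetrized first. Raises if any eigenvalue falls below the
    floor (1e-12); in that case the caller should add jitter.
    """
    w, Q = _eigh_sym(M)
    if np.any(w < EIG_FLOOR):
        raise ValueError(
            f"matrix_log: eigenvalue {w.min():.3e} below floor {EIG_FLOOR:.0e}; "
            "add diagonal jitter before taking the logarithm"
        )
    return (Q * np.log(w)[..., None, :]) @ np.swapaxes(Q, -1, -2)


def matrix_exp(S: np.ndarray) -> np.ndarray:
    """Exponential of a symmetric matrix (inverse of :func:`matrix_log`)."""
    w, Q = _eigh_sym(S)
    return (Q * np.exp(w)[..., None, :]) @ np.swapaxes(Q, -1, -2)


def matrix_sqrt(M: np.ndarray) -> np.ndarray:
    """Principal square root of a PSD matrix (negative round-off clipped)."""
    w, Q = _eigh_sym(M)
    w = np.clip(w, 0.0, None)
    return (Q * np.sqrt(w)[..., None, :]) @ np.swapaxes(Q, -1, -2)


def log_frobenius_sq(A: np.ndarray, B: np.ndarray) -> float:
    """Squared log-Euclidean discrepancy ``|| log A - log B ||_F^2``.

    This is the quantity minimized during training. It is symmetric in its
    arguments, zero iff A == B, and invariant to a common positive scaling
    of both arguments (the logs shift by the same multiple of the identity).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"dimension mismatch: {A.shape} vs {B.shape}")
    D = matrix_log(A) - matrix_log(B)
    return float(np.sum(D * D))


def log_frobenius(A: np.ndarray, B: np.ndarray) -> float:
    """Log-Euclidean distance (square root of :func:`log_frobenius_sq`)."""
    return float(np.sqrt(log_frobenius_sq(A, B)))


def bures_w2(mu1, Sigma1, mu2, Sigma2) -> float:
    """2-Wasserstein distance between Gaussians N(mu1, S1) and N(mu2, S2).

    Closed form:
    ``W2^2 = ||mu1-mu2||^2 + Tr(S1 + S2 - 2 (S1^{1/2} S2 S1^{1/2})^{1/2})``.
    Matrix square roots are taken by eigendecomposition. Small negative
    round-off in the trace term is clipped to zero.
    """
    mu1 = np.atleast_1d(np.asarray(mu1, dtype=float))
    mu2 = np.atleast_1d(np.asarray(mu2, dtype=float))
    S1 = np.asarray(Sigma1, dtype=float)
    S2 = np.asarray(Sigma2, dtype=float)
    if mu1.shape != mu2.shape or S1.shape != S2.shape:
        raise ValueError("dimension mismatch between the two Gaussians")
    w1 = np.linalg.eigvalsh(symmetrize(S1))
    w2 = np.linalg.eigvalsh(symmetrize(S2))
    if w1.min() < -1e-10 or w2.min() < -1e-10:
        raise ValueError("bures_w2 requires positive semi-definite covariances")
    root1 = matrix_sqrt(S1)
    cross = matrix_sqrt(root1 @ S2 @ root1)
    w2sq = float(np.sum((mu1 - mu2) ** 2) + np.trace(S1) + np.trace(S2) - 2.0 * np.trace(cross))
    return float(np.sqrt(max(w2sq, 0.0)))


def nearest_correlation(
    A: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> np.ndarray:
    """Nearest correlation matrix by Higham's alternating projections.

    Alternates projection onto the PSD cone (eigenvalue clipping with Dykstra
    correction) and onto the unit-diagonal affine subspace. Used to repair a
    standardized coupling matrix that became indefinite after clipping.
    """
    A = symmetrize(np.asarray(A, dtype=float))
    n = A.shape[0]
    Y = A.copy()
    dS = np.zeros_like(A)
    for _ in range(max_iter):
        R = Y - dS
        w, Q = np.linalg.eigh(symmetrize(R))
        X = (Q * np.clip(w, 0.0, None)[None, :]) @ Q.T
        dS = X - R
        Y = X.copy()
        np.fill_diagonal(Y, 1.0)
        if np.linalg.norm(Y - X, ord="fro") < tol * max(1.0, np.linalg.norm(Y, ord="fro")):
            break
    # tiny jitter so the result is strictly PD, then re-standardize
    Y = symmetrize(Y) + 1e-10 * np.eye(n)
    d = np.sqrt(np.diag(Y))
    Y = Y / np.outer(d, d)
    np.fill_diagonal(Y, 1.0)
    return Y
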