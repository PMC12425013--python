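"""Joint-covariance reconstruction and Gaussian ensemble sampling.

Given per-residue 3x3 marginals and a unit-diagonal residue-residue
correlation matrix C~, the approximate joint covariance is assembled as

    Sigma_joint = L_marg (C~ ⊗ I3) L_marg^T,

where ``L_marg = ⊕_i L_i`` is block-diagonal in the per-residue Cholesky
factors. If every marginal is SPD and C~ is SPD, the reconstruction is SPD
(the product of a full-rank triangular matrix, an SPD Kronecker product,
and its transpose), and — because C~ has unit diagonal — its 3x3 diagonal
blocks reproduce the input marginals exactly.

A closed-form Cholesky factor of the reconstruction is available without
any dense 3N x 3N factorization:

    L = L_marg (chol(C~) ⊗ I3),

which is lower-triangular with positive diagonal. Sampling then uses the
reparameterization x = mu + L eps with eps ~ N(0, I).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import spd
from .labels import CorrelationMatrix, MarginalSet
from .structures import Ensemble, Structure

__all__ = [
    "JointFactor",
    "marginal_cholesky_factors",
    "reconstruct_joint",
    "joint_factor",
    "sample_conformations",
    "predict_to_ensemble",
]


@dataclass
class JointFactor:
    """Lower-triangular 3N x 3N factor L with positive diagonal (Sigma = L L^T)."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        d = self.matrix.shape[0]
        if self.matrix.shape != (d, d) or d % 3 != 0:
            raise ValueError("factor must be square with dimension 3N")
        if not np.allclose(np.triu(self.matrix, k=1), 0.0, atol=1e-10):
            raise ValueError("factor must be lower-triangular")
        if np.any(np.diag(self.matrix) <= 0):
            raise ValueError("factor diagonal must be strictly positive")

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0] // 3

    def covariance(self) -> np.ndarray:
        return self.matrix @ self.matrix.T


def marginal_cholesky_factors(
    marginals: MarginalSet, jitter: float = spd.DEFAULT_JITTER
) -> np.ndarray:
    """Cholesky factor of each 3x3 marginal, with jitter escalation."""
    n = marginals.n_residues
    out = np.empty((n, 3, 3))
    for i in range(n):
        M = spd.symmetrize(marginals.covs[i])
        for j in (0.0, jitter, 1e-6):
            try:
                out[i] = np.linalg.cholesky(M + j * np.eye(3))
                break
            except np.linalg.LinAlgError:
                continue
        else:
            raise ValueError(f"marginal covariance {i} is not positive definite")
    return out


def _check_correlation(
    ctilde: CorrelationMatrix, repair: bool, pd_floor: float = 1e-10
) -> np.ndarray:
    Ct = ctilde.values
    w = np.linalg.eigvalsh(spd.symmetrize(Ct))
    if w.min() < pd_floor:
        if not repair:
            raise ValueError(
                f"correlation matrix is not positive definite (min eigenvalue "
                f"{w.min():.3e}); pass repair=True (nearest-correlation "
                "projection) to proceed"
            )
        Ct = spd.nearest_correlation(Ct)
    return Ct


def reconstruct_joint(
    marginals: MarginalSet,
    ctilde: CorrelationMatrix,
    repair: bool = False,
) -> np.ndarray:
    """Assemble the approximate 3N x 3N joint covariance.

    Block (i, j) is ``L_i C~_ij L_j^T``. The result is symmetric PD for SPD
    inputs, and its diagonal blocks equal the input marginals exactly.

    Parameters
    ----------
    repair : bool
        If the correlation matrix is numerically indefinite (which can
        happen for standardized *predicted* couplings after clipping),
        project it to the nearest PD correlation matrix instead of raising.
        Off by default: silent repair would mask model failure.
    """
    n = marginals.n_residues
    if ctilde.n_residues != n:
        raise ValueError("marginals and correlation matrix disagree on N")
    Ct = _check_correlation(ctilde, repair)
    Ls = marginal_cholesky_factors(marginals)
    # Sigma[3i:3i+3, 3j:3j+3] = Ct[i, j] * L_i @ L_j.T
    cross = np.einsum("iab,jcb->ijac", Ls, Ls)  # (N, N, 3, 3) = L_i L_j^T
    blocks = Ct[:, :, None, None] * cross
    Sigma = blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)
    return spd.symmetrize(Sigma)


def joint_factor(
    marginals: MarginalSet,
    ctilde: CorrelationMatrix,
    repair: bool = False,
) -> JointFactor:
    """Closed-form Cholesky factor ``L = L_marg (chol(C~) ⊗ I3)``.

    Satisfies ``L L^T == reconstruct_joint(...)`` without ever factorizing
    the dense 3N x 3N matrix. Cholesky of C~ escalates jitter
    (0 -> 1e-10 -> 1e-6) before failing.
    """
    n = marginals.n_residues
    if ctilde.n_residues != n:
        raise ValueError("marginals and correlation matrix disagree on N")
    Ct = _check_correlation(ctilde, repair)
    for j in (0.0, 1e-10, 1e-6):
        try:
            K = np.linalg.cholesky(Ct + j * np.eye(n))
            break
        except np.linalg.LinAlgError:
            continue
    else:
        raise ValueError("correlation matrix Cholesky failed even with jitter")
    Ls = marginal_cholesky_factors(marginals)
    # block (i, j) of L_marg (K ⊗ I3) is K[i, j] * L_i  (block-diag times
    # block-lower-triangular with scalar*I3 blocks)
    blocks = K[:, :, None, None] * Ls[:, None, :, :]
    L = blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)
    L = np.tril(L)  # exact zeros above the diagonal (round-off guard)
    return JointFactor(matrix=L)


def sample_conformations(
    mu: np.ndarray,
    factor: JointFactor,
    T: int,
    seed: int,
) -> Ensemble:
    """Draw T conformations x = mu + L eps, eps ~ N(0, I), reshaped (T, N, 3).

    Deterministic for a given seed (numpy PCG64 generator).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    mu = np.asarray(mu, dtype=float).ravel()
    d = factor.matrix.shape[0]
    if mu.shape[0] != d:
        raise ValueError(f"mu has length {mu.shape[0]}, factor dimension {d}")
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((T, d))
    x = mu[None, :] + eps @ factor.matrix.T
    return Ensemble(coords=x.reshape(T, d // 3, 3), aligned=True)


def predict_to_ensemble(
    structure: Structure,
    marginals: MarginalSet,
    ctilde: CorrelationMatrix,
    T: int = 250,
    seed: int = 0,
    repair: bool = False,
) -> Ensemble:
    """Sample an ensemble around a structure from predicted dynamics.

    The Gaussian mean is fixed to the input structure's Cα coordinates (the
    input is taken as the equilibrium conformation; no mean is learned).
    """
    if marginals.n_residues != structure.n_residues:
        raise ValueError("marginals do not match structure length")
    factor = joint_factor(marginals, ctilde, repair=repair)
    mu = structure.ca_coords.ravel()
    return sample_conformations(mu, factor, T=T, seed=seed)
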