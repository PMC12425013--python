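"""Ground-truth dynamics labels from aligned conformational ensembles.

An aligned ensemble of T conformations defines an empirical Gaussian over
the flattened Cα coordinates X in R^{3N}. From its 3N x 3N covariance we
derive the label hierarchy used throughout the package:

* ``Sigma_marginal(i)`` — the 3x3 diagonal block for residue i (the
  anisotropic "Gaussian blob");
* ``C`` — the N x N scalar coupling, each entry the mean-pooled 3x3
  cross-covariance block;
* ``RMSF_i = sqrt(Tr Sigma_marginal(i))``;
* ``C~`` — the unit-diagonal correlation standardization of C.

Covariances use the unbiased T-1 denominator. Alignment superposes each
conformation independently onto a fixed reference structure (Kabsch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import Ensemble, Structure
from . import spd

__all__ = [
    "JointGaussian",
    "MarginalSet",
    "CouplingMatrix",
    "CorrelationMatrix",
    "kabsch_superpose",
    "align_ensemble",
    "empirical_joint",
    "marginals_from_joint",
    "coupling_from_joint",
    "rmsf_from_marginals",
    "correlation_standardize",
    "GaussianLabels",
    "EnsembleGaussianModel",
]


@dataclass
class JointGaussian:
    """Mean (3N,) and covariance (3N, 3N) of the flattened Cα coordinates."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = np.asarray(self.cov, dtype=float)
        d = self.mean.shape[0]
        if d % 3 != 0:
            raise ValueError("mean length must be a multiple of 3")
        if self.cov.shape != (d, d):
            raise ValueError(f"cov must be ({d}, {d})")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("joint covariance is not symmetric (tol 1e-8)")
        w = np.linalg.eigvalsh(spd.symmetrize(self.cov))
        if w.min() < -1e-8:
            raise ValueError(f"joint covariance has eigenvalue {w.min():.3e} < -1e-8")

    @property
    def n_residues(self) -> int:
        return self.mean.shape[0] // 3


@dataclass
class MarginalSet:
    """N per-residue 3x3 marginal covariances (Å²)."""

    covs: np.ndarray

    def __post_init__(self):
        self.covs = np.asarray(self.covs, dtype=float)
        if self.covs.ndim != 3 or self.covs.shape[1:] != (3, 3):
            raise ValueError("covs must be (N, 3, 3)")
        if not np.allclose(self.covs, np.swapaxes(self.covs, -1, -2), atol=1e-8):
            raise ValueError("marginal covariances must be symmetric")

    @property
    def n_residues(self) -> int:
        return self.covs.shape[0]


@dataclass
class CouplingMatrix:
    """N x N scalar residue-residue coupling C (Å²), symmetric."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("coupling must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("coupling must be symmetric (tol 1e-8)")

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]


@dataclass
class CorrelationMatrix:
    """Unit-diagonal standardization C~ of a coupling matrix, entries in [-1, 1]."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.max(np.abs(self.values)) > 1.0 + 1e-10:
            raise ValueError("correlation entries must lie in [-1, 1]")

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with ``det(R) = +1`` (reflections corrected),
    such that ``mobile @ R.T + t`` minimizes the RMSD to ``reference``.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and reference must both be (N, 3)")
    n = P.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12 * max(S[0], 1e-300):
        raise ValueError("degenerate geometry: points are (near-)collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def align_ensemble(ensemble: Ensemble, reference) -> Ensemble:
    """Superpose every conformation independently onto the reference Cα set."""
    ref = reference.ca_coords if isinstance(reference, Structure) else np.asarray(reference, float)
    if ensemble.n_residues != ref.shape[0]:
        raise ValueError(
            f"ensemble has {ensemble.n_residues} residues, reference {ref.shape[0]}"
        )
    out = np.empty_like(ensemble.coords)
    for t_idx in range(ensemble.n_frames):
        R, t, _ = kabsch_superpose(ensemble.coords[t_idx], ref)
        out[t_idx] = ensemble.coords[t_idx] @ R.T + t
    return Ensemble(coords=out, aligned=True)


def empirical_joint(aligned: Ensemble) -> JointGaussian:
    """Sample mean and unbiased (T-1) covariance of the flattened ensemble."""
    if not aligned.aligned:
        raise ValueError("ensemble must be aligned first (align_ensemble)")
    T = aligned.n_frames
    if T < 2:
        raise ValueError("need at least 2 conformations for a covariance")
    flat = aligned.coords.reshape(T, -1)
    mu = flat.mean(axis=0)
    X = flat - mu
    cov = (X.T @ X) / (T - 1)
    return JointGaussian(mean=mu, cov=spd.symmetrize(cov))


def marginals_from_joint(joint: JointGaussian) -> MarginalSet:
    """Extract the N 3x3 diagonal blocks of the joint covariance."""
    n = joint.n_residues
    blocks = joint.cov.reshape(n, 3, n, 3)
    covs = np.ascontiguousarray(blocks[np.arange(n), :, np.arange(n), :])
    return MarginalSet(covs=spd.symmetrize(covs))


def coupling_from_joint(joint: JointGaussian, pool: str = "mean9") -> CouplingMatrix:
    """Scalar-project each 3x3 block of the joint into an N x N coupling.

    ``pool='mean9'`` (default) takes the arithmetic mean of all nine block
    entries; ``pool='trace3'`` takes one third of the block trace. The two
    agree on isotropic blocks.
    """
    n = joint.n_residues
    blocks = joint.cov.reshape(n, 3, n, 3)
    if pool == "mean9":
        C = blocks.mean(axis=(1, 3))
    elif pool == "trace3":
        C = np.trace(blocks, axis1=1, axis2=3) / 3.0
    else:
        raise ValueError(f"unknown pooling {pool!r}; use 'mean9' or 'trace3'")
    return CouplingMatrix(values=0.5 * (C + C.T))


def rmsf_from_marginals(marginals: MarginalSet) -> np.ndarray:
    """Per-residue RMSF_i = sqrt(Tr Sigma_marginal(i)), in Å."""
    tr = np.trace(marginals.covs, axis1=-2, axis2=-1)
    if np.any(tr < -1e-8):
        raise ValueError(f"negative marginal trace {tr.min():.3e}")
    return np.sqrt(np.clip(tr, 0.0, None))


def correlation_standardize(C: CouplingMatrix) -> CorrelationMatrix:
    """Standardize a coupling matrix to unit diagonal, clipping to [-1, 1].

    For an exactly SPD input, Cauchy–Schwarz guarantees the clipping is a
    no-op; it only bites when C came from a noisy or approximate source.
    """
    d = np.diag(C.values)
    if np.any(d <= 0):
        raise ValueError("coupling diagonal must be strictly positive")
    s = np.sqrt(d)
    Ct = C.values / np.outer(s, s)
    Ct = np.clip(Ct, -1.0, 1.0)
    Ct = 0.5 * (Ct + Ct.T)
    np.fill_diagonal(Ct, 1.0)
    return CorrelationMatrix(values=Ct)


@dataclass
class GaussianLabels:
    """Results container: the full label hierarchy extracted from one ensemble."""

    joint: JointGaussian
    marginals: MarginalSet
    coupling: CouplingMatrix
    correlation: CorrelationMatrix
    rmsf: np.ndarray
    mean_structure: np.ndarray  # (N, 3)
    n_frames: int = 0

    def summary(self) -> str:
        n = self.marginals.n_residues
        lines = [
            "Gaussian dynamics labels",
            "=" * 40,
            f"residues:            {n}",
            f"ensemble frames:     {self.n_frames}",
            f"RMSF (Å)  min/med/max: {self.rmsf.min():.3f} / "
            f"{np.median(self.rmsf):.3f} / {self.rmsf.max():.3f}",
            f"coupling diag mean (Å²): {np.mean(np.diag(self.coupling.values)):.4f}",
            f"|corr| off-diag mean:  "
            f"{np.mean(np.abs(self.correlation.values[~np.eye(n, dtype=bool)])):.4f}",
        ]
        return "\n".join(lines)


class EnsembleGaussianModel:
    """Empirical Gaussian model of one conformational ensemble.

    Statsmodels-style: construct from data, call :meth:`fit` to obtain a
    :class:`GaussianLabels` results object.

    Parameters
    ----------
    ensemble : Ensemble
        T conformations (need not be pre-aligned).
    reference : Structure or (N, 3) array
        Alignment reference; each frame is independently superposed onto it.
    pool : str
        Scalar projection for the coupling ('mean9' or 'trace3').
    """

    def __init__(self, ensemble: Ensemble, reference, pool: str = "mean9"):
        self.ensemble = ensemble
        self.reference = reference
        self.pool = pool

    def fit(self, jitter: float = spd.DEFAULT_JITTER) -> GaussianLabels:
        aligned = (
            self.ensemble
            if self.ensemble.aligned
            else align_ensemble(self.ensemble, self.reference)
        )
        joint = empirical_joint(aligned)
        marginals = marginals_from_joint(joint)
        # jitter only where standardization/factorization needs invertibility
        coupling = coupling_from_joint(joint, pool=self.pool)
        cvals = coupling.values.copy()
        np.fill_diagonal(cvals, np.diag(cvals) + jitter)
        coupling = CouplingMatrix(values=cvals)
        correlation = correlation_standardize(coupling)
        rmsf = rmsf_from_marginals(marginals)
        n = joint.n_residues
        return GaussianLabels(
            joint=joint,
            marginals=marginals,
            coupling=coupling,
            correlation=correlation,
            rmsf=rmsf,
            mean_structure=joint.mean.reshape(n, 3),
            n_frames=aligned.n_frames,
        )
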