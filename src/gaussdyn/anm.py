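"""Anisotropic Network Model (ANM) baseline.

The classic elastic-network picture: Cα atoms within a distance cutoff are
joined by identical harmonic springs, giving a 3N x 3N Hessian with
off-diagonal blocks

    H_ij = -(gamma / |r_ij|^2) r_ij r_ij^T     for |r_ij| < cutoff,

and diagonal blocks enforcing the zero block-row-sum. The pseudo-inverse of
H over its non-rigid modes (the six translations/rotations are skipped by
count) approximates the positional covariance up to an overall kBT/gamma
scale, from which marginals, scalar coupling and RMSF are extracted with
the same label machinery used for ensembles.

Defaults (cutoff 15 Å, gamma 1) follow the common ANM convention. All
comparisons against labels should use scale-free (correlation-type)
metrics, or the optional least-squares scale fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

from .labels import (
    CorrelationMatrix,
    CouplingMatrix,
    JointGaussian,
    MarginalSet,
    correlation_standardize,
    coupling_from_joint,
    marginals_from_joint,
    rmsf_from_marginals,
)
from .structures import Structure

__all__ = ["ANMModel", "AnisotropicNetworkModel", "ANMResults", "anm_hessian", "anm_covariance"]

N_RIGID_MODES = 6


@dataclass
class ANMModel:
    """Assembled ANM Hessian plus its construction parameters."""

    hessian: np.ndarray
    cutoff: float = 15.0
    gamma: float = 1.0
    n_skipped_modes: int = N_RIGID_MODES

    @property
    def n_residues(self) -> int:
        return self.hessian.shape[0] // 3


def anm_hessian(ca_coords: np.ndarray, cutoff: float = 15.0, gamma: float = 1.0) -> ANMModel:
    """Assemble the 3N x 3N elastic-network Hessian.

    Raises if the contact graph at this cutoff is disconnected (the model
    would then have more than six zero modes).
    """
    X = np.asarray(ca_coords, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("ANM needs at least 3 residues")
    diff = X[:, None, :] - X[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    od = dist[~np.eye(n, dtype=bool)]
    if np.any(od < 1e-6):
        raise ValueError("duplicate Cα coordinates")
    contact = (dist < cutoff) & ~np.eye(n, dtype=bool)
    n_comp, _ = connected_components(contact, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"contact graph is disconnected at cutoff {cutoff} Å "
            f"({n_comp} components); increase the cutoff"
        )
    H = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(i + 1, n):
            if not contact[i, j]:
                continue
            r = diff[i, j]
            block = -(gamma / (dist[i, j] ** 2)) * np.outer(r, r)
            H[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
            H[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
            H[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
            H[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return ANMModel(hessian=0.5 * (H + H.T), cutoff=cutoff, gamma=gamma)


def anm_covariance(model: ANMModel) -> JointGaussian:
    """Pseudo-inverse covariance over the non-rigid modes (zero mean).

    Skips the ``n_skipped_modes`` smallest-eigenvalue modes by count and
    verifies the 7th eigenvalue is genuinely nonzero (> 1e-6 of the max).
    """
    H = model.hessian
    d = H.shape[0]
    if d // 3 < 3 or d - model.n_skipped_modes < 1:
        raise ValueError("too few residues for a non-trivial mode spectrum")
    w, Q = np.linalg.eigh(H)
    wmax = w[-1]
    k = model.n_skipped_modes
    if w[k] <= 1e-6 * wmax:
        raise ValueError(
            f"mode {k} has eigenvalue {w[k]:.3e} <= 1e-6 * max; the network "
            "is under-constrained (disconnected or near-degenerate geometry)"
        )
    inv = np.zeros(d)
    inv[k:] = 1.0 / w[k:]
    Sigma = (Q * inv[None, :]) @ Q.T
    return JointGaussian(mean=np.zeros(d), cov=0.5 * (Sigma + Sigma.T))


class AnisotropicNetworkModel:
    """ANM of one structure; ``fit()`` returns an :class:`ANMResults`.

    Parameters
    ----------
    structure : Structure or (N, 3) array
        Cα coordinates.
    cutoff : float, Å
    gamma : float
        Spring constant (arbitrary units; rescales the covariance by 1/gamma).
    """

    def __init__(self, structure, cutoff: float = 15.0, gamma: float = 1.0):
        self.ca_coords = (
            structure.ca_coords if isinstance(structure, Structure)
            else np.asarray(structure, dtype=float)
        )
        self.cutoff = cutoff
        self.gamma = gamma

    def fit(self, pool: str = "mean9") -> "ANMResults":
        model = anm_hessian(self.ca_coords, cutoff=self.cutoff, gamma=self.gamma)
        joint = anm_covariance(model)
        marginals = marginals_from_joint(joint)
        coupling = coupling_from_joint(joint, pool=pool)
        cvals = coupling.values.copy()
        np.fill_diagonal(cvals, np.diag(cvals) + 1e-12)
        coupling = CouplingMatrix(values=cvals)
        return ANMResults(
            model=model,
            joint=joint,
            marginals=marginals,
            coupling=coupling,
            correlation=correlation_standardize(coupling),
            rmsf=rmsf_from_marginals(marginals),
        )


@dataclass
class ANMResults:
    """Elastic-network covariance projected into the label hierarchy."""

    model: ANMModel
    joint: JointGaussian
    marginals: MarginalSet
    coupling: CouplingMatrix
    correlation: CorrelationMatrix
    rmsf: np.ndarray

    def scale_to(self, reference_rmsf: np.ndarray) -> float:
        """Least-squares variance scale s minimizing ||s^0.5 rmsf - ref||.

        Returns the multiplicative factor to apply to the covariance (the
        ANM scale is arbitrary; use for RMWD-type absolute comparisons).
        """
        ref = np.asarray(reference_rmsf, dtype=float)
        num = float(np.dot(self.rmsf, ref))
        den = float(np.dot(self.rmsf, self.rmsf))
        return (num / den) ** 2

    def summary(self) -> str:
        w = np.linalg.eigvalsh(self.model.hessian)
        n = self.model.n_residues
        return "\n".join([
            "Anisotropic network model",
            "=" * 40,
            f"residues:        {n}",
            f"cutoff (Å):      {self.model.cutoff}",
            f"gamma:           {self.model.gamma}",
            f"zero modes:      {int(np.sum(np.abs(w) < 1e-8 * w[-1]))}",
            f"mode 7 / max eig: {w[N_RIGID_MODES] / w[-1]:.3e}",
            f"RMSF (rel) min/med/max: {self.rmsf.min():.3f} / "
            f"{np.median(self.rmsf):.3f} / {self.rmsf.max():.3f}",
        ])
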