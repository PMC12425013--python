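"""Evaluation metrics for predicted dynamics and sampled ensembles.

Covers:

* Pearson correlation of per-residue RMSF profiles;
* the root mean 2-Wasserstein distance (RMWD) across per-residue Gaussians,
  with a variance-only variant that drops the mean term;
* the variance contribution of the symmetric KL divergence between
  per-residue Gaussians (zero-mean form);
* band-wise Pearson correlation of residue-residue correlation matrices as
  a function of sequence separation (cumulative bands k = 1..k_max);
* ensemble-level metrics: within-ensemble pairwise RMSD, RMSF correlation,
  2-Wasserstein distances of 2D PCA projections (Gaussian closed form), and
  Jaccard similarity of weak / transient contact sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import spd
from .labels import (
    CorrelationMatrix,
    MarginalSet,
    kabsch_superpose,
)
from .structures import Ensemble, Structure

__all__ = [
    "rmsf_pearson",
    "rmwd",
    "symmetric_kl_var",
    "bandwise_pearson",
    "contact_occupancy",
    "ensemble_metrics",
    "MetricReport",
    "summarize_metrics",
]


def rmsf_pearson(pred_rmsf, true_rmsf) -> float:
    """Pearson r between two RMSF profiles; NaN when either is constant."""
    p = np.asarray(pred_rmsf, dtype=float)
    t = np.asarray(true_rmsf, dtype=float)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError("RMSF profiles must be 1-D and equal length")
    if p.size < 3:
        raise ValueError("need at least 3 residues for a correlation")
    if np.std(p) == 0 or np.std(t) == 0:
        return float("nan")
    return float(stats.pearsonr(p, t)[0])


def rmwd(
    pred: MarginalSet,
    true: MarginalSet,
    pred_means: np.ndarray | None = None,
    true_means: np.ndarray | None = None,
    variance_only: bool = False,
) -> float:
    """Root mean squared 2-Wasserstein distance over per-residue Gaussians.

    ``sqrt( (1/N) sum_i W2^2(N_i^pred, N_i^true) )`` in Å. With
    ``variance_only`` the squared mean-difference term of each W2^2 is
    dropped, leaving the covariance (Bures) contribution — and the means
    are not required.
    """
    n = pred.n_residues
    if true.n_residues != n:
        raise ValueError("marginal sets disagree on N")
    if not variance_only:
        if pred_means is None or true_means is None:
            raise ValueError("means are required unless variance_only=True")
        pm = np.asarray(pred_means, dtype=float).reshape(n, 3)
        tm = np.asarray(true_means, dtype=float).reshape(n, 3)
    total = 0.0
    zero = np.zeros(3)
    for i in range(n):
        mu_p = zero if variance_only else pm[i]
        mu_t = zero if variance_only else tm[i]
        w2 = spd.bures_w2(mu_p, pred.covs[i], mu_t, true.covs[i])
        total += w2 * w2
    return float(np.sqrt(total / n))


def symmetric_kl_var(pred: MarginalSet, true: MarginalSet):
    """Variance contribution of the symmetric KL divergence, per residue.

    For zero-mean Gaussians with covariances P and Q,
    ``KL(p||q) + KL(q||p) = 0.5 [Tr(Q^-1 P) + Tr(P^-1 Q)] - 3``.
    Returns ``(per_residue_values, mean)``.
    """
    n = pred.n_residues
    if true.n_residues != n:
        raise ValueError("marginal sets disagree on N")
    vals = np.empty(n)
    for i in range(n):
        P = spd.symmetrize(pred.covs[i])
        Q = spd.symmetrize(true.covs[i])
        try:
            qi_p = np.linalg.solve(Q, P)
            pi_q = np.linalg.solve(P, Q)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"singular marginal covariance at residue {i}; add jitter"
            ) from exc
        vals[i] = 0.5 * (np.trace(qi_p) + np.trace(pi_q)) - 3.0
    return vals, float(np.mean(vals))


def bandwise_pearson(
    pred: CorrelationMatrix,
    true: CorrelationMatrix,
    k_max: int = 50,
) -> np.ndarray:
    """Pearson r between correlation matrices within cumulative diagonal bands.

    Band k collects the upper-triangle entries with sequence separation
    ``1 <= j - i <= k`` (the main diagonal, identically 1 in both, is
    excluded). Bands are cumulative: band k contains band k-1. Bands with
    fewer than 3 entries are reported as NaN.
    """
    n = pred.n_residues
    if true.n_residues != n:
        raise ValueError("correlation matrices disagree on N")
    i_idx, j_idx = np.triu_indices(n, k=1)
    sep = j_idx - i_idx
    p = pred.values[i_idx, j_idx]
    t = true.values[i_idx, j_idx]
    out = np.full(k_max, np.nan)
    for k in range(1, k_max + 1):
        m = sep <= k
        if np.sum(m) < 3 or np.std(p[m]) == 0 or np.std(t[m]) == 0:
            continue
        out[k - 1] = stats.pearsonr(p[m], t[m])[0]
    return out


def _ensemble_rmsf(ens: Ensemble) -> np.ndarray:
    mean = ens.coords.mean(axis=0)
    return np.sqrt(np.mean(np.sum((ens.coords - mean) ** 2, axis=-1), axis=0))


def _pairwise_rmsd(ens: Ensemble, max_pairs: int = 1000, seed: int = 0) -> float:
    """Mean Cα RMSD over (a subsample of) conformation pairs, with
    per-pair superposition."""
    T = ens.n_frames
    if T < 2:
        raise ValueError("pairwise RMSD needs at least 2 conformations")
    pairs = [(a, b) for a in range(T) for b in range(a + 1, T)]
    if len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]
    vals = [kabsch_superpose(ens.coords[a], ens.coords[b])[2] for a, b in pairs]
    return float(np.mean(vals))


def contact_occupancy(ens: Ensemble, cutoff: float = 8.0, min_sep: int = 3) -> np.ndarray:
    """Fraction of frames in which each residue pair is within ``cutoff`` Å.

    Pairs closer than ``min_sep`` in sequence are masked out (NaN): trivially
    permanent neighbor contacts carry no dynamical information.
    """
    X = ens.coords
    d = np.linalg.norm(X[:, :, None, :] - X[:, None, :, :], axis=-1)
    occ = np.mean(d < cutoff, axis=0)
    n = occ.shape[0]
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    occ[np.abs(ii - jj) < min_sep] = np.nan
    return occ


def _jaccard(set_a: set, set_b: set) -> float:
    union = set_a | set_b
    if not union:
        return float("nan")
    return len(set_a & set_b) / len(union)


def _pca_w2(pred: Ensemble, ref: Ensemble, components_from: str = "reference") -> float:
    """2-Wasserstein distance between the two ensembles projected onto the
    top-2 principal components, under a Gaussian approximation of each
    projected cloud (closed form)."""
    P = pred.coords.reshape(pred.n_frames, -1)
    R = ref.coords.reshape(ref.n_frames, -1)
    if components_from == "reference":
        basis_data = R
    elif components_from == "joint":
        basis_data = np.vstack([R, P])
    else:
        raise ValueError("components_from must be 'reference' or 'joint'")
    center = basis_data.mean(axis=0)
    Xc = basis_data - center
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    W = Vt[:2].T  # (3N, 2)
    pp = (P - center) @ W
    rr = (R - center) @ W
    mu_p, mu_r = pp.mean(axis=0), rr.mean(axis=0)
    cov_p = np.cov(pp, rowvar=False)
    cov_r = np.cov(rr, rowvar=False)
    return spd.bures_w2(mu_p, np.atleast_2d(cov_p), mu_r, np.atleast_2d(cov_r))


@dataclass
class MetricReport:
    """Named per-protein metric values with quartile summaries."""

    values: dict = field(default_factory=dict)  # metric -> list of floats

    def add(self, name: str, value: float):
        self.values.setdefault(name, []).append(float(value))

    def update(self, other: dict):
        for k, v in other.items():
            self.add(k, v)

    def summary(self) -> dict:
        out = {}
        for name, vals in self.values.items():
            arr = np.asarray(vals, dtype=float)
            finite = arr[np.isfinite(arr)]
            entry = {"n": int(finite.size), "n_missing": int(arr.size - finite.size)}
            if finite.size:
                q25, med, q75 = np.percentile(finite, [25, 50, 75])
                entry.update(p25=float(q25), median=float(med), p75=float(q75))
            out[name] = entry
        return out

    def summary_table(self) -> str:
        rows = ["{:<24s} {:>8s} {:>8s} {:>8s} {:>4s}".format(
            "metric", "p25", "median", "p75", "n")]
        for name, entry in self.summary().items():
            if "median" in entry:
                rows.append("{:<24s} {:>8.3f} {:>8.3f} {:>8.3f} {:>4d}".format(
                    name, entry["p25"], entry["median"], entry["p75"], entry["n"]))
            else:
                rows.append(f"{name:<24s} {'—':>8s} {'—':>8s} {'—':>8s} {0:>4d}")
        return "\n".join(rows)


def ensemble_metrics(
    pred: Ensemble,
    reference: Ensemble,
    input_structure: Structure,
    contact_cutoff: float = 8.0,
    weak_band: tuple = (0.1, 0.9),
    transient_min: float = 0.1,
    min_sep: int = 3,
    max_pairs: int = 1000,
    seed: int = 0,
) -> dict:
    """Ensemble-vs-ensemble comparison for one protein.

    Both ensembles must be aligned to the input structure. Contacts are
    Cα–Cα distances below ``contact_cutoff``; *weak* contacts have reference
    occupancy strictly inside ``weak_band``; *transient* contacts are absent
    in the input structure but occupied in > ``transient_min`` of reference
    frames. Predicted sets use the same rules on the predicted ensemble and
    are compared by Jaccard similarity.
    """
    if pred.n_residues != reference.n_residues != input_structure.n_residues:
        raise ValueError("residue count mismatch")
    if pred.n_frames < 2 or reference.n_frames < 2:
        raise ValueError("both ensembles need at least 2 conformations")
    out = {}
    out["pairwise_rmsd_pred"] = _pairwise_rmsd(pred, max_pairs=max_pairs, seed=seed)
    out["pairwise_rmsd_ref"] = _pairwise_rmsd(reference, max_pairs=max_pairs, seed=seed)
    rmsf_p = _ensemble_rmsf(pred)
    rmsf_r = _ensemble_rmsf(reference)
    out["rmsf_pred_mean"] = float(np.mean(rmsf_p))
    out["rmsf_ref_mean"] = float(np.mean(rmsf_r))
    out["rmsf_r"] = rmsf_pearson(rmsf_p, rmsf_r)
    out["md_pca_w2"] = _pca_w2(pred, reference, components_from="reference")
    out["joint_pca_w2"] = _pca_w2(pred, reference, components_from="joint")

    occ_p = contact_occupancy(pred, cutoff=contact_cutoff, min_sep=min_sep)
    occ_r = contact_occupancy(reference, cutoff=contact_cutoff, min_sep=min_sep)
    n = occ_p.shape[0]
    iu = np.triu_indices(n, k=min_sep)
    lo, hi = weak_band
    weak_r = {tuple(p) for p in np.argwhere(
        np.triu((occ_r > lo) & (occ_r < hi), k=min_sep))}
    weak_p = {tuple(p) for p in np.argwhere(
        np.triu((occ_p > lo) & (occ_p < hi), k=min_sep))}
    out["weak_contacts_j"] = _jaccard(weak_p, weak_r)

    Xin = input_structure.ca_coords
    din = np.linalg.norm(Xin[:, None, :] - Xin[None, :, :], axis=-1)
    not_in_input = din >= contact_cutoff
    trans_r = {tuple(p) for p in np.argwhere(
        np.triu(not_in_input & (occ_r > transient_min), k=min_sep))}
    trans_p = {tuple(p) for p in np.argwhere(
        np.triu(not_in_input & (occ_p > transient_min), k=min_sep))}
    out["transient_contacts_j"] = _jaccard(trans_p, trans_r)
    return out


def summarize_metrics(per_protein: list) -> MetricReport:
    """Collect per-protein metric dicts into a quartile report."""
    report = MetricReport()
    for d in per_protein:
        report.update(d)
    return report
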