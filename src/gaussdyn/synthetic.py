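"""Synthetic chains, ground-truth covariances, and labeled datasets.

Real training corpora for this problem are MD simulation archives; for
desk-scale development and testing this module manufactures complete
substitutes with *known* ground truth:

* self-avoiding Cα chains with ideal virtual bond length (3.8 Å) and
  synthetic backbone N/C atoms so residue frames are well defined;
* a ground-truth joint covariance in one of two families:

  - ``kronecker`` — per-residue SPD marginals combined with an exponential
    residue-residue correlation ``C~_ij = exp(-|i-j|/decay)`` through the
    package's own reconstruction formula, so label extraction followed by
    reconstruction is *exact* on this family. Marginal magnitudes are tied
    to local contact density (buried residues fluctuate less) so that the
    labels are a learnable function of structure, with a small seeded
    lognormal perturbation;
  - ``anm`` — the elastic-network covariance of the chain (plus jitter),
    which is structure-determined but lies outside the Kronecker family;

* sampled ensembles of T conformations from the ground truth, and datasets
  of (structure PDB, ensemble PDB, labels HDF5) triples with a
  deterministic JSON manifest and train/val/test split assignment.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .anm import AnisotropicNetworkModel
from .joint import joint_factor, reconstruct_joint, sample_conformations
from .labels import (
    CorrelationMatrix,
    EnsembleGaussianModel,
    JointGaussian,
    MarginalSet,
    coupling_from_joint,
)
from .nn import AMINO_ACIDS
from .structures import Ensemble, Structure, write_ensemble, write_structure
from .labelio import save_labels

__all__ = ["SyntheticSpec", "make_chain", "make_ground_truth", "make_dataset"]

BOND_LENGTH = 3.8  # Å, consecutive Cα
MIN_NONBONDED = 3.0  # Å, self-avoidance floor


@dataclass
class SyntheticSpec:
    """Study conditions for a synthetic dataset.

    Defaults are desk-scale: 25 chains of 20–40 residues, ensembles of
    T=1000 conformations, Kronecker-family ground truth with marginal
    traces between 0.25 and 2.25 Å² (RMSF 0.5–1.5 Å, the range typical of
    folded-domain backbones) and a 5-residue correlation decay length.
    """

    n_proteins: int = 25
    length_range: tuple = (20, 40)
    ensemble_size: int = 1000
    family: str = "kronecker"  # 'kronecker' | 'anm'
    scale_range: tuple = (0.25, 2.25)  # Å², marginal trace
    decay: float = 5.0  # residues
    anisotropy: tuple = (0.45, 0.33, 0.22)  # marginal eigenvalue fractions
    burial_offset: float = 5.0  # soft-coordination value of a fully exposed residue
    burial_softness: float = 4.0  # e-folding of trace vs soft coordination
    seed: int = 0
    n_val: int = 0
    n_test: int = 5

    def __post_init__(self):
        if self.n_proteins <= 0 or self.ensemble_size <= 0 or self.decay <= 0:
            raise ValueError("spec parameters must be positive")
        if self.family not in ("kronecker", "anm"):
            raise ValueError("family must be 'kronecker' or 'anm'")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.n_val + self.n_test >= self.n_proteins:
            raise ValueError("splits leave no training proteins")


def make_chain(n: int, seed: int, max_retries: int = 200) -> Structure:
    """Self-avoiding Cα random walk with synthetic backbone atoms.

    Consecutive Cα distance is exactly 3.8 Å; all non-adjacent pairs are at
    least 3.0 Å apart. The walk is direction-persistent (bond-angle jitter
    around a preferred turn) which yields compact but non-clashing chains.
    N and C atoms are placed at ideal lengths in a frame built from the
    local chain direction, so Gram–Schmidt frames are always well defined.
    """
    if n < 5:
        raise ValueError("chains must have at least 5 residues")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        coords = _try_walk(n, rng)
        if coords is not None:
            break
    else:
        raise RuntimeError(f"failed to place a self-avoiding {n}-residue chain")
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
    n_at, c_at = _synthetic_backbone(coords, rng)
    return Structure(
        sequence=seq, ca_coords=coords, n_coords=n_at, c_coords=c_at, chain_id="A"
    )


def _try_walk(n: int, rng: np.random.Generator):
    coords = np.zeros((n, 3))
    d = np.array([1.0, 0.0, 0.0])
    for i in range(1, n):
        centroid = coords[:i].mean(axis=0)
        for _ in range(60):
            # persistent direction with angular jitter, biased toward the
            # running centroid so chains are globular (like folded domains)
            # rather than extended random coils
            pull = centroid - coords[i - 1]
            norm = np.linalg.norm(pull)
            pull = pull / norm if norm > 1e-9 else 0.0 * pull
            perturb = rng.normal(scale=0.55, size=3)
            cand = d + perturb + 0.45 * pull
            cand /= np.linalg.norm(cand)
            new = coords[i - 1] + BOND_LENGTH * cand
            if i >= 2:
                dists = np.linalg.norm(coords[: i - 1] - new, axis=1)
                if dists.min() < MIN_NONBONDED:
                    continue
            coords[i] = new
            d = cand
            break
        else:
            return None
    return coords


def _synthetic_backbone(ca: np.ndarray, rng: np.random.Generator):
    """Ideal-geometry N and C atoms around each Cα.

    Uses a frame from the local chain tangent; the last residue reuses the
    previous tangent. Offsets mimic ideal residue geometry: C at 1.52 Å
    along the first axis, N at 1.46 Å in the plane of the first two axes.
    """
    n = ca.shape[0]
    n_at = np.empty_like(ca)
    c_at = np.empty_like(ca)
    for i in range(n):
        t = ca[min(i + 1, n - 1)] - ca[i - 1 if i == n - 1 else i]
        t = t / np.linalg.norm(t)
        # stable perpendicular
        ref = np.array([0.0, 0.0, 1.0]) if abs(t[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(t, ref)
        u /= np.linalg.norm(u)
        c_at[i] = ca[i] + 1.52 * t
        n_at[i] = ca[i] + 1.46 * (-0.39 * t + 0.92 * u)
    return n_at, c_at


def _contact_counts(ca: np.ndarray, cutoff: float = 8.0) -> np.ndarray:
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    return np.sum((d < cutoff) & (d > 1e-9), axis=1)


def _soft_burial(ca: np.ndarray, radius: float = 8.0) -> np.ndarray:
    """Soft coordination number: sum_j exp(-d_ij^2 / (2 r^2)), j != i."""
    d2 = np.sum((ca[:, None, :] - ca[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    return np.exp(-d2 / (2.0 * radius * radius)).sum(axis=1)


def make_ground_truth(chain: Structure, spec: SyntheticSpec):
    """Ground-truth (marginals, correlation, joint) for one chain.

    Returns ``(MarginalSet, CorrelationMatrix, JointGaussian)``.
    """
    import zlib

    stable = zlib.crc32(chain.sequence.encode()) % 10007
    rng = np.random.default_rng(spec.seed + 104729 * stable)
    return _ground_truth_with_rng(chain, spec, rng)


def _ground_truth_with_rng(chain: Structure, spec: SyntheticSpec,
                           rng: np.random.Generator):
    n = chain.n_residues
    if spec.family == "anm":
        res = AnisotropicNetworkModel(chain).fit()
        # rescale so the median marginal trace sits mid scale-range
        target = 0.5 * (spec.scale_range[0] + spec.scale_range[1])
        tr = np.trace(res.marginals.covs, axis1=-2, axis2=-1)
        s = target / np.median(tr)
        cov = s * res.joint.cov + 1e-8 * np.eye(3 * n)
        joint = JointGaussian(mean=chain.ca_coords.ravel(), cov=cov)
        marg = MarginalSet(covs=s * res.marginals.covs + 1e-8 * np.eye(3))
        return marg, res.correlation, joint

    # kronecker family: marginal scale decays exponentially with burial
    # (soft coordination number), an absolute, smooth, local map — exposed
    # residues move more, and the same structural feature means the same
    # flexibility in every chain
    burial = _soft_burial(chain.ca_coords)
    smin, smax = spec.scale_range
    exposure = np.clip(
        np.exp(-(burial - spec.burial_offset) / spec.burial_softness), 0.0, 1.0
    )
    trace = smin + (smax - smin) * exposure
    trace = trace * np.exp(rng.normal(scale=0.08, size=n))  # mild seeded noise
    # anisotropy: one randomly oriented shape matrix per protein (moderate
    # eigenvalue fractions, unit trace) scaled per residue. A shared shape
    # keeps the family "isotropy compatible": mean-pooled coupling then
    # standardizes back to the generating correlation exactly, so label
    # extraction followed by reconstruction reproduces the joint.
    fractions = np.asarray(spec.anisotropy, dtype=float)
    fractions = fractions / fractions.sum()
    M = rng.standard_normal((3, 3))
    V, _ = np.linalg.qr(M)
    if np.linalg.det(V) < 0:
        V[:, 0] = -V[:, 0]
    shape = V @ np.diag(fractions) @ V.T
    covs = trace[:, None, None] * shape[None, :, :]
    marginals = MarginalSet(covs=covs)
    idx = np.arange(n)
    Ct = np.exp(-np.abs(idx[:, None] - idx[None, :]) / spec.decay)
    ctilde = CorrelationMatrix(values=Ct)
    cov = reconstruct_joint(marginals, ctilde)
    joint = JointGaussian(mean=chain.ca_coords.ravel(), cov=cov)
    return marginals, ctilde, joint


def _item_records(spec: SyntheticSpec):
    """Deterministic per-item seeds and split labels."""
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_proteins)
    n_train = spec.n_proteins - spec.n_val - spec.n_test
    records = []
    for i, child in enumerate(children):
        split = ("train" if i < n_train
                 else "val" if i < n_train + spec.n_val else "test")
        # keep derived seeds in int32 range for portability
        seed_i = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
        records.append({"index": i, "seed": seed_i, "split": split})
    return records


def generate_protein(spec: SyntheticSpec, item_seed: int):
    """One synthetic protein: chain, ground truth, sampled ensemble, labels.

    Returns a dict with keys ``structure``, ``marginals``, ``correlation``,
    ``joint`` (the clean generator truth), ``ensemble`` (T sampled
    conformations) and ``labels`` (a :class:`GaussianLabels` re-extracted
    from the sampled ensemble — i.e. carrying realistic sampling noise).
    """
    rng = np.random.default_rng(item_seed)
    n = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    chain = make_chain(n, seed=int(rng.integers(2**31 - 1)))
    marg, ctilde, joint = _ground_truth_with_rng(chain, spec, rng)
    factor = joint_factor(marg, ctilde) if spec.family == "kronecker" else None
    if factor is not None:
        ens = sample_conformations(
            joint.mean, factor, T=spec.ensemble_size,
            seed=int(rng.integers(2**31 - 1)),
        )
    else:
        # general PSD joint: sample through its (jittered) dense Cholesky
        L = np.linalg.cholesky(joint.cov + 1e-8 * np.eye(joint.cov.shape[0]))
        g = np.random.default_rng(int(rng.integers(2**31 - 1)))
        x = joint.mean[None, :] + g.standard_normal(
            (spec.ensemble_size, joint.cov.shape[0])
        ) @ L.T
        ens = Ensemble(coords=x.reshape(spec.ensemble_size, n, 3), aligned=True)
    labels = EnsembleGaussianModel(ens, chain).fit()
    return {
        "structure": chain,
        "marginals": marg,
        "correlation": ctilde,
        "joint": joint,
        "ensemble": ens,
        "labels": labels,
    }


def make_dataset(spec: SyntheticSpec, out_dir=None):
    """Generate the full dataset; optionally write it to disk.

    In-memory: returns ``(items, manifest)`` where each item is the dict of
    :func:`generate_protein` plus its manifest record. On disk (``out_dir``
    given): writes ``prot_XXX.pdb`` (structure), ``prot_XXX_ens.pdb``
    (ensemble), ``prot_XXX.h5`` (clean + empirical labels) and
    ``manifest.json``; re-running with the same spec is byte-identical.
    """
    records = _item_records(spec)
    items = []
    manifest = {"spec": _spec_dict(spec), "items": []}
    for rec in records:
        item = generate_protein(spec, rec["seed"])
        item.update(rec)
        entry = dict(rec)
        entry["n_residues"] = item["structure"].n_residues
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            stem = f"prot_{rec['index']:03d}"
            write_structure(item["structure"], out / f"{stem}.pdb")
            write_ensemble(
                item["ensemble"], item["structure"], out / f"{stem}_ens.pdb",
                bfactors=item["labels"].rmsf,
            )
            save_labels(
                out / f"{stem}.h5",
                clean={
                    "marginals": item["marginals"].covs,
                    "coupling": coupling_from_joint(item["joint"]).values,
                    "correlation": item["correlation"].values,
                    "rmsf": np.sqrt(np.trace(item["marginals"].covs,
                                             axis1=-2, axis2=-1)),
                    "mean": item["structure"].ca_coords,
                },
                empirical={
                    "marginals": item["labels"].marginals.covs,
                    "coupling": item["labels"].coupling.values,
                    "correlation": item["labels"].correlation.values,
                    "rmsf": item["labels"].rmsf,
                    "mean": item["labels"].mean_structure,
                },
            )
            entry["structure_file"] = f"{stem}.pdb"
            entry["ensemble_file"] = f"{stem}_ens.pdb"
            entry["labels_file"] = f"{stem}.h5"
        manifest["items"].append(entry)
        items.append(item)
    if out_dir is not None:
        with open(Path(out_dir) / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return items, manifest


def _spec_dict(spec: SyntheticSpec) -> dict:
    d = asdict(spec)
    d["length_range"] = list(d["length_range"])
    d["scale_range"] = list(d["scale_range"])
    return d
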