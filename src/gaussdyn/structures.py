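"""Protein structures, conformational ensembles, and residue frames.

The package works on a coarse-grained backbone representation: each residue
contributes its Cα coordinate (plus the backbone N and C atoms, which are
only needed to orient a local rigid frame). Structures are read from and
written to plain PDB; ensembles are multi-model PDB files with one MODEL
record per conformation.

Per-residue rigid frames ``T_i = (R_i, t_i)`` follow the Gram–Schmidt
convention of the AlphaFold2 structure module: the first axis points from
Cα to the backbone carbonyl C, the second is the component of Cα→N
orthogonal to it, and the third completes a right-handed basis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.sequence import ProteinSequence

__all__ = [
    "Structure",
    "ResidueFrameSet",
    "Ensemble",
    "read_structure",
    "read_ensemble",
    "write_structure",
    "write_ensemble",
    "frames_from_backbone",
]


@dataclass
class Structure:
    """A single-chain backbone structure.

    Attributes
    ----------
    sequence : str
        One-letter amino-acid string of length N (unknown residues as 'X').
    ca_coords : (N, 3) float array, Å
    n_coords, c_coords : (N, 3) float array or None
        Backbone N and carbonyl C atoms; optional (Cα-only inputs).
    chain_id : str
    residue_numbers : list of int
        Author residue numbers, 1-based as reported in the file.
    """

    sequence: str
    ca_coords: np.ndarray
    n_coords: np.ndarray | None = None
    c_coords: np.ndarray | None = None
    chain_id: str = "A"
    residue_numbers: list = field(default_factory=list)

    def __post_init__(self):
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if self.ca_coords.ndim != 2 or self.ca_coords.shape[1] != 3:
            raise ValueError("ca_coords must be (N, 3)")
        n = self.ca_coords.shape[0]
        if n < 2:
            raise ValueError("a structure needs at least 2 residues")
        if len(self.sequence) != n:
            raise ValueError(
                f"sequence length {len(self.sequence)} != coordinate rows {n}"
            )
        for name in ("n_coords", "c_coords"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (n, 3):
                    raise ValueError(f"{name} must be (N, 3)")
                setattr(self, name, v)
        if not self.residue_numbers:
            self.residue_numbers = list(range(1, n + 1))
        coords = [self.ca_coords] + [
            v for v in (self.n_coords, self.c_coords) if v is not None
        ]
        if not all(np.all(np.isfinite(c)) for c in coords):
            raise ValueError("non-finite coordinates")

    @property
    def n_residues(self) -> int:
        return self.ca_coords.shape[0]

    def has_backbone(self) -> bool:
        return self.n_coords is not None and self.c_coords is not None


@dataclass
class ResidueFrameSet:
    """Per-residue rigid frames: rotations (N,3,3), translations (N,3) Å."""

    rotations: np.ndarray
    translations: np.ndarray

    def __post_init__(self):
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        if self.rotations.ndim != 3 or self.rotations.shape[1:] != (3, 3):
            raise ValueError("rotations must be (N, 3, 3)")
        if self.translations.shape != (self.rotations.shape[0], 3):
            raise ValueError("translations must be (N, 3)")

    @property
    def n_residues(self) -> int:
        return self.rotations.shape[0]

    def transform(self, Q: np.ndarray, b: np.ndarray) -> "ResidueFrameSet":
        """Frames after a global rigid motion x -> Q x + b of the structure."""
        Q = np.asarray(Q, dtype=float)
        b = np.asarray(b, dtype=float)
        return ResidueFrameSet(
            rotations=np.einsum("ab,ibc->iac", Q, self.rotations),
            translations=self.translations @ Q.T + b,
        )


@dataclass
class Ensemble:
    """T conformations of one chain: coords (T, N, 3) Å plus an aligned flag."""

    coords: np.ndarray
    aligned: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (T, N, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("an ensemble needs at least one conformation")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite ensemble coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]


def _three_to_one(res_name: str) -> str:
    try:
        code = ProteinSequence.convert_letter_3to1(res_name.capitalize())
        return code if code != "" else "X"
    except Exception:
        return "X"


def _load_atoms(path) -> struc.AtomArrayStack:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(altloc="occupancy")
    except Exception as exc:  # pragma: no cover - message formatting only
        raise ValueError(f"could not parse PDB file {path}: {exc}") from exc
    return atoms


def _select_chain(atoms, chain):
    chains = sorted(set(atoms.chain_id))
    if chain is None:
        if len(chains) > 1:
            raise ValueError(
                f"file contains multiple chains {chains}; pass chain= explicitly"
            )
        chain = chains[0]
    if chain not in chains:
        raise ValueError(f"chain {chain!r} not found; available chains: {chains}")
    return atoms[..., atoms.chain_id == chain], chain


def _residues_from_array(arr: struc.AtomArray, chain: str):
    """Extract per-residue CA/N/C coordinates in residue order."""
    mask = struc.filter_amino_acids(arr)
    arr = arr[mask] if mask.any() else arr
    starts = struc.get_residue_starts(arr, add_exclusive_stop=True)
    seq, cas, ns, cs, numbers = [], [], [], [], []
    have_n = have_c = True
    for s, e in zip(starts[:-1], starts[1:]):
        res = arr[s:e]
        names = list(res.atom_name)
        if "CA" not in names:
            raise ValueError(
                f"residue {res.res_name[0]} {res.res_id[0]} in chain {chain} "
                "has no CA atom"
            )
        cas.append(res.coord[names.index("CA")])
        seq.append(_three_to_one(res.res_name[0]))
        numbers.append(int(res.res_id[0]))
        if "N" in names:
            ns.append(res.coord[names.index("N")])
        else:
            have_n = False
        if "C" in names:
            cs.append(res.coord[names.index("C")])
        else:
            have_c = False
    return (
        "".join(seq),
        np.array(cas, dtype=float),
        np.array(ns, dtype=float) if have_n else None,
        np.array(cs, dtype=float) if have_c else None,
        numbers,
    )


def read_structure(path, chain: str | None = None) -> Structure:
    """Read a single-model, single-chain structure from a PDB file.

    Altloc conflicts are resolved to the highest-occupancy conformer (ties
    resolve to altloc 'A'). Residues are returned in file order, which for
    well-formed files is residue-number order with insertion codes preserved.
    """
    atoms = _load_atoms(path)
    if isinstance(atoms, struc.AtomArrayStack):
        atoms = atoms[0]
    atoms, chain = _select_chain(atoms, chain)
    seq, cas, ns, cs, numbers = _residues_from_array(atoms, chain)
    return Structure(
        sequence=seq,
        ca_coords=cas,
        n_coords=ns,
        c_coords=cs,
        chain_id=chain,
        residue_numbers=numbers,
    )


def read_ensemble(path, chain: str | None = None) -> Ensemble:
    """Read a multi-model PDB file as a Cα ensemble (T, N, 3)."""
    atoms = _load_atoms(path)
    if isinstance(atoms, struc.AtomArray):
        atoms = struc.stack([atoms])
    atoms, chain = _select_chain(atoms, chain)
    ca = atoms[..., atoms.atom_name == "CA"]
    coords = np.asarray(ca.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    return Ensemble(coords=coords, aligned=False)


def _structure_to_atom_array(structure: Structure, bfactors=None) -> struc.AtomArray:
    names, elements, coords, res_ids, res_names = [], [], [], [], []
    one_to_three = {}
    for i, aa in enumerate(structure.sequence):
        try:
            res3 = ProteinSequence.convert_letter_1to3(aa).upper()
        except Exception:
            res3 = "UNK"
        one_to_three[i] = res3
    for i in range(structure.n_residues):
        rid = structure.residue_numbers[i]
        if structure.n_coords is not None:
            names.append("N"), elements.append("N")
            coords.append(structure.n_coords[i])
            res_ids.append(rid), res_names.append(one_to_three[i])
        names.append("CA"), elements.append("C")
        coords.append(structure.ca_coords[i])
        res_ids.append(rid), res_names.append(one_to_three[i])
        if structure.c_coords is not None:
            names.append("C"), elements.append("C")
            coords.append(structure.c_coords[i])
            res_ids.append(rid), res_names.append(one_to_three[i])
    n_atoms = len(names)
    arr = struc.AtomArray(n_atoms)
    arr.coord = np.array(coords, dtype=float)
    arr.chain_id = np.full(n_atoms, structure.chain_id)
    arr.res_id = np.array(res_ids, dtype=int)
    arr.res_name = np.array(res_names)
    arr.atom_name = np.array(names)
    arr.element = np.array(elements)
    arr.hetero = np.zeros(n_atoms, dtype=bool)
    arr.set_annotation("b_factor", np.zeros(n_atoms, dtype=float))
    arr.set_annotation("occupancy", np.ones(n_atoms, dtype=float))
    if bfactors is not None:
        b = np.asarray(bfactors, dtype=float)
        if b.shape != (structure.n_residues,):
            raise ValueError("bfactors must have one value per residue")
        atoms_per_res = 1 + (structure.n_coords is not None) + (structure.c_coords is not None)
        arr.b_factor = np.repeat(b, atoms_per_res)
    return arr


def write_structure(structure: Structure, path, bfactors=None) -> None:
    """Write a Structure (N, CA, C atoms when present) to a PDB file.

    If ``bfactors`` is given (one scalar per residue, e.g. an RMSF profile)
    it is written into the B-factor column of every atom of that residue.
    """
    arr = _structure_to_atom_array(structure, bfactors=bfactors)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def write_ensemble(
    ensemble: Ensemble,
    template: Structure,
    path,
    bfactors=None,
) -> None:
    """Write an ensemble as a multi-model PDB file (Cα trace per MODEL).

    The template supplies sequence and residue numbering. Coordinates round
    trip through :func:`read_ensemble` at PDB precision (3 decimals, so
    1e-3 Å). Per-residue scalars (e.g. RMSF) can be stored in the B-factor
    column via ``bfactors``.
    """
    if ensemble.n_residues != template.n_residues:
        raise ValueError(
            f"ensemble has {ensemble.n_residues} residues but template has "
            f"{template.n_residues}"
        )
    n = template.n_residues
    res3 = []
    for aa in template.sequence:
        try:
            res3.append(ProteinSequence.convert_letter_1to3(aa).upper())
        except Exception:
            res3.append("UNK")
    arr = struc.AtomArray(n)
    arr.chain_id = np.full(n, template.chain_id)
    arr.res_id = np.array(template.residue_numbers, dtype=int)
    arr.res_name = np.array(res3)
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.hetero = np.zeros(n, dtype=bool)
    b = np.zeros(n) if bfactors is None else np.asarray(bfactors, dtype=float)
    if b.shape != (n,):
        raise ValueError("bfactors must have one value per residue")
    arr.set_annotation("b_factor", b)
    arr.set_annotation("occupancy", np.ones(n, dtype=float))
    frames = []
    for t in range(ensemble.n_frames):
        a = arr.copy()
        a.coord = ensemble.coords[t]
        frames.append(a)
    stack = struc.stack(frames)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_bfactors(path, chain: str | None = None) -> np.ndarray:
    """Read the per-residue Cα B-factor column of (the first model of) a PDB."""
    atoms = _load_atoms(path)
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(altloc="occupancy", extra_fields=["b_factor"])
    if isinstance(atoms, struc.AtomArrayStack):
        atoms = atoms[0]
    atoms, chain = _select_chain(atoms, chain)
    ca = atoms[atoms.atom_name == "CA"]
    return np.asarray(ca.b_factor, dtype=float)


def frames_from_backbone(structure: Structure, tol: float = 1e-6) -> ResidueFrameSet:
    """Build per-residue rigid frames by Gram–Schmidt on the backbone.

    ``t_i`` is the Cα coordinate. ``R_i``'s columns are: the unit Cα→C
    vector; the component of Cα→N orthogonal to it, normalized; and their
    cross product (right-handed). For Cα-only structures the rotations fall
    back to the identity with a warning — downstream covariance predictions
    then lose rotation equivariance.
    """
    n = structure.n_residues
    t = structure.ca_coords.copy()
    if not structure.has_backbone():
        warnings.warn(
            "structure has no backbone N/C atoms; residue frames fall back to "
            "identity rotations and predictions lose rotation equivariance",
            stacklevel=2,
        )
        return ResidueFrameSet(rotations=np.tile(np.eye(3), (n, 1, 1)), translations=t)
    R = np.empty((n, 3, 3), dtype=float)
    for i in range(n):
        v1 = structure.c_coords[i] - t[i]
        v2 = structure.n_coords[i] - t[i]
        n1 = np.linalg.norm(v1)
        if n1 < tol:
            raise ValueError(f"degenerate backbone at residue index {i}: |C-CA| ~ 0")
        e1 = v1 / n1
        u2 = v2 - (v2 @ e1) * e1
        n2 = np.linalg.norm(u2)
        if n2 < tol:
            raise ValueError(
                f"degenerate backbone at residue index {i}: N, CA, C collinear"
            )
        e2 = u2 / n2
        e3 = np.cross(e1, e2)
        R[i] = np.stack([e1, e2, e3], axis=1)
    return ResidueFrameSet(rotations=R, translations=t)
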