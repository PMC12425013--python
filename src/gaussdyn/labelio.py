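"""HDF5 container for dynamics labels and predictions.

Layout (per group; the root is used when there is a single label set):

* ``marginals`` — (N, 3, 3) per-residue covariances, Å²
* ``coupling``  — (N, N) scalar coupling, Å²
* ``correlation`` — (N, N) unit-diagonal standardization (optional)
* ``rmsf``      — (N,) Å
* ``mean``      — (N, 3) Å
* ``joint``     — (3N, 3N) optional

Datasets may be absent (e.g. a marginal-only prediction has no coupling).
Synthetic datasets store two groups, ``clean`` (generator ground truth) and
``empirical`` (re-extracted from the sampled ensemble).
"""

from __future__ import annotations

import numpy as np
import h5py

__all__ = ["save_labels", "load_labels", "LABEL_KEYS"]

LABEL_KEYS = ("marginals", "coupling", "correlation", "rmsf", "mean", "joint")


def _write_group(grp, data: dict):
    for key in LABEL_KEYS:
        val = data.get(key)
        if val is not None:
            # track_times=False keeps files byte-identical across re-runs
            grp.create_dataset(key, data=np.asarray(val, dtype=float),
                               track_times=False)


def save_labels(path, root: dict | None = None, **groups) -> None:
    """Write label arrays to HDF5.

    ``save_labels(path, root={...})`` writes one label set at the file root;
    ``save_labels(path, clean={...}, empirical={...})`` writes named groups.
    """
    with h5py.File(path, "w") as fh:
        if root is not None:
            _write_group(fh, root)
        for name, data in groups.items():
            if data is None:
                continue
            _write_group(fh.create_group(name), data)


def _read_group(grp) -> dict:
    return {key: np.asarray(grp[key]) for key in LABEL_KEYS if key in grp}


def load_labels(path, group: str | None = None) -> dict:
    """Read one label set; ``group=None`` reads the root datasets, falling
    back to the ``empirical`` group if the root holds only groups."""
    with h5py.File(path, "r") as fh:
        if group is not None:
            if group not in fh:
                raise KeyError(
                    f"group {group!r} not in {path}; available: {list(fh.keys())}"
                )
            return _read_group(fh[group])
        root = _read_group(fh)
        if root:
            return root
        if "empirical" in fh:
            return _read_group(fh["empirical"])
        raise KeyError(f"no label datasets found at the root of {path}")
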