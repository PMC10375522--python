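"""Dataset container and file I/O.

An :class:`AnisoDataset` bundles the isotropic and anisotropic
difference-scattering matrices with per-point uncertainties on a shared
(q, t) grid. On disk it is an HDF5 container with datasets
/q, /t, /dS0, /dS2, /err0, /err2 and a ``solvent`` attribute.
Single curves travel as two-column plain text (q, value) with ``#``
header comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .scattering import ScatteringCurve

__all__ = [
    "AnisoDataset",
    "write_dataset",
    "read_dataset",
    "write_curve_text",
    "read_curve_text",
    "export_timepoint_text",
]

_DATASETS = ("q", "t", "dS0", "dS2", "err0", "err2")


@dataclass
class AnisoDataset:
    """Paired dS0(q, t) and dS2(q, t) matrices with uncertainties.

    Matrices are (nt, nq); uncertainties must be strictly positive.
    """

    q: np.ndarray
    t: np.ndarray
    dS0: np.ndarray
    dS2: np.ndarray
    err0: np.ndarray
    err2: np.ndarray
    solvent: str = ""
    truth: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        shape = (len(self.t), len(self.q))
        for name in ("dS0", "dS2", "err0", "err2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if np.any(self.err0 <= 0) or np.any(self.err2 <= 0):
            raise ValueError("uncertainties must be strictly positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    @property
    def n_timepoints(self) -> int:
        return len(self.t)


def write_dataset(dataset: AnisoDataset, path) -> None:
    with h5py.File(path, "w") as fh:
        for name in _DATASETS:
            fh.create_dataset(name, data=getattr(dataset, name))
        fh.attrs["solvent"] = dataset.solvent
        if dataset.truth is not None:
            fh.create_dataset("truth", data=dataset.truth)


def read_dataset(path) -> AnisoDataset:
    with h5py.File(path, "r") as fh:
        data = {}
        for name in _DATASETS:
            if name not in fh:
                raise KeyError(
                    f"malformed dataset file {path!s}: missing /{name}"
                )
            data[name] = fh[name][()]
        solvent = fh.attrs.get("solvent", "")
        truth = fh["truth"][()] if "truth" in fh else None
    return AnisoDataset(**data, solvent=str(solvent), truth=truth)


def write_curve_text(curve: ScatteringCurve, path, header: str = "") -> None:
    """Two-column (q, value) text export; units A^-1 and e.u./molecule."""
    lines = ["# q (1/A)    value (e.u./molecule)"]
    if header:
        lines = [f"# {line}" for line in header.splitlines()] + lines
    np.savetxt(path, np.column_stack([curve.q, curve.values]),
               header="\n".join(line.lstrip("# ") for line in lines))


def read_curve_text(path) -> ScatteringCurve:
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"{path!s} is not a two-column curve file")
    return ScatteringCurve(arr[:, 0], arr[:, 1])


def export_timepoint_text(dataset: AnisoDataset, index: int, path) -> None:
    """Export one timepoint's dS0 as a two-column text file."""
    curve = ScatteringCurve(dataset.q, dataset.dS0[index])
    write_curve_text(
        curve, path, header=f"solvent={dataset.solvent} t={dataset.t[index]} ps"
    )
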