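"""ROI time-series extraction and functional-connectivity matrices.

Per subject: mean series within each spherical ROI (voxel-center membership),
Pearson correlation across all ROI pairs, Fisher z (atanh) transform, and
the cohort-mean matrix. Matrix rows/columns follow the RoiSet order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alff import roi_membership
from .io import BoldRun, RoiSet

__all__ = [
    "ConnMatrix",
    "extract_roi_series",
    "pearson_conn_matrix",
    "fisher_z_transform",
    "cohort_mean_matrix",
]


@dataclass
class ConnMatrix:
    """R×R inter-ROI matrix, either Pearson r or Fisher z."""

    values: np.ndarray
    kind: str  # pearson | fisher_z
    roi_order: RoiSet | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.kind not in ("pearson", "fisher_z"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if self.kind == "pearson":
            if not np.allclose(np.diag(v), 1.0, atol=1e-10):
                raise ValueError("pearson matrix must have unit diagonal")
            off = v[~np.eye(len(v), dtype=bool)]
            if off.size and (off.min() < -1 - 1e-10 or off.max() > 1 + 1e-10):
                raise ValueError("pearson values outside [-1, 1]")
        else:
            if not np.allclose(np.diag(v), 0.0, atol=1e-10):
                raise ValueError("fisher_z matrix diagonal must be 0 by convention")


def extract_roi_series(
    run: BoldRun, rois: RoiSet, members: list[np.ndarray] | None = None
) -> np.ndarray:
    """R×T matrix of sphere-mean time series.

    A voxel belongs to an ROI iff its mm center lies within the ROI radius
    of the ROI center; an ROI with no member voxels is an error. Precomputed
    membership masks may be passed to amortize geometry across subjects.
    """
    if members is None:
        members = roi_membership(run.shape3d, run.affine, rois)
    out = np.empty((len(rois), run.n_timepoints))
    for j, m in enumerate(members):
        out[j] = run.data[m].mean(axis=0)
    return out


def pearson_conn_matrix(series: np.ndarray, rois: RoiSet | None = None) -> ConnMatrix:
    """Pearson correlation across all row pairs of an R×T series matrix."""
    series = np.asarray(series, dtype=np.float64)
    sd = series.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        names = [rois.labels[j] for j in bad] if rois is not None else bad.tolist()
        raise ValueError(f"zero-variance ROI series: {names}")
    r = np.corrcoef(series)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return ConnMatrix(values=r, kind="pearson", roi_order=rois)


def fisher_z_transform(m: ConnMatrix) -> ConnMatrix:
    """Elementwise atanh off-diagonal; diagonal set to 0 by convention."""
    if m.kind != "pearson":
        raise ValueError("fisher_z_transform expects a pearson matrix")
    off = ~np.eye(len(m.values), dtype=bool)
    if np.any(np.abs(m.values[off]) >= 1.0):
        i, j = np.unravel_index(
            np.argmax(np.abs(np.where(off, m.values, 0.0))), m.values.shape
        )
        raise ValueError(f"degenerate pair with |r| = 1 at ({i}, {j})")
    z = np.zeros_like(m.values)
    z[off] = np.arctanh(m.values[off])
    return ConnMatrix(values=z, kind="fisher_z", roi_order=m.roi_order)


def cohort_mean_matrix(matrices: list[ConnMatrix]) -> ConnMatrix:
    """Elementwise mean across subjects; all inputs must share kind and order."""
    if not matrices:
        raise ValueError("no matrices given")
    kinds = {m.kind for m in matrices}
    if len(kinds) > 1:
        raise ValueError(f"mixed matrix kinds: {sorted(kinds)}")
    shapes = {m.values.shape for m in matrices}
    if len(shapes) > 1:
        raise ValueError(f"mixed matrix shapes: {sorted(shapes)}")
    mean = np.mean([m.values for m in matrices], axis=0)
    return ConnMatrix(values=mean, kind=matrices[0].kind, roi_order=matrices[0].roi_order)
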