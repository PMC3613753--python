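"""Data model and standard-format I/O.

Volumes travel as NIfTI-1 files (via nibabel); ROI tables as TSV; analysis
configuration as a flat YAML document; graph exports as BrainNet-style
plain-text ``.node`` / ``.edge`` files.

Conventions
-----------
* Voxel↔mm mapping: the NIfTI affine applied to 0-based voxel indices.
  All ROI geometry is computed in millimetres.
* Masks are aligned to a run by grid shape only; grids that differ in shape
  are an error (no resampling — inputs are assumed to share a common space).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DEFAULT_ROI_RADIUS_MM = 8.0

__all__ = [
    "BoldRun",
    "MaskVolume",
    "RoiSet",
    "AnalysisConfig",
    "read_volume",
    "write_volume",
    "read_roi_table",
    "write_roi_table",
    "read_motion_params",
    "export_edge_files",
    "load_config",
    "save_config",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class BoldRun:
    """One subject's 4D BOLD acquisition.

    Parameters
    ----------
    data:
        X×Y×Z×T array of BOLD intensities (arbitrary units).
    tr:
        Repetition time in seconds (sampling interval of the series).
    affine:
        4×4 voxel-index → mm map (applied to 0-based indices).
    subject_id:
        Free-form identifier.
    """

    data: np.ndarray
    tr: float
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BoldRun data must be 4D, got shape {self.data.shape}")
        if self.n_timepoints < 8:
            raise ValueError(f"BoldRun needs T >= 8, got T={self.n_timepoints}")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BoldRun data contains non-finite values")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr)

    def with_data(self, data: np.ndarray) -> "BoldRun":
        return replace(self, data=data)


@dataclass
class MaskVolume:
    """3D boolean mask aligned (by shape) to a run.

    ``kind`` distinguishes whole-brain masks from the white-matter and CSF
    compartments used for nuisance component extraction.
    """

    data: np.ndarray
    kind: str = "brain"
    affine: np.ndarray | None = None

    VALID_KINDS = ("brain", "wm", "csf")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"MaskVolume data must be 3D, got shape {self.data.shape}")
        if self.kind not in self.VALID_KINDS:
            raise ValueError(f"kind must be one of {self.VALID_KINDS}, got {self.kind!r}")
        if self.affine is not None:
            self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_aligned(self, run: "BoldRun") -> None:
        if self.data.shape != run.shape3d:
            raise ValueError(
                f"mask grid {self.data.shape} does not match run grid {run.shape3d}"
            )


@dataclass
class RoiSet:
    """Ordered set of spherical ROIs in mm (MNI-style) coordinates.

    Row order is canonical: every downstream matrix indexes rows/columns in
    this order.
    """

    labels: list[str]
    networks: list[str]
    centers: np.ndarray  # R×3, mm
    radii: np.ndarray  # R, mm

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.networks = list(self.networks)
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=np.float64))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=np.float64))
        n = len(self.labels)
        if len(set(self.labels)) != n:
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate ROI labels: {dupes}")
        if len(self.networks) != n or self.centers.shape != (n, 3) or self.radii.shape != (n,):
            raise ValueError("inconsistent RoiSet field lengths")
        if np.any(self.radii <= 0):
            raise ValueError("ROI radii must be positive")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class AnalysisConfig:
    """All tunable parameters of the pipeline, with study defaults.

    Defaults reproduce the reference analysis: 0.01–0.08 Hz band, 8 mm FWHM
    smoothing, 5 tissue principal components per compartment, tissue
    probability cut 0.99, 2 discarded volumes, 20 ICA components, voxel-wise
    two-tailed alpha 0.001, hub rule "more than 30" significant couplings,
    familywise cluster alpha 0.05.
    """

    band: tuple[float, float] = (0.01, 0.08)
    smooth_fwhm: float = 8.0
    n_nuisance_pcs: int = 5
    tissue_prob_threshold: float = 0.99
    n_discard: int = 2
    n_components: int = 20
    alpha_voxel: float = 0.001
    hub_min_connections: int = 30
    cluster_fw_alpha: float = 0.05
    seed: int = 0
    # opt-in variants, all off by default to match the reference analysis
    fractional_alff: bool = False
    global_signal_regression: bool = False
    bandpass_before_connectivity: bool = False

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 <= low < high):
            raise ValueError(f"band must satisfy 0 <= low < high, got {self.band}")
        if self.n_nuisance_pcs < 0:
            raise ValueError("n_nuisance_pcs must be >= 0")
        if self.hub_min_connections < 0:
            raise ValueError("hub_min_connections must be >= 0")
        for name in ("alpha_voxel", "cluster_fw_alpha"):
            a = getattr(self, name)
            if not (0 < a < 1):
                raise ValueError(f"{name} must be in (0, 1), got {a}")

    def validate_band(self, tr: float) -> None:
        nyq = 1.0 / (2.0 * tr)
        if self.band[1] > nyq:
            raise ValueError(
                f"band upper edge {self.band[1]} Hz exceeds Nyquist {nyq} Hz for tr={tr}"
            )


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------


def read_volume(path: str | Path, kind: str | None = None):
    """Read a NIfTI-1 file into a :class:`BoldRun` (4D) or :class:`MaskVolume` (3D).

    A 3D volume is converted to a boolean mask via a nonzero test; ``kind``
    selects the mask role (default ``brain``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several unrelated types
        raise ValueError(f"{path} is not readable as NIfTI-1: {exc}") from exc
    if data.ndim == 4:
        if kind is not None:
            raise ValueError(f"{path} is 4D; a mask (3D) was requested")
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        return BoldRun(
            data=data, tr=tr, affine=img.affine, subject_id=path.stem.replace(".nii", "")
        )
    if data.ndim == 3:
        return MaskVolume(data=data != 0, kind=kind or "brain", affine=img.affine)
    raise ValueError(f"{path}: expected a 3D or 4D volume, got ndim={data.ndim}")


def write_volume(obj, path: str | Path, affine: np.ndarray | None = None) -> None:
    """Write a run, mask, or statistic map to NIfTI-1.

    Accepts :class:`BoldRun`, :class:`MaskVolume`, objects with ``.data``
    and ``.affine``-like attributes (e.g. ALFF maps), or a bare ndarray with
    an explicit ``affine``. NaNs are permitted (masked-out voxels).
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"directory {path.parent} does not exist")
    if isinstance(obj, BoldRun):
        img = nib.Nifti1Image(obj.data.astype(np.float64), obj.affine)
        zooms = list(img.header.get_zooms())
        zooms[3] = obj.tr
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
    elif isinstance(obj, MaskVolume):
        aff = obj.affine if obj.affine is not None else np.eye(4)
        img = nib.Nifti1Image(obj.data.astype(np.uint8), aff)
    elif hasattr(obj, "data"):
        aff = affine if affine is not None else getattr(obj, "affine", None)
        if aff is None:
            raise ValueError("no affine available for volume export")
        img = nib.Nifti1Image(np.asarray(obj.data, dtype=np.float64), aff)
    else:
        if affine is None:
            raise ValueError("writing a bare array requires an explicit affine")
        img = nib.Nifti1Image(np.asarray(obj, dtype=np.float64), affine)
    nib.save(img, str(path))


def read_motion_params(path: str | Path) -> np.ndarray:
    """Read a plain-text 6-column (T×6) rigid-body motion parameter file."""
    arr = np.loadtxt(str(path))
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"{path}: expected T×6 motion parameters, got shape {arr.shape}")
    return arr


# ---------------------------------------------------------------------------
# ROI tables
# ---------------------------------------------------------------------------


def read_roi_table(path: str | Path) -> RoiSet:
    """Read a TSV ROI table: columns label, network, x, y, z [, radius].

    Rows are kept in file order (the canonical matrix order). Missing radius
    defaults to 8 mm.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"{path}: ROI table has no data rows")
    required = {"label", "network", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    try:
        centers = df[["x", "y", "z"]].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric coordinates: {exc}") from exc
    if "radius" in df.columns:
        radii = df["radius"].fillna(DEFAULT_ROI_RADIUS_MM).astype(float).to_numpy()
    else:
        radii = np.full(len(df), DEFAULT_ROI_RADIUS_MM)
    return RoiSet(
        labels=[str(x) for x in df["label"]],
        networks=[str(x) for x in df["network"]],
        centers=centers,
        radii=radii,
    )


def write_roi_table(rois: RoiSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "label": rois.labels,
            "network": rois.networks,
            "x": rois.centers[:, 0],
            "y": rois.centers[:, 1],
            "z": rois.centers[:, 2],
            "radius": rois.radii,
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Graph export (BrainNet-style node/edge text files)
# ---------------------------------------------------------------------------


def export_edge_files(coupling, rois: RoiSet, path_prefix: str | Path) -> None:
    """Write ``<prefix>.node`` and ``<prefix>.edge`` files for graph viewers.

    ``coupling`` is either an R×R signed thresholded matrix or an object
    exposing ``significant`` (the matrix) and optionally ``hub_flags``.
    The node file rows are: x y z network-code hub-flag label; the edge file
    is the space-separated signed matrix.
    """
    matrix = np.asarray(getattr(coupling, "significant", coupling), dtype=float)
    if matrix.shape != (len(rois), len(rois)):
        raise ValueError(
            f"coupling matrix shape {matrix.shape} does not match {len(rois)} ROIs"
        )
    hub_flags = getattr(coupling, "hub_flags", None)
    if hub_flags is None:
        hub_flags = np.zeros(len(rois), dtype=int)
    net_codes = {name: i + 1 for i, name in enumerate(dict.fromkeys(rois.networks))}
    prefix = Path(path_prefix)
    with open(f"{prefix}.node", "w") as fh:
        for i in range(len(rois)):
            x, y, z = rois.centers[i]
            fh.write(
                f"{x:g} {y:g} {z:g} {net_codes[rois.networks[i]]} "
                f"{int(hub_flags[i])} {rois.labels[i]}\n"
            )
    with open(f"{prefix}.edge", "w") as fh:
        for row in matrix:
            fh.write(" ".join(f"{v:g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Configuration files
# ---------------------------------------------------------------------------


def load_config(path: str | Path | None = None, **overrides) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a YAML file plus keyword overrides.

    Overrides (e.g. CLI flags) win over file values; unknown keys are an error.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in fields(AnalysisConfig)}
    unknown = set(values) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "band" in values:
        values["band"] = tuple(float(v) for v in values["band"])
    return AnalysisConfig(**values)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    doc = {f.name: getattr(config, f.name) for f in fields(AnalysisConfig)}
    doc["band"] = list(doc["band"])
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
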