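"""Preprocessing: volume discarding, nuisance regression, spatial smoothing.

The recipe, in order: discard initial volumes; regress out the six rigid-body
motion parameters plus the leading principal components of the white-matter
and CSF compartment signals (5 + 5 by default); smooth with a Gaussian
kernel (8 mm FWHM by default, reflective boundaries). Tissue components are
extracted from the post-discard, pre-regression data — they are regressors,
so they must exist before the regression that uses them. No global-signal
regression and no temporal filtering are applied by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .io import AnalysisConfig, BoldRun, MaskVolume

logger = logging.getLogger(__name__)

__all__ = [
    "NuisanceDesign",
    "drop_initial_volumes",
    "compute_tissue_pcs",
    "build_nuisance_design",
    "nuisance_regress",
    "smooth_gaussian",
    "bandpass_filter",
    "preprocess_run",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class NuisanceDesign:
    """T×C confound design matrix with named columns (intercept included)."""

    columns: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=np.float64)
        if self.columns.ndim != 2:
            raise ValueError("design must be a T×C matrix")
        t, c = self.columns.shape
        if len(self.labels) != c:
            raise ValueError("one label per design column required")
        if c >= t:
            raise ValueError(f"design has {c} columns for only {t} time points")
        nonintercept = [
            i for i, lab in enumerate(self.labels) if lab != "intercept"
        ]
        zero = [
            self.labels[i]
            for i in nonintercept
            if np.allclose(self.columns[:, i], 0)
        ]
        if zero:
            raise ValueError(f"all-zero design columns: {zero}")

    @property
    def n_timepoints(self) -> int:
        return self.columns.shape[0]


def drop_initial_volumes(run: BoldRun, n: int) -> BoldRun:
    """Discard the first ``n`` frames (signal-equilibration volumes)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= run.n_timepoints:
        raise ValueError(
            f"cannot drop {n} of {run.n_timepoints} volumes"
        )
    if n == 0:
        return run
    return run.with_data(run.data[..., n:])


def compute_tissue_pcs(run: BoldRun, mask: MaskVolume, n_pcs: int) -> np.ndarray:
    """Leading temporal principal components of a tissue compartment.

    Per-voxel means are removed, then the voxel×time matrix is decomposed by
    SVD; the returned T×n columns are the orthonormal time-domain singular
    vectors ordered by decreasing singular value. If the compartment's rank
    is below ``n_pcs`` the available components are returned with a warning.
    """
    mask.check_aligned(run)
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    if mask.n_voxels < n_pcs:
        raise ValueError(
            f"{mask.kind} mask has {mask.n_voxels} voxels < n_pcs={n_pcs}"
        )
    series = run.data[mask.data]  # voxels × T
    series = series - series.mean(axis=1, keepdims=True)
    if np.allclose(series, 0):
        raise ValueError(f"{mask.kind} compartment has zero variance")
    _, s, vt = np.linalg.svd(series, full_matrices=False)
    tol = s[0] * max(series.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if rank < n_pcs:
        logger.warning(
            "%s compartment rank %d < requested %d components; returning %d",
            mask.kind,
            rank,
            n_pcs,
            rank,
        )
        n_pcs = rank
    return vt[:n_pcs].T  # T × n_pcs, orthonormal


def build_nuisance_design(
    motion: np.ndarray,
    tissue_pcs: list[np.ndarray] | None = None,
    tissue_names: list[str] | None = None,
) -> NuisanceDesign:
    """Assemble [motion | tissue PCs | intercept] into a NuisanceDesign."""
    motion = np.asarray(motion, dtype=np.float64)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be T×6, got {motion.shape}")
    cols = [motion]
    labels = [f"motion_{i + 1}" for i in range(6)]
    tissue_pcs = tissue_pcs or []
    tissue_names = tissue_names or [f"tissue{i}" for i in range(len(tissue_pcs))]
    for name, pcs in zip(tissue_names, tissue_pcs):
        if pcs.shape[0] != motion.shape[0]:
            raise ValueError(f"{name} PCs have {pcs.shape[0]} rows, motion {motion.shape[0]}")
        cols.append(pcs)
        labels.extend(f"{name}_pc{i + 1}" for i in range(pcs.shape[1]))
    cols.append(np.ones((motion.shape[0], 1)))
    labels.append("intercept")
    return NuisanceDesign(columns=np.hstack(cols), labels=labels)


def _check_full_rank(design: NuisanceDesign) -> None:
    x = design.columns
    rank = np.linalg.matrix_rank(x)
    if rank == x.shape[1]:
        return
    # identify offending columns: those whose removal restores the rank
    offenders = []
    for i in range(x.shape[1]):
        reduced = np.delete(x, i, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            offenders.append(design.labels[i])
    raise ValueError(
        f"rank-deficient nuisance design (rank {rank} < {x.shape[1]}); "
        f"collinear columns involve: {offenders}"
    )


def nuisance_regress(run: BoldRun, design: NuisanceDesign) -> BoldRun:
    """Replace every voxel series by its least-squares residual to the design.

    The intercept column makes residuals mean-free; residuals are orthogonal
    to every design column to numerical precision.
    """
    if design.n_timepoints != run.n_timepoints:
        raise ValueError(
            f"design rows {design.n_timepoints} != run frames {run.n_timepoints}"
        )
    _check_full_rank(design)
    x = design.columns
    y = run.data.reshape(-1, run.n_timepoints).T  # T × V
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return run.with_data(resid.T.reshape(run.data.shape))


def smooth_gaussian(data, fwhm: float, voxel_size) -> np.ndarray:
    """3D Gaussian smoothing, sigma = FWHM/(2√(2 ln 2)) per axis in mm.

    Accepts a 3D map, a 4D run array (smoothed volume by volume), or a
    BoldRun (returns a BoldRun). Reflective boundary handling.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if isinstance(data, BoldRun):
        return data.with_data(smooth_gaussian(data.data, fwhm, voxel_size))
    arr = np.asarray(data, dtype=np.float64)
    if fwhm == 0:
        return arr.copy()
    voxel_size = np.asarray(voxel_size, dtype=np.float64)
    sigma_vox = (fwhm * FWHM_TO_SIGMA) / voxel_size
    if arr.ndim == 3:
        return ndimage.gaussian_filter(arr, sigma=sigma_vox, mode="reflect")
    if arr.ndim == 4:
        out = np.empty_like(arr)
        for t in range(arr.shape[3]):
            out[..., t] = ndimage.gaussian_filter(
                arr[..., t], sigma=sigma_vox, mode="reflect"
            )
        return out
    raise ValueError(f"expected 3D or 4D data, got ndim={arr.ndim}")


def bandpass_filter(run: BoldRun, band: tuple[float, float]) -> BoldRun:
    """Zero-phase Butterworth band-pass of every voxel series (opt-in).

    Not part of the default recipe; available for analyses that want
    connectivity restricted to the fluctuation band.
    """
    low, high = band
    nyq = run.nyquist
    if not (0 < low < high < nyq):
        raise ValueError(f"band {band} must lie strictly inside (0, {nyq})")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=1.0 / run.tr, output="sos")
    flat = run.data.reshape(-1, run.n_timepoints)
    filtered = signal.sosfiltfilt(sos, flat, axis=1)
    return run.with_data(filtered.reshape(run.data.shape))


def preprocess_run(
    run: BoldRun,
    motion: np.ndarray,
    wm_mask: MaskVolume,
    csf_mask: MaskVolume,
    config: AnalysisConfig,
    voxel_size=None,
    brain_mask: MaskVolume | None = None,
) -> tuple[BoldRun, NuisanceDesign]:
    """Full preprocessing of one subject: discard → regress → smooth.

    With ``config.global_signal_regression`` (opt-in, off by default) the
    in-brain mean series joins the design; ``brain_mask`` is then required.
    Returns the cleaned run and the nuisance design used (for audit export).
    """
    run = drop_initial_volumes(run, config.n_discard)
    motion = np.asarray(motion, dtype=np.float64)
    if motion.shape[0] == run.n_timepoints + config.n_discard:
        motion = motion[config.n_discard :]
    if motion.shape[0] != run.n_timepoints:
        raise ValueError(
            f"motion rows {motion.shape[0]} do not match {run.n_timepoints} frames"
        )
    tissue_pcs, tissue_names = [], []
    if config.n_nuisance_pcs > 0:
        for name, mask in (("wm", wm_mask), ("csf", csf_mask)):
            tissue_pcs.append(compute_tissue_pcs(run, mask, config.n_nuisance_pcs))
            tissue_names.append(name)
    if config.global_signal_regression:
        if brain_mask is None:
            raise ValueError("global_signal_regression requires a brain mask")
        brain_mask.check_aligned(run)
        gs = run.data[brain_mask.data].mean(axis=0)
        gs = gs - gs.mean()
        tissue_pcs.append(gs[:, None] / max(np.linalg.norm(gs), 1e-12))
        tissue_names.append("global")
    design = build_nuisance_design(motion, tissue_pcs, tissue_names)
    run = nuisance_regress(run, design)
    if voxel_size is None:
        voxel_size = np.abs(np.diag(run.affine)[:3])
    run = smooth_gaussian(run, config.smooth_fwhm, voxel_size)
    return run, design
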