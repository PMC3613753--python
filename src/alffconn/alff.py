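"""Amplitude of low-frequency fluctuations (ALFF).

Per voxel, the linearly detrended series is Fourier-transformed and the
one-sided spectral amplitude ``2·|DFT|/T`` is averaged over the frequency
bins inside the analysis band (0.01–0.08 Hz by default; closed interval).
With this scaling a pure sinusoid of amplitude A contributes an in-bin
amplitude of A. Maps are normalized by the whole-brain in-mask mean, so the
fixed spectral scale cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .io import BoldRun, MaskVolume, RoiSet

__all__ = ["AlffMap", "compute_alff_map", "normalize_alff_global", "roi_mean_alff",
           "roi_membership", "roi_mean_map"]


@dataclass
class AlffMap:
    """Per-voxel nonnegative band-limited amplitude map."""

    data: np.ndarray
    band: tuple[float, float]
    normalized: bool = False
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("AlffMap data must be 3D")
        finite = self.data[np.isfinite(self.data)]
        if finite.size and finite.min() < -1e-12:
            raise ValueError("ALFF values must be nonnegative")


def compute_alff_map(
    run: BoldRun,
    band: tuple[float, float] = (0.01, 0.08),
    fractional: bool = False,
) -> AlffMap:
    """Mean in-band one-sided spectral amplitude per voxel.

    A bin at frequency f is in-band iff low ≤ f ≤ high (DC excluded). The
    series is linearly detrended before the transform. With
    ``fractional=True`` the in-band amplitude sum is divided by the
    full-spectrum amplitude sum (fALFF), an opt-in variant.
    """
    low, high = band
    if not (0 <= low < high):
        raise ValueError(f"invalid band {band}")
    if high > run.nyquist + 1e-12:
        raise ValueError(f"band upper edge {high} Hz exceeds Nyquist {run.nyquist} Hz")
    t = run.n_timepoints
    freqs = np.fft.rfftfreq(t, d=run.tr)
    in_band = (freqs >= low) & (freqs <= high) & (freqs > 0)
    if not np.any(in_band):
        raise ValueError(
            f"no frequency bins inside {band} for T={t}, tr={run.tr}"
        )
    flat = run.data.reshape(-1, t)
    detrended = signal.detrend(flat, axis=1, type="linear")
    spectrum = np.fft.rfft(detrended, axis=1)
    amplitude = 2.0 * np.abs(spectrum) / t
    alff = amplitude[:, in_band].mean(axis=1)
    if fractional:
        total = amplitude[:, freqs > 0].sum(axis=1)
        in_sum = amplitude[:, in_band].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            alff = np.where(total > 0, in_sum / total, 0.0)
    return AlffMap(
        data=alff.reshape(run.shape3d), band=band, normalized=False, affine=run.affine
    )


def normalize_alff_global(amap: AlffMap, brain_mask: MaskVolume) -> AlffMap:
    """Divide in-mask voxels by the in-mask mean; mask-out voxels become NaN.

    Idempotent: normalizing an already unit-mean map leaves it unchanged.
    """
    if brain_mask.data.shape != amap.data.shape:
        raise ValueError("brain mask grid does not match ALFF map grid")
    if brain_mask.n_voxels == 0:
        raise ValueError("empty brain mask")
    mean = float(np.nanmean(amap.data[brain_mask.data]))
    if not mean > 0:
        raise ValueError(f"in-mask mean ALFF must be positive, got {mean}")
    out = np.full_like(amap.data, np.nan)
    out[brain_mask.data] = amap.data[brain_mask.data] / mean
    return replace(amap, data=out, normalized=True)


def roi_membership(
    grid_shape: tuple[int, int, int], affine: np.ndarray, rois: RoiSet
) -> list[np.ndarray]:
    """Boolean membership mask per ROI: voxel centers within radius (mm)."""
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in grid_shape], indexing="ij"), axis=-1
    ).astype(float)
    coords = idx @ affine[:3, :3].T + affine[:3, 3]
    members = []
    for j in range(len(rois)):
        d2 = ((coords - rois.centers[j]) ** 2).sum(axis=-1)
        m = d2 <= rois.radii[j] ** 2
        if not m.any():
            raise ValueError(f"ROI {rois.labels[j]!r} contains no voxel")
        members.append(m)
    return members


def roi_mean_map(data3d: np.ndarray, members: list[np.ndarray]) -> np.ndarray:
    """Mean of a 3D map over each ROI's member voxels (NaN-aware)."""
    return np.array([float(np.nanmean(data3d[m])) for m in members])


def roi_mean_alff(amap: AlffMap, rois: RoiSet, affine: np.ndarray | None = None) -> np.ndarray:
    """Per-ROI sphere-mean of the normalized ALFF map."""
    if not amap.normalized:
        raise ValueError("roi_mean_alff expects a normalized ALFF map")
    aff = affine if affine is not None else amap.affine
    if aff is None:
        raise ValueError("no affine available for ROI geometry")
    members = roi_membership(amap.data.shape, aff, rois)
    values = roi_mean_map(amap.data, members)
    if np.any(np.isnan(values)):
        bad = [rois.labels[j] for j in range(len(rois)) if np.isnan(values[j])]
        raise ValueError(f"ROIs with no in-mask voxels: {bad}")
    return values
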