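"""ALFF×connectivity coupling statistics.

The core inter-subject analyses: analytic critical values for Pearson r and
one-sample t; voxel-matched correlation between subject network-strength
maps and ALFF maps; ROI-wise correlation of a region's ALFF with its
Fisher-z connectivity to every other region (an asymmetric R×R matrix) with
hub identification; and a Monte-Carlo cluster-extent threshold for smoothed
Gaussian null fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .io import MaskVolume, RoiSet
from .preprocess import smooth_gaussian

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelCouplingMap",
    "RoiCouplingMatrix",
    "HubResult",
    "ClusterNull",
    "critical_value",
    "voxel_matched_coupling",
    "roi_alff_coupling",
    "identify_coupling_hubs",
    "cluster_extent_threshold",
]


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class VoxelCouplingMap:
    """Voxel-wise inter-subject correlation of network strength with ALFF."""

    r: np.ndarray  # 3D; NaN where across-subject variance is zero
    n_subjects: int
    threshold_r: float
    significant: np.ndarray = field(init=False)  # signed suprathreshold mask

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        with np.errstate(invalid="ignore"):
            supra = np.abs(self.r) > self.threshold_r
        self.significant = np.where(supra & np.isfinite(self.r), np.sign(self.r), 0.0)

    def sign_rectified(self, group_map: np.ndarray) -> np.ndarray:
        """Coupling with the component's voxel sign folded in.

        A negative correlation of ALFF with a *negative* component value is
        the same phenomenon as a positive correlation with a positive value;
        multiplying r by the sign of the group map at each voxel yields a
        view invariant to the ICA sign indeterminacy.
        """
        g = np.asarray(group_map, dtype=np.float64)
        if g.shape != self.r.shape:
            raise ValueError("group map grid does not match coupling map grid")
        return self.r * np.sign(g)


@dataclass
class RoiCouplingMatrix:
    """Entry (j,k): inter-subject corr of ROI j's ALFF with z-connectivity (j,k).

    Generally asymmetric — the two regions of a pair relate to the shared
    edge through their own amplitudes. Diagonal is set to 0 and excluded
    from counts.
    """

    r: np.ndarray
    n_subjects: int
    threshold_r: float
    roi_order: RoiSet | None = None
    significant: np.ndarray = field(init=False)
    positive_counts: np.ndarray = field(init=False)
    negative_counts: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        np.fill_diagonal(self.r, 0.0)
        with np.errstate(invalid="ignore"):
            supra = np.abs(self.r) > self.threshold_r
        self.significant = np.where(supra & np.isfinite(self.r), np.sign(self.r), 0.0)
        np.fill_diagonal(self.significant, 0.0)
        self.positive_counts = (self.significant > 0).sum(axis=1)
        self.negative_counts = (self.significant < 0).sum(axis=1)

    @property
    def hub_flags(self) -> np.ndarray:
        """1 where any hub criterion could apply; used by graph export."""
        return ((self.positive_counts > 0) | (self.negative_counts > 0)).astype(int)


@dataclass
class HubResult:
    """ROIs whose ALFF couples to more than ``min_connections`` edges."""

    hubs: list  # (label, network, sign, count)
    min_connections: int

    def labels(self, sign: int | None = None) -> list[str]:
        return [h[0] for h in self.hubs if sign is None or h[2] == sign]


@dataclass
class ClusterNull:
    """Null distribution of the largest suprathreshold cluster size."""

    max_sizes: np.ndarray
    voxel_alpha: float
    familywise_alpha: float
    extent_threshold: int
    n_iter: int
    fwhm: float
    seed: int


# ---------------------------------------------------------------------------
# Analytic critical values
# ---------------------------------------------------------------------------


def critical_value(kind: str, n: int, alpha: float) -> float:
    """Two-tailed critical threshold for a given sample size.

    ``one_sample_t``: upper alpha/2 quantile of t with df = n−1.
    ``pearson_r``: the same quantile with df = n−2, mapped through
    r* = t*/√(t*² + df).
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if kind == "one_sample_t":
        if n < 2:
            raise ValueError("one_sample_t needs n >= 2")
        return float(stats.t.ppf(1 - alpha / 2, df=n - 1))
    if kind == "pearson_r":
        if n < 4:
            raise ValueError("pearson_r needs n >= 4")
        df = n - 2
        t_star = stats.t.ppf(1 - alpha / 2, df=df)
        return float(t_star / np.sqrt(t_star**2 + df))
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# Inter-subject correlation helpers
# ---------------------------------------------------------------------------


def _pearson_over_axis0(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation along axis 0 (subjects), NaN where degenerate."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    num = (xc * yc).sum(axis=0)
    den = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r = np.where(den == 0, np.nan, r)
    return np.clip(r, -1.0, 1.0)


def voxel_matched_coupling(
    subject_maps: np.ndarray, alff_maps: np.ndarray, threshold_r: float
) -> VoxelCouplingMap:
    """Correlate, voxel by voxel across subjects, network strength with ALFF.

    Both inputs are N×X×Y×Z stacks on the same grid; voxels with zero
    across-subject variance in either input are NaN.
    """
    s = np.asarray(subject_maps, dtype=np.float64)
    a = np.asarray(alff_maps, dtype=np.float64)
    if s.shape != a.shape:
        raise ValueError(f"shape mismatch: maps {s.shape} vs ALFF {a.shape}")
    n = s.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects")
    r = _pearson_over_axis0(s, a)
    return VoxelCouplingMap(r=r, n_subjects=n, threshold_r=threshold_r)


def roi_alff_coupling(
    z_matrices: np.ndarray,
    roi_alff: np.ndarray,
    threshold_r: float,
    rois: RoiSet | None = None,
) -> RoiCouplingMatrix:
    """Correlate each ROI's ALFF with its Fisher-z edges across subjects.

    ``z_matrices`` is N×R×R, ``roi_alff`` N×R. Entry (j,k), j≠k, is the
    Pearson correlation over subjects of ALFF_j with z_{j,k}. A zero-variance
    ALFF column yields a NaN row (logged).
    """
    z = np.asarray(z_matrices, dtype=np.float64)
    a = np.asarray(roi_alff, dtype=np.float64)
    if z.ndim != 3 or z.shape[1] != z.shape[2]:
        raise ValueError("z_matrices must be N×R×R")
    n, r_count = a.shape if a.ndim == 2 else (0, 0)
    if z.shape[0] != n or z.shape[1] != r_count:
        raise ValueError(
            f"inconsistent shapes: z {z.shape}, alff {a.shape}"
        )
    if n < 4:
        raise ValueError("need at least 4 subjects")
    # broadcast ALFF_j over k: x[i, j, k] = alff[i, j]
    x = np.broadcast_to(a[:, :, None], z.shape)
    rmat = _pearson_over_axis0(x, z)
    dead = np.flatnonzero(a.std(axis=0) == 0)
    if dead.size:
        names = [rois.labels[j] for j in dead] if rois is not None else dead.tolist()
        logger.warning("ROIs with zero across-subject ALFF variance: %s", names)
        rmat[dead, :] = np.nan
    np.fill_diagonal(rmat, 0.0)
    return RoiCouplingMatrix(
        r=rmat, n_subjects=n, threshold_r=threshold_r, roi_order=rois
    )


def identify_coupling_hubs(
    m: RoiCouplingMatrix, min_connections: int
) -> HubResult:
    """ROIs with more than ``min_connections`` significant couplings.

    Positive and negative edges are tallied separately; an ROI can appear in
    both lists. Counts follow the signed thresholded matrix rows.
    """
    hubs = []
    r_count = m.r.shape[0]
    labels = m.roi_order.labels if m.roi_order is not None else [str(j) for j in range(r_count)]
    networks = m.roi_order.networks if m.roi_order is not None else [""] * r_count
    for j in range(r_count):
        if m.positive_counts[j] > min_connections:
            hubs.append((labels[j], networks[j], +1, int(m.positive_counts[j])))
        if m.negative_counts[j] > min_connections:
            hubs.append((labels[j], networks[j], -1, int(m.negative_counts[j])))
    return HubResult(hubs=hubs, min_connections=min_connections)


# ---------------------------------------------------------------------------
# Monte-Carlo cluster-extent threshold
# ---------------------------------------------------------------------------


def cluster_extent_threshold(
    mask: MaskVolume,
    fwhm: float,
    voxel_size,
    voxel_alpha: float,
    familywise_alpha: float,
    n_iter: int = 1000,
    seed: int = 0,
) -> ClusterNull:
    """Null max-cluster-size simulation on smoothed Gaussian fields.

    Each iteration fills the mask's bounding grid with standard normal
    noise, smooths to the nominal FWHM, re-standardizes within the mask,
    thresholds two-tailed at ``voxel_alpha``, and records the largest
    26-connected suprathreshold cluster. The extent threshold is the
    smallest size k with null exceedance probability ≤ ``familywise_alpha``
    (ties resolved conservatively).
    """
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if not (0 < familywise_alpha < 1):
        raise ValueError("familywise_alpha must be in (0, 1)")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    z_crit = stats.norm.ppf(1 - voxel_alpha / 2)
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    inmask = mask.data
    max_sizes = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        field3d = rng.standard_normal(mask.data.shape)
        if fwhm > 0:
            field3d = smooth_gaussian(field3d, fwhm, voxel_size)
        vals = field3d[inmask]
        sd = vals.std()
        if sd == 0:
            continue
        field3d = (field3d - vals.mean()) / sd
        supra = np.zeros(mask.data.shape, dtype=bool)
        supra[inmask] = np.abs(field3d[inmask]) > z_crit
        if not supra.any():
            continue
        labeled, n_clusters = ndimage.label(supra, structure=structure)
        if n_clusters:
            sizes = np.bincount(labeled.ravel())[1:]
            max_sizes[it] = int(sizes.max())
    extent = 1
    while np.mean(max_sizes >= extent) > familywise_alpha:
        extent += 1
    return ClusterNull(
        max_sizes=max_sizes,
        voxel_alpha=voxel_alpha,
        familywise_alpha=familywise_alpha,
        extent_threshold=extent,
        n_iter=n_iter,
        fwhm=fwhm,
        seed=seed,
    )
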