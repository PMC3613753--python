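"""Synthetic multi-subject BOLD cohort generator with planted ground truth.

Emulates a resting-state cohort in a common space: each subject's voxel
series is a sum of band-limited (0.01–0.08 Hz) network signals weighted by
Gaussian spatial maps, broadband private noise, and nuisance structure
(six motion traces correlated with a global artifact, plus white-matter and
CSF compartment signals). Two planting mechanisms control the sign of the
inter-subject coupling between regional fluctuation amplitude and
connectivity:

``shared_signal_gain``
    The per-subject network gain ``a_ik`` is spread across subjects; a high
    gain raises both the regional amplitude and the within-network
    correlations → positive amplitude×connectivity coupling.

``private_noise_gain``
    The private-noise standard deviation inside one ROI is spread across
    subjects; a high gain raises that region's amplitude while diluting its
    correlations to network peers → negative coupling.

All draws are recorded in :class:`SynthTruth` so downstream stages can be
tested by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import BoldRun, MaskVolume, RoiSet, write_roi_table, write_volume

__all__ = [
    "NetworkSpec",
    "CouplingPlant",
    "NuisanceSpec",
    "CohortSpec",
    "SynthTruth",
    "SubjectData",
    "make_bandlimited_timecourse",
    "make_network_maps",
    "generate_cohort",
    "cohort_roi_set",
    "demo_cohort_spec",
    "null_cohort_spec",
    "recovery_cohort_spec",
    "desk_analysis_config",
    "write_cohort",
]

# Acquisition geometry mirrored from the emulated study: TR 2.5 s,
# 3.44×3.44×3.40 mm voxels, 0.01–0.08 Hz fluctuation band.
DEFAULT_TR = 2.5
DEFAULT_VOXEL = (3.44, 3.44, 3.40)
DEFAULT_BAND = (0.01, 0.08)


# ---------------------------------------------------------------------------
# Specs and truth containers
# ---------------------------------------------------------------------------


@dataclass
class NetworkSpec:
    """One planted network: spatial weights, band, and amplitude model."""

    name: str
    spatial_map: np.ndarray  # 3D nonnegative weights, peak 1
    band: tuple[float, float] = DEFAULT_BAND
    base_amplitude: float = 1.0
    amplitude_sd_across_subjects: float = 0.0
    roi_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spatial_map = np.asarray(self.spatial_map, dtype=np.float64)
        if not np.any(self.spatial_map > 0):
            raise ValueError(f"network {self.name!r}: spatial map has no positive voxel")
        if self.amplitude_sd_across_subjects < 0 or self.base_amplitude < 0:
            raise ValueError("amplitudes must be nonnegative")


@dataclass
class CouplingPlant:
    """A planted amplitude×connectivity coupling.

    ``target`` names a network (shared_signal_gain) or an ROI label
    (private_noise_gain). ``effect_r`` sets sign and strength: its absolute
    value scales the relative across-subject spread of the planted gain.
    A private_noise_gain plant models a physiological-noise hotspot: the
    regional noise floor is elevated by ``noise_base_factor`` so the
    subject-varying gain has a detectable footprint in both the regional
    amplitude and the region's correlations.
    """

    target: str
    mechanism: str  # shared_signal_gain | private_noise_gain
    effect_r: float = 0.5
    noise_base_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.mechanism not in ("shared_signal_gain", "private_noise_gain"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if abs(self.effect_r) > 1:
            raise ValueError("|effect_r| must be <= 1")
        if self.noise_base_factor <= 0:
            raise ValueError("noise_base_factor must be positive")


@dataclass
class NuisanceSpec:
    """Amplitudes of the nuisance machinery (signal units; 0 disables)."""

    motion_amp: float = 0.5
    global_artifact_amp: float = 0.3
    wm_amp: float = 1.5
    csf_amp: float = 2.0


@dataclass
class CohortSpec:
    n_subjects: int
    grid: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    t_points: int
    tr: float
    networks: list[NetworkSpec]
    noise_sd: float = 1.0
    coupling: list[CouplingPlant] = field(default_factory=list)
    nuisance: NuisanceSpec = field(default_factory=NuisanceSpec)
    seed: int = 0
    roi_set: RoiSet | None = None
    roi_in_band_noise_sd: float = 0.0  # extra in-band private signal per ROI blob

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need n_subjects >= 3")
        if self.t_points < 32:
            raise ValueError("need t_points >= 32")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SubjectData:
    """One simulated subject: run, motion trace, and tissue masks."""

    run: BoldRun
    motion: np.ndarray  # T×6
    masks: dict  # {'brain','wm','csf'} → MaskVolume


@dataclass
class SynthTruth:
    """Ground truth of a generated cohort, for parameter-recovery tests."""

    amplitudes: np.ndarray  # N×K per-subject network gains a_ik
    network_names: list[str]
    private_gains: dict  # roi label → length-N noise gains
    planted_hubs: list  # (roi label, sign) pairs expected to surface as hubs
    within_network_r: np.ndarray  # N×K predicted per-voxel within-network correlation
    nuisance_timecourses: list  # per subject: dict of named T-series
    motion: list  # per subject: T×6


# ---------------------------------------------------------------------------
# Primitive generators
# ---------------------------------------------------------------------------


def make_bandlimited_timecourse(
    t_points: int,
    tr: float,
    band: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean, unit-variance series with its power confined to ``band``.

    Built in the frequency domain: flat magnitude on the in-band rFFT bins,
    uniform random phases, zero elsewhere, then inverse-transformed. Power
    control is therefore exact up to bin discretisation.
    """
    low, high = band
    nyquist = 1.0 / (2.0 * tr)
    if not (0 <= low < high):
        raise ValueError(f"band must satisfy 0 <= low < high, got {band}")
    if high > nyquist + 1e-12:
        raise ValueError(f"band upper edge {high} Hz exceeds Nyquist {nyquist} Hz")
    freqs = np.fft.rfftfreq(t_points, d=tr)
    in_band = (freqs >= low) & (freqs <= high) & (freqs > 0)
    if not np.any(in_band):
        raise ValueError(f"no frequency bins inside {band} for T={t_points}, tr={tr}")
    spectrum = np.zeros(len(freqs), dtype=complex)
    phases = rng.uniform(0, 2 * np.pi, size=int(in_band.sum()))
    spectrum[in_band] = np.exp(1j * phases)
    series = np.fft.irfft(spectrum, n=t_points)
    series -= series.mean()
    sd = series.std()
    if sd == 0:
        raise ValueError("degenerate band produced a constant series")
    return series / sd


def make_network_maps(
    grid: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    blob_centers,
    blob_fwhm: float,
) -> list[np.ndarray]:
    """Gaussian-blob spatial maps, one per group of centers, peak value 1.

    ``blob_centers`` is a list of maps, each a list of mm centers (a single
    (x, y, z) triple is promoted to a one-blob map). Centers must lie inside
    the grid (grid-centered mm frame, see :func:`grid_affine`).
    """
    affine = grid_affine(grid, voxel_size)
    coords = _voxel_centers_mm(grid, affine)  # X×Y×Z×3
    sigma = blob_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    lo = coords.reshape(-1, 3).min(axis=0) - np.asarray(voxel_size) / 2
    hi = coords.reshape(-1, 3).max(axis=0) + np.asarray(voxel_size) / 2
    maps = []
    for group in blob_centers:
        group_arr = np.atleast_2d(np.asarray(group, dtype=np.float64))
        m = np.zeros(grid)
        for center in group_arr:
            if np.any(center < lo) or np.any(center > hi):
                raise ValueError(f"blob center {center} lies outside the grid")
            d2 = ((coords - center) ** 2).sum(axis=-1)
            m += np.exp(-d2 / (2.0 * sigma**2))
        maps.append(m / m.max())
    return maps


def grid_affine(
    grid: tuple[int, int, int], voxel_size: tuple[float, float, float]
) -> np.ndarray:
    """Diagonal affine placing the mm origin at the grid center."""
    affine = np.eye(4)
    for ax in range(3):
        affine[ax, ax] = voxel_size[ax]
        affine[ax, 3] = -voxel_size[ax] * (grid[ax] - 1) / 2.0
    return affine


def _voxel_centers_mm(grid: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in grid], indexing="ij"), axis=-1
    ).astype(float)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def _smooth_walk(t_points: int, rng: np.random.Generator) -> np.ndarray:
    """Standardized smooth random walk (cumulative sum, lightly low-passed)."""
    steps = rng.standard_normal(t_points)
    walk = np.cumsum(steps)
    kernel = np.ones(5) / 5.0
    walk = np.convolve(walk, kernel, mode="same")
    walk -= walk.mean()
    sd = walk.std()
    return walk / sd if sd > 0 else walk


# ---------------------------------------------------------------------------
# Cohort geometry: compartments and ROI layout
# ---------------------------------------------------------------------------


def _compartment_masks(grid, affine) -> dict:
    """Fixed geometric tissue compartments.

    CSF: ventricle-like central block; WM: one-voxel shell around it;
    brain: an inscribed ellipsoid covering most of the grid.
    """
    nx, ny, nz = grid
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    c = (np.asarray(grid) - 1) / 2.0
    semi = np.asarray(grid) / 2.0
    brain = (
        ((ii - c[0]) / semi[0]) ** 2
        + ((jj - c[1]) / semi[1]) ** 2
        + ((kk - c[2]) / semi[2]) ** 2
    ) <= 1.0
    csf_half = np.maximum(np.asarray(grid) // 8, 1)
    csf = (
        (np.abs(ii - c[0]) <= csf_half[0])
        & (np.abs(jj - c[1]) <= csf_half[1])
        & (np.abs(kk - c[2]) <= csf_half[2])
    )
    wm_half = csf_half + 1
    wm = (
        (np.abs(ii - c[0]) <= wm_half[0])
        & (np.abs(jj - c[1]) <= wm_half[1])
        & (np.abs(kk - c[2]) <= wm_half[2])
        & ~csf
    )
    csf &= brain
    wm &= brain
    return {
        "brain": MaskVolume(brain, "brain", affine),
        "wm": MaskVolume(wm, "wm", affine),
        "csf": MaskVolume(csf, "csf", affine),
    }


def _roi_lattice(grid, voxel_size, n_rois: int, margin_vox: int = 2) -> np.ndarray:
    """Deterministic mm centers for ``n_rois`` blobs in gray matter.

    Centers sit on a jittered lattice inside the brain ellipsoid, excluding
    the central WM/CSF block, spaced to keep 4 mm-radius spheres disjoint.
    """
    affine = grid_affine(grid, voxel_size)
    masks = _compartment_masks(grid, affine)
    gray = masks["brain"].data & ~masks["wm"].data & ~masks["csf"].data
    # erode the gray set away from the grid boundary so blobs fit
    idx = np.argwhere(gray)
    bounds = np.asarray(grid)
    keep = np.all((idx >= margin_vox) & (idx <= bounds - 1 - margin_vox), axis=1)
    idx = idx[keep]
    if len(idx) < n_rois:
        raise ValueError(f"grid too small for {n_rois} ROIs")
    # greedy max-min spacing over candidates, deterministic
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
    cand = idx[order].astype(float)
    chosen = [cand[0]]
    remaining = cand[1:]
    d2 = ((remaining - chosen[0]) ** 2).sum(axis=1)
    while len(chosen) < n_rois:
        pick = int(np.argmax(d2))
        chosen.append(remaining[pick])
        nd2 = ((remaining - chosen[-1]) ** 2).sum(axis=1)
        d2 = np.minimum(d2, nd2)
        d2[pick] = -1
    chosen_vox = np.asarray(chosen)
    return chosen_vox @ affine[:3, :3].T + affine[:3, 3]


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectData], SynthTruth]:
    """Generate the cohort and its ground truth.

    Subject i, voxel v:
    ``y_iv(t) = Σ_k a_ik·M_kv·s_ik(t) + b_iv·ε_iv(t) + nuisance``,
    where ``a_ik`` is the per-subject network gain (spread across subjects by
    the network's ``amplitude_sd_across_subjects``, itself set by any
    shared_signal_gain plant), ``b_iv`` the private-noise sd (elevated, with
    subject spread, inside a private_noise_gain plant's ROI), and the
    nuisance block adds a global artifact (correlated with the motion trace)
    plus WM/CSF compartment signals. Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    grid = tuple(spec.grid)
    affine = grid_affine(grid, spec.voxel_size)
    masks = _compartment_masks(grid, affine)
    n, t = spec.n_subjects, spec.t_points
    k = len(spec.networks)
    for net in spec.networks:
        if net.spatial_map.shape != grid:
            raise ValueError(
                f"network {net.name!r} map shape {net.spatial_map.shape} != grid {grid}"
            )

    # resolve plants
    shared_targets = {}
    private_plants = []
    net_names = [net.name for net in spec.networks]
    for plant in spec.coupling:
        if plant.mechanism == "shared_signal_gain":
            if plant.target not in net_names:
                raise ValueError(f"plant targets unknown network {plant.target!r}")
            shared_targets[plant.target] = plant
        else:
            if spec.roi_set is None or plant.target not in spec.roi_set.labels:
                raise ValueError(f"plant targets unknown ROI {plant.target!r}")
            private_plants.append(plant)

    # per-subject network gains a_ik
    amplitudes = np.empty((n, k))
    for ki, net in enumerate(spec.networks):
        rel_sd = net.amplitude_sd_across_subjects / max(net.base_amplitude, 1e-12)
        if net.name in shared_targets:
            rel_sd = max(rel_sd, 0.8 * abs(shared_targets[net.name].effect_r))
        draws = 1.0 + rel_sd * rng.standard_normal(n)
        amplitudes[:, ki] = net.base_amplitude * np.clip(draws, 0.1, None)

    # private-noise gain fields
    coords = _voxel_centers_mm(grid, affine)
    noise_field = np.full(grid, spec.noise_sd)  # baseline b_v, subject-independent
    private_gains: dict[str, np.ndarray] = {}
    private_regions: dict[str, np.ndarray] = {}
    planted_hubs: list[tuple[str, int]] = []
    for plant in private_plants:
        ridx = spec.roi_set.index(plant.target)
        center = spec.roi_set.centers[ridx]
        radius = spec.roi_set.radii[ridx]
        region = ((coords - center) ** 2).sum(axis=-1) <= radius**2
        if not region.any():
            raise ValueError(f"private plant ROI {plant.target!r} covers no voxel")
        rel_sd = 0.8 * abs(plant.effect_r)
        gains = plant.noise_base_factor * np.clip(
            1.0 + rel_sd * rng.standard_normal(n), 0.1, None
        )
        private_gains[plant.target] = gains
        private_regions[plant.target] = region
        planted_hubs.append((plant.target, -1))
    for net_name, plant in shared_targets.items():
        ki = net_names.index(net_name)
        net = spec.networks[ki]
        if spec.roi_set is not None and net.roi_indices:
            for ridx in net.roi_indices:
                planted_hubs.append((spec.roi_set.labels[ridx], +1))

    # optional per-ROI in-band private signal maps (decorrelates distinct ROIs
    # that share a network map; used by the null cohort)
    roi_maps = None
    if spec.roi_in_band_noise_sd > 0 and spec.roi_set is not None:
        roi_maps = make_network_maps(
            grid,
            spec.voxel_size,
            [tuple(c) for c in spec.roi_set.centers],
            blob_fwhm=1.5 * float(np.mean(spec.voxel_size)),
        )

    subjects: list[SubjectData] = []
    nuisance_tcs = []
    motions = []
    within_r = np.empty((n, k))
    wm_mask, csf_mask = masks["wm"].data, masks["csf"].data
    brain = masks["brain"].data
    nu = spec.nuisance
    for i in range(n):
        data = np.zeros(grid + (t,))
        # network signals
        for ki, net in enumerate(spec.networks):
            s = make_bandlimited_timecourse(t, spec.tr, net.band, rng)
            data += amplitudes[i, ki] * net.spatial_map[..., None] * s
        # private broadband noise with per-subject regional gains
        b_field = noise_field.copy()
        for label, gains in private_gains.items():
            b_field = np.where(private_regions[label], noise_field * gains[i], b_field)
        if spec.noise_sd > 0 or private_gains:
            data += b_field[..., None] * rng.standard_normal(grid + (t,))
        # per-ROI in-band private signal
        if roi_maps is not None:
            for m in roi_maps:
                s = make_bandlimited_timecourse(t, spec.tr, DEFAULT_BAND, rng)
                data += spec.roi_in_band_noise_sd * m[..., None] * s
        # nuisance: global artifact + compartment signals + motion
        g = _smooth_walk(t, rng)
        wm_sig = 0.7 * g + 0.7 * _smooth_walk(t, rng)
        csf_sig = 0.7 * g + 0.7 * _smooth_walk(t, rng)
        data[brain] += nu.global_artifact_amp * g
        data[wm_mask] += nu.wm_amp * wm_sig
        data[csf_mask] += nu.csf_amp * csf_sig
        motion = np.empty((t, 6))
        for c in range(6):
            motion[:, c] = nu.motion_amp * (0.6 * _smooth_walk(t, rng) + 0.4 * g)
        data += 100.0  # baseline intensity
        run = BoldRun(data=data, tr=spec.tr, affine=affine, subject_id=f"sub-{i:03d}")
        subjects.append(SubjectData(run=run, motion=motion, masks=masks))
        nuisance_tcs.append({"global": g, "wm": wm_sig, "csf": csf_sig})
        motions.append(motion)
        for ki, net in enumerate(spec.networks):
            a2 = amplitudes[i, ki] ** 2
            within_r[i, ki] = a2 / (a2 + spec.noise_sd**2) if a2 > 0 else 0.0

    truth = SynthTruth(
        amplitudes=amplitudes,
        network_names=net_names,
        private_gains=private_gains,
        planted_hubs=planted_hubs,
        within_network_r=within_r,
        nuisance_timecourses=nuisance_tcs,
        motion=motions,
    )
    return subjects, truth


def cohort_roi_set(spec: CohortSpec) -> RoiSet:
    if spec.roi_set is None:
        raise ValueError("cohort spec carries no ROI set")
    return spec.roi_set


# ---------------------------------------------------------------------------
# Ready-made cohort specs (the study conditions at desk scale)
# ---------------------------------------------------------------------------

_GRID = (16, 16, 12)
_T_DESK = 120
_ROI_RADIUS = 4.0  # mm; scaled to the desk grid (8 mm on the full-size grid)
_BLOB_FWHM = 5.0  # mm


def desk_analysis_config(**overrides):
    """AnalysisConfig matched to the desk-scale cohort geometry.

    The desk grid shrinks head geometry roughly two-fold, so the smoothing
    kernel scales with it (4 mm FWHM, like the 4 mm ROI radius); an 8 mm
    kernel on the 55 mm desk grid would blur neighbouring ROIs together.
    All other parameters keep the study defaults.
    """
    from .io import AnalysisConfig

    params = {"smooth_fwhm": 4.0}
    params.update(overrides)
    return AnalysisConfig(**params)


def _build_roi_networks(
    grid, voxel_size, n_rois: int, network_sizes: dict[str, int]
) -> tuple[RoiSet, dict[str, list[int]]]:
    """Lay out ``n_rois`` blob ROIs and assign the first blocks to networks."""
    centers = _roi_lattice(grid, voxel_size, n_rois)
    labels, networks = [], []
    assignment: dict[str, list[int]] = {name: [] for name in network_sizes}
    cursor = 0
    for name, size in network_sizes.items():
        for _ in range(size):
            labels.append(f"{name}_{len(assignment[name]):02d}")
            networks.append(name)
            assignment[name].append(cursor)
            cursor += 1
    while cursor < n_rois:
        labels.append(f"bg_{cursor:02d}")
        networks.append("background")
        cursor += 1
    rois = RoiSet(
        labels=labels,
        networks=networks,
        centers=centers[:n_rois],
        radii=np.full(n_rois, _ROI_RADIUS),
    )
    return rois, assignment


def demo_cohort_spec(
    n_subjects: int = 20,
    t_points: int = _T_DESK,
    seed: int = 0,
    n_rois: int = 20,
) -> CohortSpec:
    """Desk-scale cohort: two planted networks plus independent background ROIs.

    Defaults (20 subjects, 16×16×12 grid, 120 time points) keep a full
    pipeline run interactive while leaving the planted structure easily
    recoverable.
    """
    grid, voxel = _GRID, DEFAULT_VOXEL
    rois, assign = _build_roi_networks(
        grid, voxel, n_rois, {"netA": 6, "netB": 6}
    )
    networks = []
    for name, idxs in assign.items():
        maps = make_network_maps(
            grid, voxel, [[tuple(rois.centers[j]) for j in idxs]], _BLOB_FWHM
        )
        networks.append(
            NetworkSpec(
                name=name,
                spatial_map=maps[0],
                base_amplitude=1.0,
                amplitude_sd_across_subjects=0.3,
                roi_indices=idxs,
            )
        )
    return CohortSpec(
        n_subjects=n_subjects,
        grid=grid,
        voxel_size=voxel,
        t_points=t_points,
        tr=DEFAULT_TR,
        networks=networks,
        noise_sd=0.6,
        coupling=[CouplingPlant("netA", "shared_signal_gain", 0.5)],
        seed=seed,
        roi_set=rois,
        roi_in_band_noise_sd=0.3,
    )


def null_cohort_spec(
    n_subjects: int = 79,
    n_rois: int = 40,
    t_points: int = _T_DESK,
    seed: int = 0,
) -> CohortSpec:
    """Fully null cohort for Type-I calibration.

    Every ROI is its own single-blob network with zero across-subject
    amplitude spread and no coupling plant, so no true inter-ROI
    connectivity and no true amplitude×connectivity coupling exist. The
    brain-wide artifact term is disabled here by construction: a global
    signal whose realized energy varies by subject couples every region's
    amplitude to every correlation — the physiological-noise confound
    itself — and therefore cannot be part of a null. Motion and the WM/CSF
    compartment signals remain, so the nuisance regression is exercised.
    """
    grid, voxel = _GRID, DEFAULT_VOXEL
    rois, _ = _build_roi_networks(grid, voxel, n_rois, {})
    maps = make_network_maps(
        grid, voxel, [tuple(c) for c in rois.centers], _BLOB_FWHM
    )
    networks = [
        NetworkSpec(
            name=f"roi{j:02d}",
            spatial_map=maps[j],
            base_amplitude=1.0,
            amplitude_sd_across_subjects=0.0,
            roi_indices=[j],
        )
        for j in range(n_rois)
    ]
    return CohortSpec(
        n_subjects=n_subjects,
        grid=grid,
        voxel_size=voxel,
        t_points=t_points,
        tr=DEFAULT_TR,
        networks=networks,
        noise_sd=0.6,
        coupling=[],
        nuisance=NuisanceSpec(global_artifact_amp=0.0),
        seed=seed,
        roi_set=rois,
    )


def recovery_cohort_spec(
    n_subjects: int = 79,
    t_points: int = _T_DESK,
    seed: int = 0,
    n_rois: int = 40,
    shared_effect: float = 0.5,
    private_effect: float = -0.5,
) -> CohortSpec:
    """Hub-recovery cohort: one positive and one negative coupling plant.

    Network A (12 ROIs) carries a shared_signal_gain plant → its ROIs should
    surface as positive hubs; network B (12 ROIs) has fixed amplitude but one
    of its ROIs carries a private_noise_gain plant → that ROI should surface
    as a negative hub. Remaining ROIs are independent background.
    """
    grid, voxel = _GRID, DEFAULT_VOXEL
    rois, assign = _build_roi_networks(
        grid, voxel, n_rois, {"netA": 12, "netB": 12}
    )
    networks = []
    for name, idxs in assign.items():
        maps = make_network_maps(
            grid, voxel, [[tuple(rois.centers[j]) for j in idxs]], _BLOB_FWHM
        )
        networks.append(
            NetworkSpec(
                name=name,
                spatial_map=maps[0],
                base_amplitude=1.0,
                amplitude_sd_across_subjects=0.0,
                roi_indices=idxs,
            )
        )
    private_target = rois.labels[assign["netB"][0]]
    return CohortSpec(
        n_subjects=n_subjects,
        grid=grid,
        voxel_size=voxel,
        t_points=t_points,
        tr=DEFAULT_TR,
        networks=networks,
        noise_sd=0.6,
        coupling=[
            CouplingPlant("netA", "shared_signal_gain", shared_effect),
            CouplingPlant(private_target, "private_noise_gain", private_effect),
        ],
        seed=seed,
        roi_set=rois,
    )


# ---------------------------------------------------------------------------
# Disk export (simulate CLI)
# ---------------------------------------------------------------------------


def write_cohort(
    subjects: list[SubjectData], truth: SynthTruth, spec: CohortSpec, out_dir
) -> None:
    """Write per-subject NIfTI runs, motion text files, masks and a truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sub in subjects:
        sid = sub.run.subject_id
        write_volume(sub.run, out / f"{sid}_bold.nii")
        np.savetxt(out / f"{sid}_motion.txt", sub.motion, fmt="%.6f")
    for kind, mask in subjects[0].masks.items():
        write_volume(mask, out / f"mask_{kind}.nii")
    if spec.roi_set is not None:
        write_roi_table(spec.roi_set, out / "rois.tsv")
    import pandas as pd

    amp = pd.DataFrame(
        truth.amplitudes,
        columns=[f"amp_{name}" for name in truth.network_names],
    )
    for label, gains in truth.private_gains.items():
        amp[f"private_gain_{label}"] = gains
    amp.insert(0, "subject", [s.run.subject_id for s in subjects])
    amp.to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "planted_hubs.tsv", "w") as fh:
        fh.write("label\tsign\n")
        for label, sign in truth.planted_hubs:
            fh.write(f"{label}\t{sign:+d}\n")
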