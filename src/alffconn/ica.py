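"""Group spatial ICA with dual-regression back-reconstruction.

Two-stage reduction (per-subject temporal PCA, temporal concatenation,
group PCA), FastICA unmixing in the spatial domain, dual regression to
recover subject-specific maps and time courses, voxel-wise one-sample t
maps, and optimal component matching for automated network identification.

Component sign and order are arbitrary (the usual ICA indeterminacy);
downstream inter-subject statistics are invariant to joint sign flips of a
map and its time course.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .io import BoldRun

logger = logging.getLogger(__name__)

__all__ = [
    "GroupDecomposition",
    "ComponentTMap",
    "reduce_group_pca",
    "fit_spatial_ica",
    "back_reconstruct",
    "group_component_tmap",
    "match_components",
    "run_group_ica",
]


@dataclass
class ReductionInfo:
    subject_dim: int
    group_dim: int
    subject_variance_fraction: list[float]
    group_variance_fraction: float
    voxel_mask: np.ndarray  # flattened nonzero-variance voxel selector
    grid: tuple[int, int, int]


@dataclass
class GroupDecomposition:
    """K group spatial maps plus per-subject maps and time courses."""

    k: int
    group_maps: np.ndarray  # K × X×Y×Z
    subject_maps: np.ndarray | None = None  # N × K × X×Y×Z
    subject_timecourses: np.ndarray | None = None  # N × K × T
    reduction: ReductionInfo | None = None
    mixing: np.ndarray | None = None


@dataclass
class ComponentTMap:
    """Voxel-wise one-sample t statistics for one component across subjects."""

    t: np.ndarray
    df: int
    threshold: float
    mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.mask = np.abs(self.t) > self.threshold


def _flatten_runs(runs: list[BoldRun]) -> tuple[list[np.ndarray], np.ndarray]:
    grid = runs[0].shape3d
    for run in runs:
        if run.shape3d != grid:
            raise ValueError("all runs must share the same grid")
    flats = [run.data.reshape(-1, run.n_timepoints).T for run in runs]  # T×V
    variance = np.zeros(flats[0].shape[1])
    for f in flats:
        variance += f.var(axis=0)
    voxel_mask = variance > 0
    if not voxel_mask.any():
        raise ValueError("all voxels have zero variance")
    return [f[:, voxel_mask] for f in flats], voxel_mask


def reduce_group_pca(
    runs: list[BoldRun], subject_dim: int, group_dim: int
) -> tuple[np.ndarray, ReductionInfo]:
    """Two-stage PCA reduction for temporal-concatenation group ICA.

    Stage 1 projects each subject's (centered) data onto its top
    ``subject_dim`` temporal eigenvectors; the reduced blocks are
    concatenated along the (reduced) time axis and stage 2 reduces the stack
    to ``group_dim`` rows. Returns the group_dim × V_retained matrix and the
    retained-variance bookkeeping (zero-variance voxels are dropped and
    recorded for reinsertion).
    """
    if not runs:
        raise ValueError("no runs given")
    t = runs[0].n_timepoints
    if subject_dim > t:
        raise ValueError(f"subject_dim {subject_dim} exceeds T={t}")
    if group_dim > len(runs) * subject_dim:
        raise ValueError(
            f"group_dim {group_dim} exceeds stacked dimension {len(runs) * subject_dim}"
        )
    flats, voxel_mask = _flatten_runs(runs)
    reduced_blocks = []
    subj_fracs = []
    for f in flats:
        f = f - f.mean(axis=0)
        cov = f @ f.T  # T×T temporal Gram matrix
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][:subject_dim]
        total = evals.sum()
        subj_fracs.append(float(evals[order].sum() / total) if total > 0 else 0.0)
        reduced_blocks.append(evecs[:, order].T @ f)  # subject_dim × V
    stacked = np.vstack(reduced_blocks)
    cov2 = stacked @ stacked.T
    evals2, evecs2 = np.linalg.eigh(cov2)
    order2 = np.argsort(evals2)[::-1][:group_dim]
    total2 = evals2.sum()
    group_frac = float(evals2[order2].sum() / total2) if total2 > 0 else 0.0
    reduced = evecs2[:, order2].T @ stacked  # group_dim × V
    info = ReductionInfo(
        subject_dim=subject_dim,
        group_dim=group_dim,
        subject_variance_fraction=subj_fracs,
        group_variance_fraction=group_frac,
        voxel_mask=voxel_mask,
        grid=runs[0].shape3d,
    )
    return reduced, info


def fit_spatial_ica(
    reduced: np.ndarray,
    info: ReductionInfo,
    k: int,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
    n_restarts: int = 5,
) -> GroupDecomposition:
    """FastICA unmixing of the reduced data into k spatial sources.

    Voxels are the samples and reduced time dimensions the features, so the
    recovered sources are spatial maps (maximally non-Gaussian across
    voxels, log-cosh contrast). Deterministic under ``seed``; up to
    ``n_restarts`` re-initializations with a seed-derived schedule before a
    non-convergence error is raised.
    """
    if k > reduced.shape[0]:
        raise ValueError(f"k={k} exceeds group dimension {reduced.shape[0]}")
    x = reduced.T  # voxels × group_dim
    if k == 1:
        # one source: ICA reduces to the standardized leading component
        src = x[:, 0] - x[:, 0].mean()
        sd = src.std()
        if sd == 0:
            raise ValueError("rank-0 data: cannot extract a component")
        maps = np.zeros((1, info.voxel_mask.size))
        maps[0, info.voxel_mask] = src / sd
        return GroupDecomposition(
            k=1,
            group_maps=maps.reshape((1,) + info.grid),
            reduction=info,
            mixing=np.ones((reduced.shape[0], 1)),
        )
    last_err: Exception | None = None
    for attempt in range(n_restarts):
        ica = FastICA(
            n_components=k,
            algorithm="parallel",
            fun="logcosh",
            whiten="unit-variance",
            max_iter=max_iter,
            tol=tol,
            random_state=seed + 1000 * attempt,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                sources = ica.fit_transform(x)  # voxels × k
            except ConvergenceWarning as exc:
                last_err = exc
                logger.warning("ICA restart %d did not converge", attempt + 1)
                continue
        maps = np.zeros((k, info.voxel_mask.size))
        maps[:, info.voxel_mask] = sources.T
        group_maps = maps.reshape((k,) + info.grid)
        return GroupDecomposition(
            k=k, group_maps=group_maps, reduction=info, mixing=ica.mixing_
        )
    raise RuntimeError(
        f"spatial ICA failed to converge after {n_restarts} restarts "
        f"(max_iter={max_iter}, tol={tol}): {last_err}"
    )


def back_reconstruct(
    decomp: GroupDecomposition, runs: list[BoldRun]
) -> GroupDecomposition:
    """Dual regression: subject time courses then subject spatial maps.

    Stage 1 regresses the group maps onto every time frame (time courses);
    the time courses are then variance-normalized so that a subject's
    component amplitude is carried by the stage-2 spatial map — the quantity
    the inter-subject coupling analyses consume. Stage 2 regresses the
    normalized time courses onto the subject's voxel series (maps). When a
    subject's data exactly follow the generative model
    ``maps × timecourses`` the reconstruction is exact up to that scale
    convention.
    """
    info = decomp.reduction
    if info is None:
        raise ValueError("decomposition carries no reduction metadata")
    grid = runs[0].shape3d
    if grid != info.grid:
        raise ValueError("runs grid does not match the fitted decomposition")
    g = decomp.group_maps.reshape(decomp.k, -1)[:, info.voxel_mask]  # K×V
    n = len(runs)
    t = runs[0].n_timepoints
    subject_maps = np.zeros((n, decomp.k) + grid)
    subject_tcs = np.empty((n, decomp.k, t))
    for i, run in enumerate(runs):
        y = run.data.reshape(-1, t).T[:, info.voxel_mask]  # T×V
        if np.allclose(y.var(axis=0).sum(), 0):
            raise ValueError(f"subject {run.subject_id!r} has zero variance")
        y = y - y.mean(axis=0)
        tc, *_ = np.linalg.lstsq(g.T, y.T, rcond=None)  # K×T
        tc_sd = tc.std(axis=1, keepdims=True)
        tc_norm = np.where(tc_sd > 0, tc / np.where(tc_sd == 0, 1, tc_sd), tc)
        smap, *_ = np.linalg.lstsq(tc_norm.T, y, rcond=None)  # K×V
        subject_tcs[i] = tc
        flat = np.zeros((decomp.k, info.voxel_mask.size))
        flat[:, info.voxel_mask] = smap
        subject_maps[i] = flat.reshape((decomp.k,) + grid)
    decomp.subject_maps = subject_maps
    decomp.subject_timecourses = subject_tcs
    return decomp


def group_component_tmap(
    subject_maps: np.ndarray, threshold_t: float
) -> ComponentTMap:
    """Voxel-wise one-sample t across subjects for one component.

    t = mean / (sd/√N) with df = N−1. Voxels with zero across-subject
    variance but nonzero mean get signed infinity (and enter the mask);
    all-zero voxels get t = 0.
    """
    maps = np.asarray(subject_maps, dtype=np.float64)
    n = maps.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for a t map")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    if np.any(zero_var & (mean != 0)):
        logger.warning(
            "%d voxels have zero across-subject variance; t set to ±inf",
            int((zero_var & (mean != 0)).sum()),
        )
    t[zero_var & (mean > 0)] = np.inf
    t[zero_var & (mean < 0)] = -np.inf
    t[zero_var & (mean == 0)] = 0.0
    return ComponentTMap(t=t, df=n - 1, threshold=threshold_t)


def match_components(
    maps_a: np.ndarray, maps_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one matching of two map lists by |spatial correlation|.

    Returns ``assignment`` (index into ``maps_b`` for each map in
    ``maps_a``; −1 for unmatched when counts differ) and the signed
    correlation of each matched pair.
    """
    a = np.asarray(maps_a, dtype=np.float64)
    b = np.asarray(maps_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty map lists")
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("map grids differ")
    af = a.reshape(a.shape[0], -1)
    bf = b.reshape(b.shape[0], -1)
    af = af - af.mean(axis=1, keepdims=True)
    bf = bf - bf.mean(axis=1, keepdims=True)
    asd = np.linalg.norm(af, axis=1)
    bsd = np.linalg.norm(bf, axis=1)
    corr = (af @ bf.T) / np.outer(
        np.where(asd == 0, 1, asd), np.where(bsd == 0, 1, bsd)
    )
    rows, cols = linear_sum_assignment(-np.abs(corr))
    assignment = np.full(a.shape[0], -1, dtype=int)
    signed = np.zeros(a.shape[0])
    for r, c in zip(rows, cols):
        assignment[r] = c
        signed[r] = corr[r, c]
    return assignment, signed


def run_group_ica(
    runs: list[BoldRun],
    k: int,
    seed: int = 0,
    subject_dim: int | None = None,
    group_dim: int | None = None,
) -> GroupDecomposition:
    """Reduction → ICA → dual regression in one call."""
    t = runs[0].n_timepoints
    if subject_dim is None:
        subject_dim = min(t - 1, 30)
    if group_dim is None:
        group_dim = min(len(runs) * subject_dim, max(k, min(2 * k, 40)))
    reduced, info = reduce_group_pca(runs, subject_dim, group_dim)
    decomp = fit_spatial_ica(reduced, info, k, seed=seed)
    return back_reconstruct(decomp, runs)
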