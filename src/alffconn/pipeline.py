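"""Cohort-level orchestration: preprocessing → ALFF → connectivity → coupling.

Convenience drivers used by the CLI ``run-all`` command, the test suite and
the reproduction script. Each function is a thin composition of the module
APIs; no statistics live here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alff import AlffMap, compute_alff_map, normalize_alff_global, roi_mean_alff, roi_membership, roi_mean_map
from .connectivity import ConnMatrix, extract_roi_series, fisher_z_transform, pearson_conn_matrix
from .coupling import RoiCouplingMatrix, critical_value, identify_coupling_hubs, roi_alff_coupling
from .io import AnalysisConfig, RoiSet
from .preprocess import bandpass_filter, preprocess_run
from .synth import SubjectData

__all__ = ["CohortMeasures", "compute_cohort_measures", "run_roi_coupling_analysis"]


@dataclass
class CohortMeasures:
    """Per-subject ROI measures for a cohort: ALFF and Fisher-z connectivity."""

    roi_alff: np.ndarray  # N × R
    z_matrices: np.ndarray  # N × R × R
    alff_maps: list  # per subject normalized AlffMap
    rois: RoiSet


def compute_cohort_measures(
    subjects: list[SubjectData],
    rois: RoiSet,
    config: AnalysisConfig,
) -> CohortMeasures:
    """Preprocess every subject and extract ROI ALFF and connectivity."""
    n = len(subjects)
    r_count = len(rois)
    roi_alff = np.empty((n, r_count))
    z_matrices = np.empty((n, r_count, r_count))
    alff_maps = []
    members = None
    for i, sub in enumerate(subjects):
        clean, _ = preprocess_run(
            sub.run,
            sub.motion,
            sub.masks["wm"],
            sub.masks["csf"],
            config,
            brain_mask=sub.masks.get("brain"),
        )
        if members is None:
            members = roi_membership(clean.shape3d, clean.affine, rois)
        amap = compute_alff_map(clean, config.band, fractional=config.fractional_alff)
        amap = normalize_alff_global(amap, sub.masks["brain"])
        alff_maps.append(amap)
        roi_alff[i] = roi_mean_map(amap.data, members)
        conn_input = (
            bandpass_filter(clean, config.band)
            if config.bandpass_before_connectivity
            else clean
        )
        series = extract_roi_series(conn_input, rois, members=members)
        pear = pearson_conn_matrix(series, rois)
        z_matrices[i] = fisher_z_transform(pear).values
    return CohortMeasures(
        roi_alff=roi_alff, z_matrices=z_matrices, alff_maps=alff_maps, rois=rois
    )


def run_roi_coupling_analysis(
    measures: CohortMeasures, config: AnalysisConfig
) -> tuple[RoiCouplingMatrix, "HubResult"]:
    """ROI coupling matrix and hubs at the configured alpha and hub rule."""
    thr = critical_value("pearson_r", measures.roi_alff.shape[0], config.alpha_voxel)
    coupling = roi_alff_coupling(
        measures.z_matrices, measures.roi_alff, thr, rois=measures.rois
    )
    hubs = identify_coupling_hubs(coupling, config.hub_min_connections)
    return coupling, hubs
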