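"""Discarding, tissue PCs, nuisance regression, smoothing."""

import numpy as np
import pytest

from alffconn import (
    AnalysisConfig,
    MaskVolume,
    build_nuisance_design,
    compute_tissue_pcs,
    drop_initial_volumes,
    nuisance_regress,
    preprocess_run,
    smooth_gaussian,
)
from alffconn.preprocess import NuisanceDesign

from conftest import make_run


class TestDropInitialVolumes:
    def test_study_discard(self):
        run = make_run(shape=(4, 4, 4, 200))
        out = drop_initial_volumes(run, 2)
        assert out.n_timepoints == 198
        np.testing.assert_array_equal(out.data, run.data[..., 2:])

    def test_zero_is_identity(self, small_run):
        out = drop_initial_volumes(small_run, 0)
        np.testing.assert_array_equal(out.data, small_run.data)

    def test_dropping_everything_rejected(self, small_run):
        with pytest.raises(ValueError):
            drop_initial_volumes(small_run, small_run.n_timepoints)


class TestTissuePcs:
    def test_rank_one_region_recovers_common_series(self, rng):
        run = make_run(shape=(6, 6, 4, 40))
        u = rng.standard_normal(40)
        mask = np.zeros((6, 6, 4), dtype=bool)
        mask[:3, 0, 0] = True
        data = run.data.copy()
        for idx in np.argwhere(mask):
            data[tuple(idx)] = 3.0 * u + 7.0
        run = run.with_data(data)
        pcs = compute_tissue_pcs(run, MaskVolume(mask, "wm"), 1)
        uc = u - u.mean()
        cos = abs(pcs[:, 0] @ uc) / np.linalg.norm(uc)
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_matches_dense_svd_oracle(self, rng):
        run = make_run(shape=(6, 6, 4, 40), seed=5)
        mask = np.zeros((6, 6, 4), dtype=bool)
        mask.ravel()[rng.choice(mask.size, 50, replace=False)] = True
        pcs = compute_tissue_pcs(run, MaskVolume(mask, "csf"), 5)
        # independent oracle: dense SVD of the demeaned voxel×time matrix
        m = run.data[mask]
        m = m - m.mean(axis=1, keepdims=True)
        _, s, vt = np.linalg.svd(m, full_matrices=False)
        for j in range(5):
            assert abs(pcs[:, j] @ vt[j]) > 1 - 1e-8
        # orthonormal columns
        np.testing.assert_allclose(pcs.T @ pcs, np.eye(5), atol=1e-10)

    def test_rank_deficient_returns_available_components(self, rng, caplog):
        run = make_run(shape=(6, 6, 4, 40))
        mask = np.zeros((6, 6, 4), dtype=bool)
        mask[:6, 0, 0] = True
        base = rng.standard_normal((3, 40))
        data = run.data.copy()
        coeff = rng.standard_normal((6, 3))
        for v, idx in enumerate(np.argwhere(mask)):
            data[tuple(idx)] = coeff[v] @ base
        run = run.with_data(data)
        # rank ≤ 3 after demeaning, 5 requested → fall back with warning
        import logging

        with caplog.at_level(logging.WARNING):
            pcs = compute_tissue_pcs(run, MaskVolume(mask, "wm"), 5)
        assert pcs.shape[1] <= 3
        assert any("rank" in r.message for r in caplog.records)

    def test_zero_variance_region_rejected(self):
        run = make_run(data=np.ones((4, 4, 4, 20)))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0] = True
        with pytest.raises(ValueError):
            compute_tissue_pcs(run, MaskVolume(mask, "wm"), 2)


class TestNuisanceRegress:
    def _design(self, rng, t=40):
        motion = rng.standard_normal((t, 6))
        return build_nuisance_design(motion)

    def test_design_column_series_regressed_to_zero(self, rng):
        design = self._design(rng)
        run = make_run(shape=(4, 4, 4, 40))
        data = run.data.copy()
        data[0, 0, 0] = 5.0 * design.columns[:, 2] - 1.0
        out = nuisance_regress(run.with_data(data), design)
        np.testing.assert_allclose(out.data[0, 0, 0], 0.0, atol=1e-10)

    def test_orthogonal_series_only_demeaned(self, rng):
        design = self._design(rng)
        q, _ = np.linalg.qr(design.columns)
        v = rng.standard_normal(40)
        v -= q @ (q.T @ v)  # orthogonal to the whole design
        run = make_run(shape=(4, 4, 4, 40))
        data = run.data.copy()
        data[1, 1, 1] = v + 3.0
        out = nuisance_regress(run.with_data(data), design)
        np.testing.assert_allclose(out.data[1, 1, 1], v, atol=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        design = self._design(rng)
        run = make_run(shape=(4, 4, 4, 40), seed=11)
        out = nuisance_regress(run, design)
        x = design.columns
        proj = np.eye(40) - x @ np.linalg.pinv(x.T @ x) @ x.T
        expected = (proj @ run.data.reshape(-1, 40).T).T.reshape(run.data.shape)
        np.testing.assert_allclose(out.data, expected, atol=1e-8)

    def test_residuals_orthogonal_to_design(self, rng):
        design = self._design(rng)
        run = make_run(shape=(4, 4, 4, 40), seed=2)
        out = nuisance_regress(run, design)
        resid = out.data.reshape(-1, 40)
        inner = np.abs(resid @ design.columns)
        scale = np.linalg.norm(resid) * np.linalg.norm(design.columns)
        assert inner.max() / scale <= 1e-8

    def test_idempotent(self, rng):
        design = self._design(rng)
        run = make_run(shape=(4, 4, 4, 40), seed=3)
        once = nuisance_regress(run, design)
        twice = nuisance_regress(once, design)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-8)

    def test_collinear_design_names_offenders(self, rng):
        motion = rng.standard_normal((40, 6))
        motion[:, 5] = 2.0 * motion[:, 0]
        design = build_nuisance_design(motion)
        with pytest.raises(ValueError, match="motion"):
            nuisance_regress(make_run(shape=(4, 4, 4, 40)), design)

    def test_row_mismatch_rejected(self, rng):
        design = self._design(rng, t=30)
        with pytest.raises(ValueError):
            nuisance_regress(make_run(shape=(4, 4, 4, 40)), design)

    def test_all_zero_column_rejected(self):
        cols = np.ones((40, 2))
        cols[:, 0] = 0.0
        with pytest.raises(ValueError):
            NuisanceDesign(columns=cols, labels=["a", "intercept"])


class TestSmoothing:
    VOX = (3.44, 3.44, 3.40)

    def test_zero_fwhm_identity(self, rng):
        vol = rng.standard_normal((8, 8, 6))
        np.testing.assert_array_equal(smooth_gaussian(vol, 0.0, self.VOX), vol)

    def test_impulse_response_width(self):
        vol = np.zeros((31, 31, 31))
        vol[15, 15, 15] = 1.0
        out = smooth_gaussian(vol, 8.0, self.VOX)
        profile = out[:, 15, 15]
        x_mm = (np.arange(31) - 15) * self.VOX[0]
        half = profile.max() / 2
        # interpolate crossings for a sub-voxel FWHM estimate
        above = profile >= half
        lo_i = np.argmax(above)
        hi_i = len(above) - 1 - np.argmax(above[::-1])

        def crossing(i0, i1):
            y0, y1 = profile[i0], profile[i1]
            return x_mm[i0] + (half - y0) / (y1 - y0) * (x_mm[i1] - x_mm[i0])

        width = crossing(hi_i, hi_i + 1) - crossing(lo_i, lo_i - 1)
        assert width == pytest.approx(8.0, rel=0.05)

    def test_constant_volume_unchanged(self):
        vol = np.full((8, 8, 6), 3.7)
        np.testing.assert_allclose(smooth_gaussian(vol, 8.0, self.VOX), vol, atol=1e-12)

    def test_mean_preserved_for_interior_support(self, rng):
        vol = np.zeros((24, 24, 24))
        vol[9:15, 9:15, 9:15] = rng.standard_normal((6, 6, 6))
        out = smooth_gaussian(vol, 6.0, (3.0, 3.0, 3.0))
        assert out.mean() == pytest.approx(vol.mean(), abs=1e-10)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_gaussian(np.zeros((4, 4, 4)), -1.0, self.VOX)

    def test_4d_smooths_each_volume(self, rng):
        data = rng.standard_normal((6, 6, 4, 3))
        out = smooth_gaussian(data, 5.0, self.VOX)
        for t in range(3):
            np.testing.assert_allclose(
                out[..., t], smooth_gaussian(data[..., t], 5.0, self.VOX)
            )


class TestFullPreprocess:
    def test_pure_nuisance_run_annihilated(self, rng):
        """A run whose signal is entirely spanned by the design leaves ~0 residual."""
        t_total, drop = 42, 2
        t = t_total - drop
        motion = rng.standard_normal((t_total, 6))
        u = rng.standard_normal(t)  # wm compartment series
        v = rng.standard_normal(t)  # csf compartment series
        shape = (6, 6, 4)
        wm = np.zeros(shape, dtype=bool)
        wm[0:2] = True
        csf = np.zeros(shape, dtype=bool)
        csf[4:6] = True
        data = np.zeros(shape + (t_total,))
        coeffs = rng.standard_normal((np.prod(shape), 8))
        basis = np.column_stack([motion[drop:], u, v])  # T×8
        flat = data.reshape(-1, t_total)
        flat[:, drop:] = coeffs @ basis.T
        for idx in np.argwhere(wm):
            data[tuple(idx)][drop:] = u
        for idx in np.argwhere(csf):
            data[tuple(idx)][drop:] = v
        run = make_run(data=data + 50.0)
        cfg = AnalysisConfig(n_discard=drop, n_nuisance_pcs=5, smooth_fwhm=4.0)
        clean, design = preprocess_run(
            run, motion, MaskVolume(wm, "wm"), MaskVolume(csf, "csf"), cfg
        )
        assert clean.n_timepoints == t
        in_var = np.var(flat[:, drop:])
        assert np.var(clean.data) <= 1e-10 * in_var
        assert design.n_timepoints == t
        assert "wm_pc1" in design.labels and "csf_pc1" in design.labels

    def test_motion_trimmed_to_match_discard(self, demo_cohort, desk_config):
        spec, subjects, _ = demo_cohort
        sub = subjects[0]
        clean, design = preprocess_run(
            sub.run, sub.motion, sub.masks["wm"], sub.masks["csf"], desk_config
        )
        assert clean.n_timepoints == spec.t_points - desk_config.n_discard
        assert design.columns.shape[0] == clean.n_timepoints


class TestOptInVariants:
    def test_bandpass_concentrates_power(self, rng):
        from alffconn.preprocess import bandpass_filter
        from scipy import signal as sps

        run = make_run(shape=(4, 4, 3, 120), tr=2.5, seed=8)
        out = bandpass_filter(run, (0.01, 0.08))
        freqs, power = sps.periodogram(out.data[0, 0, 0], fs=1 / 2.5)
        sel = (freqs >= 0.005) & (freqs <= 0.1)
        assert power[sel].sum() / power[freqs > 0].sum() > 0.95

    def test_bandpass_invalid_band(self, small_run):
        from alffconn.preprocess import bandpass_filter

        with pytest.raises(ValueError):
            bandpass_filter(small_run, (0.01, 0.5))

    def test_global_signal_regression_removes_brain_mean(self, rng, demo_cohort):
        spec, subjects, _ = demo_cohort
        sub = subjects[0]
        cfg = AnalysisConfig(
            smooth_fwhm=0.0, global_signal_regression=True, n_discard=2
        )
        clean, design = preprocess_run(
            sub.run, sub.motion, sub.masks["wm"], sub.masks["csf"], cfg,
            brain_mask=sub.masks["brain"],
        )
        assert "global_pc1" in design.labels
        # the in-brain mean series is a design column, so the residual mean
        # series vanishes identically
        gs_after = clean.data[sub.masks["brain"].data].mean(axis=0)
        gs_before = sub.run.data[sub.masks["brain"].data][:, cfg.n_discard:].mean(axis=0)
        assert np.linalg.norm(gs_after) <= 1e-8 * np.linalg.norm(gs_before - gs_before.mean())

    def test_global_signal_regression_needs_mask(self, demo_cohort):
        spec, subjects, _ = demo_cohort
        sub = subjects[0]
        cfg = AnalysisConfig(global_signal_regression=True)
        with pytest.raises(ValueError, match="brain mask"):
            preprocess_run(
                sub.run, sub.motion, sub.masks["wm"], sub.masks["csf"], cfg
            )
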