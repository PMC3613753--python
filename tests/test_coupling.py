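"""Critical values, voxel-matched and ROI coupling, hubs, cluster threshold."""

import numpy as np
import pytest

from alffconn import (
    MaskVolume,
    cluster_extent_threshold,
    critical_value,
    identify_coupling_hubs,
    roi_alff_coupling,
    voxel_matched_coupling,
)

from conftest import tiny_roiset


class TestCriticalValue:
    def test_one_sample_t_reference_cohort(self):
        # 79 subjects, two-tailed p=0.001 → the conventional 3.42 threshold
        assert critical_value("one_sample_t", 79, 0.001) == pytest.approx(3.42, abs=0.005)

    def test_pearson_r_reference_cohort(self):
        # exact t↔r inversion gives 0.3633 for n=79; the conventional rounded
        # threshold 0.364 agrees to its own printed precision
        r = critical_value("pearson_r", 79, 0.001)
        assert r == pytest.approx(0.3633, abs=5e-4)
        assert r == pytest.approx(0.364, abs=1.5e-3)

    def test_threshold_vanishes_for_large_n(self):
        assert critical_value("pearson_r", 10**6, 0.001) < 0.01

    def test_monotone_in_alpha(self):
        assert critical_value("pearson_r", 50, 0.001) > critical_value(
            "pearson_r", 50, 0.05
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            critical_value("pearson_r", 3, 0.001)
        with pytest.raises(ValueError):
            critical_value("one_sample_t", 10, 1.5)
        with pytest.raises(ValueError):
            critical_value("chi2", 10, 0.05)


class TestVoxelMatchedCoupling:
    def test_identical_inputs_give_unit_correlation(self, rng):
        maps = rng.standard_normal((6, 4, 4, 3))
        out = voxel_matched_coupling(maps, maps, threshold_r=0.5)
        np.testing.assert_allclose(out.r, 1.0, atol=1e-12)
        assert np.all(out.significant == 1.0)

    def test_matches_per_voxel_loop_oracle(self, rng):
        s = rng.standard_normal((8, 3, 4, 2))
        a = rng.standard_normal((8, 3, 4, 2))
        out = voxel_matched_coupling(s, a, threshold_r=0.7)
        for i in range(3):
            for j in range(4):
                for k in range(2):
                    expected = np.corrcoef(s[:, i, j, k], a[:, i, j, k])[0, 1]
                    assert out.r[i, j, k] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_voxel_is_nan(self, rng):
        s = rng.standard_normal((6, 2, 2, 1))
        a = rng.standard_normal((6, 2, 2, 1))
        s[:, 0, 0, 0] = 3.0
        out = voxel_matched_coupling(s, a, threshold_r=0.5)
        assert np.isnan(out.r[0, 0, 0])
        assert out.significant[0, 0, 0] == 0.0

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            voxel_matched_coupling(
                rng.standard_normal((6, 2, 2, 2)), rng.standard_normal((5, 2, 2, 2)), 0.5
            )

    def test_null_inputs_calibrated_suprathreshold_fraction(self):
        """Independent inputs at N=79 exceed the p<0.001 threshold ~0.1% of the time."""
        rng = np.random.default_rng(77)
        n, shape = 79, (30, 30, 20)
        s = rng.standard_normal((n,) + shape)
        a = rng.standard_normal((n,) + shape)
        thr = critical_value("pearson_r", n, 0.001)
        out = voxel_matched_coupling(s, a, thr)
        frac = np.mean(np.abs(out.significant) > 0)
        n_vox = np.prod(shape)
        sd = np.sqrt(0.001 * 0.999 / n_vox)
        assert abs(frac - 0.001) < 4 * sd

    def test_sign_rectified_view_invariant_to_component_flip(self, rng):
        maps = rng.standard_normal((6, 4, 4, 3))
        alff = rng.standard_normal((6, 4, 4, 3))
        group_map = rng.standard_normal((4, 4, 3))
        out = voxel_matched_coupling(maps, alff, 0.5)
        flipped = voxel_matched_coupling(-maps, alff, 0.5)
        np.testing.assert_allclose(
            out.sign_rectified(group_map),
            flipped.sign_rectified(-group_map),
            atol=1e-12,
        )


class TestRoiCoupling:
    def test_constructed_pair_is_asymmetric(self, rng):
        n, r = 10, 4
        z = rng.standard_normal((n, r, r))
        z = (z + z.transpose(0, 2, 1)) / 2
        alff = rng.standard_normal((n, r))
        alff[:, 0] = z[:, 0, 1]  # ROI 0's ALFF tracks edge (0,1) exactly
        out = roi_alff_coupling(z, alff, threshold_r=0.9)
        assert out.r[0, 1] == pytest.approx(1.0)
        assert abs(out.r[1, 0]) < 0.99  # generically not 1 the other way

    def test_matches_two_loop_oracle(self, rng):
        n, r = 9, 5
        z = rng.standard_normal((n, r, r))
        z = (z + z.transpose(0, 2, 1)) / 2
        alff = rng.standard_normal((n, r))
        out = roi_alff_coupling(z, alff, threshold_r=0.5)
        for j in range(r):
            for k in range(r):
                if j == k:
                    assert out.r[j, k] == 0.0
                    continue
                expected = np.corrcoef(alff[:, j], z[:, j, k])[0, 1]
                assert out.r[j, k] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_alff_row_is_nan(self, rng, caplog):
        import logging

        n, r = 8, 3
        z = rng.standard_normal((n, r, r))
        alff = rng.standard_normal((n, r))
        alff[:, 1] = 2.0
        with caplog.at_level(logging.WARNING):
            out = roi_alff_coupling(z, alff, 0.5, rois=tiny_roiset(np.zeros((3, 3)) + np.arange(3)[:, None] * 10))
        assert np.isnan(out.r[1, [0, 2]]).all()
        assert out.positive_counts[1] == 0

    def test_counts_tally_signed_entries(self, rng):
        n, r = 8, 4
        z = rng.standard_normal((n, r, r))
        alff = rng.standard_normal((n, r))
        out = roi_alff_coupling(z, alff, threshold_r=0.2)
        for j in range(r):
            assert out.positive_counts[j] == (out.significant[j] > 0).sum()
            assert out.negative_counts[j] == (out.significant[j] < 0).sum()

    def test_inconsistent_shapes_rejected(self, rng):
        with pytest.raises(ValueError):
            roi_alff_coupling(
                rng.standard_normal((6, 4, 4)), rng.standard_normal((6, 3)), 0.5
            )


class TestHubIdentification:
    def test_all_subthreshold_gives_empty(self, rng):
        z = rng.standard_normal((8, 5, 5))
        alff = rng.standard_normal((8, 5))
        out = roi_alff_coupling(z, alff, threshold_r=0.9999)
        hubs = identify_coupling_hubs(out, 0)
        assert hubs.hubs == []

    def test_forced_positive_hub(self, rng):
        n, r = 12, 40
        z = rng.standard_normal((n, r, r)) * 0.01
        alff = rng.standard_normal((n, r))
        # make 35 edges of ROI 0 track its ALFF exactly
        for k in range(1, 36):
            z[:, 0, k] = alff[:, 0]
        out = roi_alff_coupling(z, alff, threshold_r=0.9)
        hubs = identify_coupling_hubs(out, min_connections=30)
        assert ("0", "", 1, 35) in [
            (h[0], h[1], h[2], h[3]) for h in hubs.hubs
        ] or any(h[0] == "0" and h[2] == 1 and h[3] == 35 for h in hubs.hubs)

    def test_roi_can_be_both_positive_and_negative_hub(self, rng):
        n, r = 12, 10
        z = rng.standard_normal((n, r, r)) * 0.01
        alff = rng.standard_normal((n, r))
        for k in range(1, 5):
            z[:, 0, k] = alff[:, 0]
        for k in range(5, 9):
            z[:, 0, k] = -alff[:, 0]
        out = roi_alff_coupling(z, alff, threshold_r=0.9)
        hubs = identify_coupling_hubs(out, min_connections=3)
        signs = {h[2] for h in hubs.hubs if h[0] == "0"}
        assert signs == {1, -1}


class TestClusterExtent:
    MASK = MaskVolume(np.ones((12, 12, 8), dtype=bool), "brain")
    VOX = (3.44, 3.44, 3.40)

    def test_degenerate_voxel_alpha_gives_one(self):
        null = cluster_extent_threshold(
            self.MASK, 0.0, self.VOX, voxel_alpha=1e-9, familywise_alpha=0.05,
            n_iter=200, seed=0,
        )
        assert null.extent_threshold == 1

    def test_deterministic_under_seed(self):
        a = cluster_extent_threshold(self.MASK, 4.0, self.VOX, 0.01, 0.05, 100, seed=3)
        b = cluster_extent_threshold(self.MASK, 4.0, self.VOX, 0.01, 0.05, 100, seed=3)
        np.testing.assert_array_equal(a.max_sizes, b.max_sizes)
        assert a.extent_threshold == b.extent_threshold

    def test_threshold_nondecreasing_in_fwhm(self):
        smooth0 = cluster_extent_threshold(self.MASK, 0.0, self.VOX, 0.01, 0.05, 200, seed=4)
        smooth8 = cluster_extent_threshold(self.MASK, 8.0, self.VOX, 0.01, 0.05, 200, seed=4)
        assert smooth8.extent_threshold >= smooth0.extent_threshold

    def test_exceedance_probability_bound_holds(self):
        null = cluster_extent_threshold(self.MASK, 4.0, self.VOX, 0.01, 0.05, 300, seed=5)
        k = null.extent_threshold
        assert np.mean(null.max_sizes >= k) <= 0.05
        if k > 1:
            assert np.mean(null.max_sizes >= k - 1) > 0.05

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            cluster_extent_threshold(
                MaskVolume(np.zeros((4, 4, 4), dtype=bool), "brain"),
                4.0, self.VOX, 0.01, 0.05, 10, seed=0,
            )
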