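from dataclasses import replace

import numpy as np
import pytest

import petfsv as p


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.count_nonzero(a & b) / (np.count_nonzero(a) + np.count_nonzero(b))


class TestErodeCluster:
    def test_3cube_erodes_to_center(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        eroded = p.erode_cluster(mask, 1)
        expected = np.zeros_like(mask)
        expected[2, 2, 2] = True
        np.testing.assert_array_equal(eroded, expected)

    def test_5cube_erodes_to_3cube(self):
        mask = np.zeros((7, 7, 7), dtype=bool)
        mask[1:6, 1:6, 1:6] = True
        expected = np.zeros_like(mask)
        expected[2:5, 2:5, 2:5] = True
        np.testing.assert_array_equal(p.erode_cluster(mask, 1), expected)

    def test_zero_iterations_identity(self):
        mask = np.random.default_rng(0).random((6, 6, 6)) > 0.5
        out = p.erode_cluster(mask, 0)
        np.testing.assert_array_equal(out, mask)
        assert out is not mask  # copy, not alias

    def test_cardinality_non_increasing(self):
        mask = np.random.default_rng(1).random((10, 10, 10)) > 0.3
        counts = [p.erode_cluster(mask, i).sum() for i in range(4)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_negative_iterations_rejected(self):
        with pytest.raises(ValueError):
            p.erode_cluster(np.ones((3, 3, 3), dtype=bool), -1)

    def test_empty_result_permitted(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        assert p.erode_cluster(mask, 1).sum() == 0


class TestExtractClusterTac:
    def _series(self, values):
        sched = p.FrameSchedule.from_spans([(values.shape[-1], 5.0)])
        return p.DynamicSeries(values, (3.0, 3.0, 3.0), sched)

    def test_single_voxel_mask(self):
        vox = np.zeros((3, 3, 3, 4))
        vox[1, 1, 1] = [1.0, 2.0, 3.0, 4.0]
        series = self._series(vox)
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        np.testing.assert_array_equal(p.extract_cluster_tac(series, mask).value, [1, 2, 3, 4])

    def test_mean_of_v_and_3v(self):
        vox = np.zeros((2, 1, 1, 3))
        v = np.array([2.0, 4.0, 6.0])
        vox[0, 0, 0] = v
        vox[1, 0, 0] = 3 * v
        series = self._series(vox)
        mask = np.ones((2, 1, 1), dtype=bool)
        np.testing.assert_allclose(p.extract_cluster_tac(series, mask).value, 2 * v, rtol=1e-15)

    def test_empty_mask_rejected(self):
        series = self._series(np.zeros((2, 2, 2, 3)))
        with pytest.raises(ValueError, match="empty"):
            p.extract_cluster_tac(series, np.zeros((2, 2, 2), dtype=bool))

    def test_shape_mismatch_rejected(self):
        series = self._series(np.zeros((2, 2, 2, 3)))
        with pytest.raises(ValueError, match="shape"):
            p.extract_cluster_tac(series, np.zeros((3, 3, 3), dtype=bool))


class TestClusterVoxelTacs:
    def test_noiseless_two_population_exact_recovery(self):
        series, truth, _ = p.two_population_phantom()
        config = p.ClusterConfig(n_clusters=2, erosion_iterations=0)
        labels = p.cluster_voxel_tacs(series, config)
        aid, vid = p.select_blood_clusters(labels, series)
        assert dice(labels == aid, truth.arterial_mask) == 1.0
        assert dice(labels == vid, truth.venous_mask) == 1.0

    def test_noisy_two_population_dice(self):
        # peak SNR 10 -> noise SD 10% of frame value
        series, truth, _ = p.two_population_phantom(noise_sd_fraction=0.1, seed=42)
        config = p.ClusterConfig(n_clusters=2, erosion_iterations=0, seed=42)
        labels = p.cluster_voxel_tacs(series, config)
        aid, vid = p.select_blood_clusters(labels, series)
        assert dice(labels == aid, truth.arterial_mask) >= 0.8
        assert dice(labels == vid, truth.venous_mask) >= 0.8

    def test_deterministic_under_fixed_seed(self):
        series, _, _ = p.two_population_phantom(noise_sd_fraction=0.1, seed=3)
        config = p.ClusterConfig(n_clusters=3, seed=11)
        l1 = p.cluster_voxel_tacs(series, config)
        l2 = p.cluster_voxel_tacs(series, config)
        np.testing.assert_array_equal(l1, l2)

    def test_constant_image_rejected(self):
        sched = p.FrameSchedule.from_spans([(10, 5.0)])
        series = p.DynamicSeries(np.full((4, 4, 4, 10), 7.0), (3, 3, 3), sched)
        with pytest.raises(ValueError, match="constant"):
            p.cluster_voxel_tacs(series, p.ClusterConfig(n_clusters=2))

    def test_too_few_surviving_voxels(self):
        sched = p.FrameSchedule.from_spans([(10, 5.0)])
        vox = np.zeros((4, 4, 4, 10))
        vox[0, 0, 0, 2] = 1.0  # single non-background voxel
        series = p.DynamicSeries(vox, (3, 3, 3), sched)
        with pytest.raises(ValueError, match="survive"):
            p.cluster_voxel_tacs(series, p.ClusterConfig(n_clusters=4))

    def test_noiseless_cluster_mean_matches_generating_tac(self):
        series, truth, _ = p.two_population_phantom()
        config = p.ClusterConfig(n_clusters=2, erosion_iterations=0)
        labels = p.cluster_voxel_tacs(series, config)
        aid, _ = p.select_blood_clusters(labels, series)
        tac = p.extract_cluster_tac(series, labels == aid)
        np.testing.assert_allclose(tac.value, truth.ideal_arterial_tac.value, rtol=1e-6)


class TestSelectBloodClusters:
    def test_auto_orders_by_peak_time(self):
        # venous peaks at 10 s, arterial at 18 s
        series, truth, _ = p.two_population_phantom(venous_peak_s=10.0, arterial_peak_s=18.0)
        labels = p.cluster_voxel_tacs(series, p.ClusterConfig(n_clusters=2))
        aid, vid = p.select_blood_clusters(labels, series)
        art_tac = p.extract_cluster_tac(series, labels == aid)
        ven_tac = p.extract_cluster_tac(series, labels == vid)
        assert art_tac.mid_time[np.argmax(art_tac.value)] > ven_tac.mid_time[np.argmax(ven_tac.value)]
        assert dice(labels == aid, truth.arterial_mask) == 1.0

    def test_manual_mode_verbatim(self):
        series, _, _ = p.two_population_phantom()
        labels = p.cluster_voxel_tacs(series, p.ClusterConfig(n_clusters=2))
        ids = sorted(np.unique(labels[labels > 0]))
        assert p.select_blood_clusters(labels, series, "manual", (ids[1], ids[0])) == (
            ids[1], ids[0],
        )

    def test_manual_identical_ids_rejected(self):
        series, _, _ = p.two_population_phantom()
        labels = p.cluster_voxel_tacs(series, p.ClusterConfig(n_clusters=2))
        with pytest.raises(ValueError, match="differ"):
            p.select_blood_clusters(labels, series, "manual", (1, 1))

    def test_manual_missing_id_rejected(self):
        series, _, _ = p.two_population_phantom()
        labels = p.cluster_voxel_tacs(series, p.ClusterConfig(n_clusters=2))
        with pytest.raises(ValueError, match="not present"):
            p.select_blood_clusters(labels, series, "manual", (1, 99))

    def test_auto_needs_two_blood_like_clusters(self):
        # all cluster TACs peak late: nothing blood-like within 90 s
        sched = p.FrameSchedule.from_spans([(10, 30.0)])
        mid = sched.mid_time
        vox = np.zeros((4, 4, 2, 10))
        vox[:2] = mid / mid[-1]
        vox[2:] = (mid / mid[-1]) ** 2
        series = p.DynamicSeries(vox, (3, 3, 3), sched)
        labels = p.cluster_voxel_tacs(
            series, p.ClusterConfig(n_clusters=2, activity_prefilter_percentile=0)
        )
        with pytest.raises(ValueError, match="blood-like"):
            p.select_blood_clusters(labels, series)


class TestSegmentBloodPools:
    def test_segmentation_invariants(self, small_noiseless_phantom):
        series, truth, _ = small_noiseless_phantom
        seg = p.segment_blood_pools(series, p.ClusterConfig())
        assert seg.arterial_id != seg.venous_id
        assert seg.eroded_arterial_mask.sum() > 0
        assert np.all(seg.labels[seg.eroded_arterial_mask] == seg.arterial_id)
        assert np.all(seg.labels[seg.eroded_venous_mask] == seg.venous_id)
        # eroded masks stay inside the true compartments for the clean phantom
        assert np.all(truth.arterial_mask[seg.eroded_arterial_mask])
        assert np.all(truth.venous_mask[seg.eroded_venous_mask])


class TestErosionSensitivity:
    def test_zero_extra_iterations_is_zero_change(self, small_noiseless_phantom):
        series, _, config = small_noiseless_phantom
        seg = p.segment_blood_pools(series, p.ClusterConfig())
        ctx = p.AcquisitionContext(config.dose_bq, config.heart_rate_per_min)
        sens = p.erosion_sensitivity(series, seg, ctx, extra_iterations=0)
        assert sens["arterial"] == 0.0
        assert sens["venous"] == 0.0

    def test_blur_free_change_below_one_percent(self, small_noiseless_phantom):
        series, _, config = small_noiseless_phantom
        seg = p.segment_blood_pools(series, p.ClusterConfig())
        ctx = p.AcquisitionContext(config.dose_bq, config.heart_rate_per_min)
        sens = p.erosion_sensitivity(series, seg, ctx, extra_iterations=1)
        assert abs(sens["arterial"]) < 1.0
        assert abs(sens["venous"]) < 1.0

    def test_mask_vanishing_is_an_error(self, small_noiseless_phantom):
        series, _, config = small_noiseless_phantom
        seg = p.segment_blood_pools(series, p.ClusterConfig())
        ctx = p.AcquisitionContext(config.dose_bq, config.heart_rate_per_min)
        with pytest.raises(ValueError, match="vanished"):
            p.erosion_sensitivity(series, seg, ctx, extra_iterations=50)


class TestClusterConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_clusters": 1},
            {"activity_prefilter_percentile": 100.0},
            {"activity_prefilter_percentile": -1.0},
            {"erosion_iterations": -1},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            p.ClusterConfig(**kwargs)

    def test_tracer_cluster_counts(self):
        assert p.TRACER_CLUSTER_COUNTS["acetate"] == 5
        assert p.TRACER_CLUSTER_COUNTS["water"] == 6
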