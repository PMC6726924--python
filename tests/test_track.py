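import numpy as np
import pytest

from pswarp.embed import EmbeddedRecord, EmbeddingParams, TimeSeries, delay_embed
from pswarp.errors import DimensionError, InsufficientDataError, ParameterError
from pswarp.track import (RecordingPlan, build_tracking, characteristic_distance,
                          choose_references, partition_records)


def embedded(points):
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    return EmbeddedRecord(points=points,
                          params=EmbeddingParams(1, points.shape[1]))


class TestPartition:
    def test_exact_division(self, rng):
        series = TimeSeries(rng.standard_normal(100), 1.0)
        segments, times = partition_records(series, RecordingPlan(25))
        assert len(segments) == 4
        np.testing.assert_array_equal(times, [0, 25, 50, 75])

    def test_overlap_formula(self, rng):
        # floor((100 - 40) / 20) + 1 = 4
        series = TimeSeries(rng.standard_normal(100), 1.0)
        segments, _ = partition_records(series, RecordingPlan(40, overlap=20))
        assert len(segments) == 4

    def test_trailing_partial_dropped(self, rng):
        series = TimeSeries(rng.standard_normal(109), 1.0)
        segments, _ = partition_records(series, RecordingPlan(25))
        assert len(segments) == 4
        assert all(len(s) == 25 for s in segments)

    def test_too_few_records_raises(self, rng):
        series = TimeSeries(rng.standard_normal(30), 1.0)
        with pytest.raises(InsufficientDataError):
            partition_records(series, RecordingPlan(25))

    def test_segments_are_verbatim_slices(self, rng):
        y = rng.standard_normal(100)
        series = TimeSeries(y, 2.0)
        segments, times = partition_records(series, RecordingPlan(30, overlap=10))
        np.testing.assert_array_equal(segments[1].values, y[20:50])
        assert times[1] == pytest.approx(10.0)  # 20 samples at 2 Hz


class TestChooseReferences:
    def test_k1_is_seeded_initial_point(self):
        rec = embedded(np.arange(10.0))
        refs = choose_references(rec, 1, seed=0)
        assert refs.size == 1
        assert refs.points[0, 0] in rec.points[:, 0]

    def test_farthest_point_on_a_line(self):
        rec = embedded(np.arange(10.0))
        # find a seed whose initial pick is the point 0, then the farthest
        # point must be 9
        for seed in range(100):
            refs = choose_references(rec, 2, seed=seed)
            if refs.points[0, 0] == 0.0:
                assert refs.points[1, 0] == 9.0
                return
        pytest.fail("no seed picked index 0")

    def test_deterministic_given_seed(self, rng):
        rec = embedded(rng.standard_normal((50, 3)))
        a = choose_references(rec, 5, seed=42)
        b = choose_references(rec, 5, seed=42)
        np.testing.assert_array_equal(a.points, b.points)

    def test_points_distinct_and_from_record(self, rng):
        pts = rng.standard_normal((40, 2))
        refs = choose_references(embedded(pts), 8, seed=1)
        assert np.unique(refs.points, axis=0).shape[0] == 8
        for p in refs.points:
            assert np.any(np.all(pts == p, axis=1))

    def test_k_exceeding_points_raises(self, rng):
        rec = embedded(rng.standard_normal((5, 2)))
        with pytest.raises(ParameterError):
            choose_references(rec, 6, seed=0)


class TestCharacteristicDistance:
    def test_coincident_points_give_zero(self):
        rec = embedded(np.ones((10, 2)))
        refs = choose_references(rec, 1, seed=0)
        feat = characteristic_distance(rec, refs)
        assert feat[0] == 0.0

    def test_hand_computed_mean(self):
        rec = embedded([[0.0, 0.0], [2.0, 0.0]])
        refs = choose_references(embedded([[1.0, 0.0], [1.0, 0.0]]), 1, seed=0)
        feat = characteristic_distance(rec, refs)
        np.testing.assert_allclose(feat, [1.0])

    def test_translation_invariance(self, rng):
        pts = rng.standard_normal((30, 3))
        rec = embedded(pts)
        refs = choose_references(rec, 4, seed=3)
        shift = np.array([5.0, -2.0, 1.0])
        rec2 = embedded(pts + shift)
        refs2 = choose_references(rec2, 4, seed=3)
        np.testing.assert_allclose(characteristic_distance(rec, refs),
                                   characteristic_distance(rec2, refs2),
                                   rtol=1e-12)

    def test_permutation_invariance(self, rng):
        pts = rng.standard_normal((30, 2))
        refs = choose_references(embedded(pts), 3, seed=0)
        a = characteristic_distance(embedded(pts), refs)
        b = characteristic_distance(embedded(pts[::-1].copy()), refs)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_dimension_mismatch_raises(self, rng):
        refs = choose_references(embedded(rng.standard_normal((10, 3))), 2, 0)
        with pytest.raises(DimensionError):
            characteristic_distance(embedded(rng.standard_normal((10, 2))), refs)


class TestBuildTracking:
    def test_constant_columns_zero_derivative(self):
        tm = build_tracking([np.array([1.0, 2.0])] * 6)
        np.testing.assert_array_equal(tm.V, 0.0)

    def test_linear_ramp_derivative(self):
        feats = [np.array([float(i)]) for i in range(4)]
        tm = build_tracking(feats)
        np.testing.assert_allclose(tm.V[:, 0], [1.0, 1.0, 1.0, 1.0])

    def test_single_feature_shapes(self, rng):
        feats = [rng.standard_normal(1) for _ in range(5)]
        tm = build_tracking(feats)
        assert tm.X.shape == (5, 1) and tm.V.shape == (5, 1)

    def test_columns_centered_and_means_stored(self, rng):
        feats = [rng.standard_normal(3) + 10 for _ in range(8)]
        tm = build_tracking(feats)
        np.testing.assert_allclose(tm.X.mean(axis=0), 0.0, atol=1e-12)
        assert np.all(tm.column_means > 5)

    def test_ragged_features_raise(self):
        with pytest.raises(DimensionError):
            build_tracking([np.zeros(2), np.zeros(3), np.zeros(2), np.zeros(2)])

    def test_too_few_records_raise(self):
        with pytest.raises(InsufficientDataError):
            build_tracking([np.zeros(2)] * 3)

    def test_timestamp_spacing_scales_derivative(self, rng):
        feats = [rng.standard_normal(2) for _ in range(6)]
        t = np.arange(6.0)
        a = build_tracking(feats, timestamps=t)
        b = build_tracking(feats, timestamps=2.0 * t)
        np.testing.assert_allclose(b.V, a.V / 2.0, rtol=1e-12)


class TestStationaryDriftBound:
    def test_no_feature_trend_without_damage(self, stationary_run):
        # eps = 0: no column of X may trend more than stationary (circular
        # block bootstrap) replicates allow
        from pswarp.embed import EmbeddingOptions, select_embedding

        series = TimeSeries(stationary_run.measurement,
                            stationary_run.config.sample_rate)
        segments, _ = partition_records(series, RecordingPlan(2048))
        sel = select_embedding(segments[0], EmbeddingOptions(fnn_threshold=0.02))
        first = delay_embed(segments[0], sel.params)
        refs = choose_references(first, 8, seed=0)
        feats = [characteristic_distance(delay_embed(s, sel.params), refs)
                 for s in segments]
        tm = build_tracking(feats)
        m = tm.n_records
        t = np.arange(m)

        def slopes(x):
            return np.polyfit(t, x, 1)[0]

        observed = np.abs(np.apply_along_axis(slopes, 0, tm.X))
        rng = np.random.default_rng(0)
        boot_max = np.zeros_like(observed)
        block = 2
        for _ in range(100):
            idx = []
            while len(idx) < m:  # stationary (circular block) bootstrap
                s = int(rng.integers(m))
                idx.extend(((s + np.arange(block)) % m).tolist())
            rep = np.abs(np.apply_along_axis(slopes, 0,
                                             tm.X[np.array(idx[:m])]))
            boot_max = np.maximum(boot_max, rep)
        assert np.all(observed <= 1.5 * boot_max)
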