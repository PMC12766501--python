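"""Preprocessing pipeline: binning, filters, outlier fences, fills,
normalization, splits, and the no-leakage guarantee."""

import numpy as np
import pandas as pd
import pytest

from odtgc.preprocess import (
    FeatureTensor,
    bin_events,
    censor_outliers_iqr,
    compute_stats,
    filter_missing,
    impute,
    normalize,
    preprocess_events,
    split_cohort,
)


def make_events(rows):
    return pd.DataFrame(rows, columns=["patient_id", "t_hours", "feature_id", "value"])


class TestBinEvents:
    def test_48h_window_at_4h_bins_gives_12_steps(self):
        ev = make_events([("p1", 0.0, "hr", 80.0)])
        t = bin_events(ev, 48, 4)
        assert t.n_bins == 12
        assert len(t.bin_edges) == 13

    def test_multiple_readings_are_averaged(self):
        ev = make_events([("p1", 4.5, "hr", 4.0), ("p1", 6.0, "hr", 6.0)])
        t = bin_events(ev, 48, 4)
        assert t.values[0, 1, 0] == pytest.approx(5.0)
        assert t.mask[0, 1, 0] == 1

    def test_empty_bin_is_masked_nan(self):
        ev = make_events([("p1", 0.0, "hr", 80.0)])
        t = bin_events(ev, 48, 4)
        assert np.isnan(t.values[0, 5, 0])
        assert t.mask[0, 5, 0] == 0

    def test_negative_timestamps_rejected_with_warning(self, caplog):
        ev = make_events([("p1", -1.0, "hr", 80.0), ("p1", 2.0, "hr", 70.0)])
        with caplog.at_level("WARNING"):
            t = bin_events(ev, 48, 4)
        assert "rejecting" in caplog.text
        assert t.values[0, 0, 0] == pytest.approx(70.0)

    def test_measurement_at_window_end_lands_in_final_bin(self):
        ev = make_events([("p1", 48.0, "hr", 99.0)])
        t = bin_events(ev, 48, 4)
        assert t.values[0, 11, 0] == pytest.approx(99.0)

    def test_indivisible_window_rejected(self):
        with pytest.raises(ValueError):
            bin_events(make_events([("p1", 1.0, "hr", 1.0)]), 48, 5)


def tensor_from(values, mask=None, feature_ids=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = ~np.isnan(values)
    n, t, f = values.shape
    return FeatureTensor(
        values, np.asarray(mask, dtype=np.uint8), np.arange(t + 1) * 4.0,
        feature_ids or [f"f{i}" for i in range(f)],
        [f"p{i}" for i in range(n)],
    )


class TestFilterMissing:
    def test_feature_over_threshold_dropped(self):
        # feature 0 observed in 41% of cells -> missing 59% > 40% -> dropped
        vals = np.ones((100, 1, 2))
        mask = np.ones((100, 1, 2), dtype=np.uint8)
        mask[:59, 0, 0] = 0
        t, stats = filter_missing(tensor_from(vals, mask), 0.4, 0.4)
        assert t.feature_ids == ["f1"]
        assert stats.dropped_features == ["f0"]

    def test_fully_observed_tensor_unchanged(self):
        t0 = tensor_from(np.random.default_rng(0).normal(size=(5, 3, 2)))
        t, stats = filter_missing(t0, 0.4, 0.4)
        assert t.feature_ids == t0.feature_ids
        assert t.patient_ids == t0.patient_ids
        np.testing.assert_array_equal(t.values, t0.values)

    def test_patient_lacking_essential_monitoring_dropped(self):
        vals = np.ones((2, 12, 2))
        mask = np.ones_like(vals, dtype=np.uint8)
        mask[1, :6, 0] = 0  # p1 has no f0 observation in first 24 h (bins 0-5)
        t, stats = filter_missing(
            tensor_from(vals, mask), 0.9, 0.9,
            essential_features=["f0"], essential_window_h=24.0,
        )
        assert t.patient_ids == ["p0"]
        assert stats.dropped_patients == ["p1"]

    def test_all_features_dropped_is_error(self):
        vals = np.ones((4, 2, 1))
        mask = np.zeros_like(vals, dtype=np.uint8)
        with pytest.raises(ValueError):
            filter_missing(tensor_from(vals, mask), 0.4, 0.4)


class TestIqrCensoring:
    def test_hand_fence_example(self):
        # Q1=4, Q3=8, k=1.5 -> fences [-2, 14]; 20 removed, 14 retained
        train = np.array([4.0, 4, 4, 5, 6, 7, 8, 8, 8])[None, :, None]
        t0 = tensor_from(np.concatenate([train, [[[20.0]] * 9]], axis=0)
                         .reshape(2, 9, 1))
        stats = compute_stats(t0, ["p0"])
        assert stats.q1[0] == pytest.approx(4.0)
        assert stats.q3[0] == pytest.approx(8.0)
        censored = censor_outliers_iqr(t0, stats, k=1.5)
        assert censored.mask[1, 0, 0] == 0 and np.isnan(censored.values[1, 0, 0])

    def test_value_exactly_at_fence_retained(self):
        train = np.array([4.0, 4, 4, 5, 6, 7, 8, 8, 8, 14.0])[None, :, None]
        t0 = tensor_from(train)
        stats = compute_stats(t0, ["p0"])
        hi = stats.q3[0] + 1.5 * (stats.q3[0] - stats.q1[0])
        t0.values[0, -1, 0] = hi
        censored = censor_outliers_iqr(t0, stats, k=1.5)
        assert censored.mask[0, -1, 0] == 1

    def test_constant_feature_untouched(self, caplog):
        t0 = tensor_from(np.full((3, 4, 1), 5.0))
        stats = compute_stats(t0, t0.patient_ids)
        with caplog.at_level("WARNING"):
            censored = censor_outliers_iqr(t0, stats)
        np.testing.assert_array_equal(censored.values, t0.values)
        assert "IQR is zero" in caplog.text


class TestImpute:
    def test_forward_then_backward_fill(self):
        vals = np.array([[np.nan, 5.0, np.nan, 7.0]]).reshape(1, 4, 1)
        t0 = tensor_from(vals)
        stats = compute_stats(t0, t0.patient_ids)
        out = impute(t0, stats)
        np.testing.assert_allclose(out.values[0, :, 0], [5, 5, 5, 7])
        # mask still records the original observation pattern
        np.testing.assert_array_equal(out.mask[0, :, 0], [0, 1, 0, 1])

    def test_all_missing_series_uses_cohort_mean(self):
        vals = np.array([[[3.2], [3.2]], [[np.nan], [np.nan]]])
        t0 = tensor_from(vals)
        stats = compute_stats(t0, ["p0"])
        out = impute(t0, stats)
        np.testing.assert_allclose(out.values[1, :, 0], [3.2, 3.2])

    def test_fully_observed_unchanged(self, rng):
        t0 = tensor_from(rng.normal(size=(4, 6, 3)))
        out = impute(t0, compute_stats(t0, t0.patient_ids))
        np.testing.assert_array_equal(out.values, t0.values)


class TestNormalize:
    def test_zscore_example(self):
        t0 = tensor_from(np.array([[[9.0]]]))
        stats = compute_stats(t0, t0.patient_ids)
        stats.mean[:] = 5.0
        stats.sd[:] = 2.0
        assert normalize(t0, stats).values[0, 0, 0] == pytest.approx(2.0)

    def test_train_features_standardised(self, rng):
        t0 = tensor_from(rng.normal(3, 4, size=(50, 6, 2)))
        stats = compute_stats(t0, t0.patient_ids)
        out = normalize(t0, stats)
        flat = out.values.reshape(-1, 2)
        np.testing.assert_allclose(flat.mean(0), 0.0, atol=1e-10)
        np.testing.assert_allclose(flat.std(0), 1.0, atol=1e-10)

    def test_zero_sd_maps_to_zero(self):
        t0 = tensor_from(np.full((3, 2, 1), 7.0))
        out = normalize(t0, compute_stats(t0, t0.patient_ids))
        np.testing.assert_array_equal(out.values, 0.0)


class TestSplitCohort:
    def test_622_sizes(self):
        tr, va, te = split_cohort([f"p{i}" for i in range(10)], (0.6, 0.2, 0.2), 0)
        assert (len(tr), len(va), len(te)) == (6, 2, 2)

    def test_deterministic_and_partition(self):
        ids = [f"p{i}" for i in range(37)]
        a = split_cohort(ids, seed=5)
        b = split_cohort(ids, seed=5)
        assert a == b
        union = set(a[0]) | set(a[1]) | set(a[2])
        assert union == set(ids)
        assert len(a[0]) + len(a[1]) + len(a[2]) == len(ids)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            split_cohort(["p0", "p1"], (0.6, 0.2, 0.2), 0)


class TestPipelineProperties:
    def test_no_test_split_leakage(self, default_cohort):
        """Perturbing test-split values leaves the transform stats unchanged."""
        ev = default_cohort.events
        _, stats, (tr, va, te) = preprocess_events(ev, seed=0)
        ev2 = ev.copy()
        test_set = set(te)
        in_test = ev2["patient_id"].isin(test_set)
        ev2.loc[in_test, "value"] = ev2.loc[in_test, "value"] * 3.0 + 10.0
        _, stats2, _ = preprocess_events(ev2, seed=0)
        np.testing.assert_array_equal(stats.mean, stats2.mean)
        np.testing.assert_array_equal(stats.sd, stats2.sd)

    def test_output_finite_and_masked(self, default_cohort):
        tensor, stats, _ = preprocess_events(default_cohort.events, seed=0)
        assert np.all(np.isfinite(tensor.values))
        assert set(np.unique(tensor.mask)) <= {0, 1}
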