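"""Plausibility, minimum-record, and pacing filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from vitalcentiles.quality import (
    PacingClassifier,
    UntrainedClassifierError,
    apply_pacing_filter,
    calibrate_pacing_threshold,
    extract_pacing_features,
    min_record_duration_hours,
    minimum_record_filter,
    plausibility_filter,
    train_pacing_classifier,
    windowed_features,
)


def _stream(values, variable="HR", patient_id="P1"):
    n = len(values)
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "time": np.datetime64("2014-01-01", "s")
            + (np.arange(n) * 5).astype("timedelta64[s]"),
            "variable": variable,
            "value": np.asarray(values, dtype=np.int64),
        }
    )


def _pacing_training_set(rng, n_windows=200, window=24):
    """Separable fixture: near-constant paced vs noisy intrinsic windows."""
    X, y = [], []
    for _ in range(n_windows):
        if rng.uniform() < 0.5:
            w = np.round(rng.normal(80, 0.3, window))
            y.append(True)
        else:
            w = np.round(rng.normal(120, 8, window))
            y.append(False)
        X.append(extract_pacing_features(w))
    return np.array(X), np.array(y)


class TestPlausibility:
    def test_discard_rule_example(self):
        kept, discarded = plausibility_filter(_stream([80, 0, 300, -5, 120]))
        assert kept["value"].tolist() == [80, 120]
        assert discarded == 3

    def test_boundary_values_kept(self):
        kept, discarded = plausibility_filter(_stream([1, 299]))
        assert kept["value"].tolist() == [1, 299]
        assert discarded == 0

    def test_empty_stream(self):
        kept, discarded = plausibility_filter(_stream([]))
        assert len(kept) == 0 and discarded == 0

    @given(st.lists(st.integers(min_value=-50, max_value=350)))
    def test_idempotent_and_count_preserving(self, values):
        stream = _stream(values)
        kept, discarded = plausibility_filter(stream)
        assert len(kept) + discarded == len(stream)
        again, zero = plausibility_filter(kept)
        assert zero == 0
        assert again["value"].tolist() == kept["value"].tolist()


class TestMinimumRecord:
    def test_threshold_boundary(self):
        included = minimum_record_filter({"A": 10_000, "B": 9_999})
        assert included == {"A"}

    def test_empty_cohort(self):
        assert minimum_record_filter({}) == set()

    def test_implied_duration_is_about_fourteen_hours(self):
        hours = min_record_duration_hours()
        assert hours == pytest.approx(10_000 * 5 / 3600)
        assert round(hours) == 14


class TestFeatures:
    def test_constant_window(self):
        f = extract_pacing_features([100] * 24)
        assert f[1] == 0.0  # SD
        assert f[3] == 1.0  # mode fraction

    def test_alternating_window(self):
        f = extract_pacing_features([100, 110] * 12)
        assert f[2] == 10.0  # mean |successive difference|

    def test_matches_direct_recomputation(self, rng):
        w = rng.normal(100, 5, 24)
        f = extract_pacing_features(w)
        assert f[0] == pytest.approx(np.mean(w))
        assert f[1] == pytest.approx(np.std(w))
        assert f[2] == pytest.approx(np.mean(np.abs(np.diff(w))))
        vals, counts = np.unique(w, return_counts=True)
        assert f[3] == pytest.approx(counts.max() / 24)

    def test_windowing_drops_partial_tail(self):
        X, starts = windowed_features(np.arange(50), 24)
        assert X.shape == (2, 4)
        assert starts.tolist() == [0, 24]


class TestTraining:
    def test_separable_features_reach_perfect_training_accuracy(self, rng):
        X, y = _pacing_training_set(rng)
        clf = train_pacing_classifier(X, y, seed=0)
        assert clf.metrics["training_accuracy"] == 1.0

    def test_label_shuffled_data_scores_at_chance(self, rng):
        X, y = _pacing_training_set(rng, n_windows=400)
        y_shuffled = rng.permutation(y)
        clf = train_pacing_classifier(X, y_shuffled, seed=0)
        assert abs(clf.metrics["holdout_accuracy"] - 0.5) < 0.15

    def test_deterministic_under_fixed_seed(self, rng):
        X, y = _pacing_training_set(rng)
        c1 = train_pacing_classifier(X, y, seed=7)
        c2 = train_pacing_classifier(X, y, seed=7)
        for w1, w2 in zip(c1.model.coefs_, c2.model.coefs_):
            np.testing.assert_array_equal(w1, w2)

    def test_single_class_rejected(self):
        X = np.zeros((10, 4))
        with pytest.raises(ValueError):
            train_pacing_classifier(X, np.zeros(10, dtype=bool))


class TestCalibration:
    def test_separable_scores_meet_target_and_exclude_all_paced(self, rng):
        # the threshold is the k-th smallest non-paced score with
        # k = ceil(target * N), so inclusion lands at k/N >= target (not 1.0)
        X, y = _pacing_training_set(rng)
        clf = train_pacing_classifier(X, y, seed=0)
        calibrate_pacing_threshold(clf, X, y)
        assert clf.metrics["non_paced_inclusion_rate"] >= 0.98
        assert clf.metrics["paced_exclusion_rate"] == 1.0

    def test_full_inclusion_admits_every_nonpaced_window(self, rng):
        X, y = _pacing_training_set(rng)
        clf = train_pacing_classifier(X, y, seed=0)
        calibrate_pacing_threshold(clf, X, y, target_inclusion=1.0)
        scores = clf.score(X[~y])
        assert (scores <= clf.threshold).all()

    def test_achieved_inclusion_verified_by_direct_count(self, rng):
        # overlapping classes so the threshold actually bites
        n = 500
        X_paced = np.column_stack(
            [rng.normal(80, 5, n), rng.normal(1, 0.5, n).clip(0),
             rng.normal(1, 0.5, n).clip(0), rng.uniform(0.5, 1, n)]
        )
        X_clean = np.column_stack(
            [rng.normal(110, 10, n), rng.normal(4, 2, n).clip(0),
             rng.normal(4, 2, n).clip(0), rng.uniform(0.05, 0.6, n)]
        )
        X = np.vstack([X_paced, X_clean])
        y = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
        clf = train_pacing_classifier(X, y, seed=1)
        threshold = calibrate_pacing_threshold(clf, X, y, target_inclusion=0.98)
        scores = clf.score(X[~y])
        assert (scores <= threshold).mean() >= 0.98

    def test_invalid_target_rejected(self, rng):
        X, y = _pacing_training_set(rng)
        clf = train_pacing_classifier(X, y, seed=0)
        for bad in (0.0, -0.5, 1.1):
            with pytest.raises(ValueError):
                calibrate_pacing_threshold(clf, X, y, target_inclusion=bad)


class TestApplyFilter:
    def _calibrated(self, rng):
        X, y = _pacing_training_set(rng)
        clf = train_pacing_classifier(X, y, seed=0)
        calibrate_pacing_threshold(clf, X, y)
        return clf

    def test_unpaced_stream_mostly_retained(self, rng):
        clf = self._calibrated(rng)
        stream = _stream(np.round(rng.normal(120, 8, 24 * 50)).astype(int))
        kept, periods = apply_pacing_filter(stream, clf)
        # the >=98% inclusion guarantee holds on the calibration windows;
        # fresh windows see binomial noise around that rate
        assert len(kept) / len(stream) >= 0.90

    def test_fully_paced_stream_mostly_removed(self, rng):
        clf = self._calibrated(rng)
        stream = _stream(np.round(rng.normal(80, 0.3, 24 * 50)).astype(int))
        kept, periods = apply_pacing_filter(stream, clf)
        assert len(kept) < 0.5 * len(stream)
        assert len(periods) > 0

    def test_removal_has_window_boundary_resolution(self, rng):
        clf = self._calibrated(rng)
        clean = np.round(rng.normal(120, 8, 24 * 10)).astype(int)
        paced = np.round(rng.normal(80, 0.3, 24 * 4)).astype(int)
        stream = _stream(np.concatenate([clean, paced, clean]))
        kept, periods = apply_pacing_filter(stream, clf)
        removed = sorted(set(stream.index) - set(kept.index))
        # ground-truth paced block occupies whole windows [240, 336)
        assert removed == list(range(240, 336))

    def test_empty_stream(self, rng):
        clf = self._calibrated(rng)
        kept, periods = apply_pacing_filter(_stream([]), clf)
        assert len(kept) == 0 and len(periods) == 0

    def test_untrained_classifier_rejected(self):
        clf = PacingClassifier()
        with pytest.raises(UntrainedClassifierError):
            apply_pacing_filter(_stream([100] * 48), clf)

    def test_non_hr_stream_rejected(self, rng):
        clf = self._calibrated(rng)
        with pytest.raises(ValueError):
            apply_pacing_filter(_stream([100] * 48, variable="MBP"), clf)
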