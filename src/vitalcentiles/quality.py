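"""Data-quality filters for monitor streams.

Three rules gate samples into the analysis:

1. plausibility — values <= 0 or >= 300 are physically impossible monitor
   outputs and are discarded outright;
2. pacing — stretches of electrically paced heart rate do not reflect the
   intrinsic rate and are removed as whole time periods, flagged by a small
   single-hidden-layer neural network scoring fixed-length windows, with the
   decision threshold calibrated so at least 98% of non-paced windows are
   retained;
3. minimum record — a patient (or patient x age-group subset) must have at
   least 10,000 analyzable samples (~14 h at the 5-s cadence) to contribute
   a stable normalized distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

from .distributions import MIN_OBS_PER_PATIENT_GROUP
from .synthetic import DEFAULT_SAMPLING_INTERVAL_S

PLAUSIBLE_LOWER = 0  # exclusive
PLAUSIBLE_UPPER = 300  # exclusive

DEFAULT_WINDOW_LENGTH = 24  # samples; 2 min at the 5-s cadence
DEFAULT_HIDDEN_UNITS = 8
DEFAULT_TARGET_INCLUSION = 0.98

FEATURE_NAMES = ("mean", "sd", "mean_abs_diff", "mode_fraction")


class UntrainedClassifierError(RuntimeError):
    """Raised when a pacing filter is applied before training/calibration."""


def min_record_duration_hours(
    min_records: int = MIN_OBS_PER_PATIENT_GROUP,
    interval_s: int = DEFAULT_SAMPLING_INTERVAL_S,
) -> float:
    """Recording time implied by the minimum-record rule (~14 h at defaults)."""
    return min_records * interval_s / 3600.0


def plausibility_filter(stream: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep exactly the samples with 0 < value < 300, preserving order."""
    values = stream["value"].to_numpy()
    keep = (values > PLAUSIBLE_LOWER) & (values < PLAUSIBLE_UPPER)
    return stream.loc[keep], int((~keep).sum())


def minimum_record_filter(
    counts: Mapping[str, int], threshold: int = MIN_OBS_PER_PATIENT_GROUP
) -> set[str]:
    """Patients (or subsets) with at least ``threshold`` samples on record."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return {key for key, n in dict(counts).items() if n >= threshold}


def extract_pacing_features(window: Sequence[float]) -> np.ndarray:
    """Window statistics separating paced from intrinsic heart rate.

    Paced rhythm is near-constant: tiny SD, tiny successive differences,
    and one dominant value.  Features: mean, SD, mean |successive
    difference|, fraction of samples equal to the window mode.
    """
    w = np.asarray(window, dtype=float)
    if w.size < 2:
        raise ValueError("pacing feature window needs at least 2 samples")
    values, counts = np.unique(w, return_counts=True)
    mode_fraction = counts.max() / w.size
    return np.array(
        [w.mean(), w.std(), np.abs(np.diff(w)).mean(), mode_fraction]
    )


def windowed_features(
    values: np.ndarray, window_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Features for every full non-overlapping window; returns (X, starts)."""
    values = np.asarray(values, dtype=float)
    n_windows = values.size // window_length
    if n_windows == 0:
        return np.empty((0, len(FEATURE_NAMES))), np.empty(0, dtype=int)
    starts = np.arange(n_windows) * window_length
    X = np.stack(
        [extract_pacing_features(values[s : s + window_length]) for s in starts]
    )
    return X, starts


@dataclass
class PacingClassifier:
    """Single-hidden-layer scorer for paced vs non-paced HR windows."""

    window_length: int = DEFAULT_WINDOW_LENGTH
    hidden_units: int = DEFAULT_HIDDEN_UNITS
    feature_names: tuple[str, ...] = FEATURE_NAMES
    model: Optional[MLPClassifier] = None
    threshold: Optional[float] = None
    metrics: dict = field(default_factory=dict)

    def score(self, X: np.ndarray) -> np.ndarray:
        """Paced probability per window, in [0, 1]."""
        if self.model is None:
            raise UntrainedClassifierError("pacing classifier has not been trained")
        if X.shape[0] == 0:
            return np.empty(0)
        return self.model.predict_proba(X)[:, 1]

    def is_paced(self, X: np.ndarray) -> np.ndarray:
        """Decision per window: paced iff score strictly exceeds the threshold."""
        if self.threshold is None:
            raise UntrainedClassifierError(
                "pacing classifier threshold has not been calibrated"
            )
        return self.score(X) > self.threshold


def train_pacing_classifier(
    X: np.ndarray,
    y_paced: np.ndarray,
    hidden_units: int = DEFAULT_HIDDEN_UNITS,
    seed: int = 0,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    holdout_fraction: float = 0.25,
) -> PacingClassifier:
    """Train the window scorer; deterministic under a fixed seed.

    A stratified hold-out split reports an unbiased accuracy in
    ``metrics["holdout_accuracy"]``; the final model is refit on all data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_paced).astype(int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain both paced and non-paced windows")

    def make_model() -> MLPClassifier:
        return MLPClassifier(
            hidden_layer_sizes=(hidden_units,),
            activation="logistic",
            solver="adam",
            max_iter=2000,
            random_state=seed,
        )

    X_tr, X_ho, y_tr, y_ho = train_test_split(
        X, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    holdout_accuracy = float("nan")
    if np.unique(y_tr).size == 2:
        probe = make_model().fit(X_tr, y_tr)
        holdout_accuracy = float((probe.predict(X_ho) == y_ho).mean())
    model = make_model().fit(X, y)
    clf = PacingClassifier(
        window_length=window_length, hidden_units=hidden_units, model=model
    )
    clf.metrics["training_accuracy"] = float((model.predict(X) == y).mean())
    clf.metrics["holdout_accuracy"] = holdout_accuracy
    return clf


def calibrate_pacing_threshold(
    classifier: PacingClassifier,
    X: np.ndarray,
    y_paced: np.ndarray,
    target_inclusion: float = DEFAULT_TARGET_INCLUSION,
) -> float:
    """Set the decision cutoff from non-paced calibration windows.

    The threshold is the smallest score cutoff that still classifies at
    least ``target_inclusion`` of the non-paced windows as non-paced (score
    <= threshold), i.e. the most aggressive pacing removal compatible with
    the inclusion target.  The achieved paced-exclusion rate is reported in
    ``metrics`` — it depends on the data and is not enforced.
    """
    if not (0.0 < target_inclusion <= 1.0):
        raise ValueError(f"target_inclusion must lie in (0, 1], got {target_inclusion}")
    y = np.asarray(y_paced).astype(bool)
    if not (~y).any():
        raise ValueError("calibration set contains no non-paced windows")
    scores = classifier.score(np.asarray(X, dtype=float))
    nonpaced_scores = np.sort(scores[~y])
    k = math.ceil(target_inclusion * nonpaced_scores.size)
    threshold = float(nonpaced_scores[k - 1])
    classifier.threshold = threshold
    included = float((scores[~y] <= threshold).mean())
    classifier.metrics["non_paced_inclusion_rate"] = included
    if y.any():
        classifier.metrics["paced_exclusion_rate"] = float(
            (scores[y] > threshold).mean()
        )
    else:
        classifier.metrics["paced_exclusion_rate"] = float("nan")
    return threshold


def apply_pacing_filter(
    stream: pd.DataFrame, classifier: PacingClassifier
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove whole windows scored as paced from an HR stream.

    Operates per patient on non-overlapping windows of the classifier's
    window length; a trailing partial window is always retained (it cannot
    be scored).  Returns the kept stream (order and timestamps preserved)
    and a table of removed time periods (patient_id, start, end).
    """
    if classifier.model is None or classifier.threshold is None:
        raise UntrainedClassifierError(
            "apply_pacing_filter requires a trained, calibrated classifier"
        )
    if len(stream) == 0:
        return stream, pd.DataFrame(columns=["patient_id", "start", "end"])
    if not (stream["variable"] == "HR").all():
        raise ValueError("pacing filter applies to HR streams only")
    drop_mask = np.zeros(len(stream), dtype=bool)
    periods = []
    L = classifier.window_length
    positions = np.arange(len(stream))
    for pid, grp in stream.groupby("patient_id", sort=False):
        pos = positions[stream["patient_id"].to_numpy() == pid]
        values = grp["value"].to_numpy()
        times = grp["time"].to_numpy()
        X, starts = windowed_features(values, L)
        if X.shape[0] == 0:
            continue
        paced = classifier.is_paced(X)
        for s, flag in zip(starts, paced):
            if flag:
                drop_mask[pos[s : s + L]] = True
                periods.append(
                    {"patient_id": pid, "start": times[s], "end": times[s + L - 1]}
                )
    kept = stream.loc[~drop_mask]
    return kept, pd.DataFrame(periods, columns=["patient_id", "start", "end"])
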