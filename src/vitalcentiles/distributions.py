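"""Per-patient and per-age-group value distributions.

The unit of analysis is a normalized probability mass function (pmf) over the
integer monitor values 1..299 (the plausibility rule discards <=0 and >=300,
so this support is exhaustive after filtering).  Per-patient pmfs within an
age group are combined by arithmetic mean — every patient carries the same
weight regardless of length of stay, which removes the bias toward long-stay
patients that naive pooling of raw counts would introduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

VARIABLES = ("HR", "SBP", "MBP", "DBP")

#: Integer value support after plausibility filtering.
VALUE_BINS = np.arange(1, 300)

#: Patient x age-group subsets with fewer observations are excluded.
MIN_OBS_PER_PATIENT_GROUP = 10_000

_NORM_TOL = 1e-9


class DegenerateDistributionError(ValueError):
    """Raised when a pmf has zero variance and shape moments are undefined."""


class InsufficientObservationsError(ValueError):
    """Raised when a patient age-group subset falls below the record minimum."""


def _check_pmf(pmf: np.ndarray) -> np.ndarray:
    pmf = np.asarray(pmf, dtype=float)
    if pmf.shape != VALUE_BINS.shape:
        raise ValueError(f"pmf must have {VALUE_BINS.size} bins (values 1..299)")
    if (pmf < 0).any():
        raise ValueError("pmf entries must be non-negative")
    if abs(pmf.sum() - 1.0) > _NORM_TOL:
        raise ValueError(f"pmf must sum to 1 (got {pmf.sum():.12f})")
    return pmf


@dataclass(frozen=True)
class ValueHistogram:
    """Normalized pmf of one vital-sign variable over integer bins 1..299."""

    variable: str
    pmf: np.ndarray
    n_obs: int

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")
        object.__setattr__(self, "pmf", _check_pmf(self.pmf))

    @classmethod
    def from_values(cls, variable: str, values: Sequence[int]) -> "ValueHistogram":
        values = np.asarray(values)
        if values.size == 0:
            raise ValueError("cannot build a histogram from zero observations")
        if (values < 1).any() or (values > 299).any():
            raise ValueError("values outside 1..299; apply the plausibility filter first")
        counts = np.bincount(values.astype(int), minlength=300)[1:300]
        return cls(variable=variable, pmf=counts / counts.sum(), n_obs=int(values.size))

    @property
    def support(self) -> np.ndarray:
        return VALUE_BINS[self.pmf > 0]


@dataclass(frozen=True)
class PatientAgeDistribution:
    patient_id: str
    age_group: str
    histogram: ValueHistogram


@dataclass
class AgeGroupDistribution:
    """Equal-patient-weight aggregate pmf for one (variable, age group)."""

    age_group: str
    variable: str
    pmf: np.ndarray
    n_patients: int
    skewness: float = field(init=False)
    excess_kurtosis: float = field(init=False)
    pmf_smoothed: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pmf = _check_pmf(self.pmf)
        try:
            self.skewness, self.excess_kurtosis = distribution_moments(self.pmf)
        except DegenerateDistributionError:
            self.skewness = float("nan")
            self.excess_kurtosis = float("nan")


def build_patient_distribution(
    patient_id: str,
    age_group: str,
    variable: str,
    values: Sequence[int],
    min_obs: int = MIN_OBS_PER_PATIENT_GROUP,
) -> PatientAgeDistribution:
    """Normalize one patient's observations within one age group.

    Raises :class:`InsufficientObservationsError` when the subset holds fewer
    than ``min_obs`` observations — exclusion is explicit, never silent.
    """
    n = len(values)
    if n < min_obs:
        raise InsufficientObservationsError(
            f"patient {patient_id!r} in group {age_group!r}: "
            f"{n} observations < minimum {min_obs}"
        )
    return PatientAgeDistribution(
        patient_id=patient_id,
        age_group=age_group,
        histogram=ValueHistogram.from_values(variable, values),
    )


def aggregate_equal_weight(
    patient_distributions: Iterable[PatientAgeDistribution],
) -> AgeGroupDistribution:
    """Arithmetic mean of patient pmfs, renormalized.

    Each patient contributes identically regardless of how many observations
    back their pmf.  Mixed variables or age groups are rejected.
    """
    dists = list(patient_distributions)
    if not dists:
        raise ValueError("cannot aggregate an empty collection of patient distributions")
    variables = {d.histogram.variable for d in dists}
    groups = {d.age_group for d in dists}
    if len(variables) != 1:
        raise ValueError(f"mixed variables in aggregation: {sorted(variables)}")
    if len(groups) != 1:
        raise ValueError(f"mixed age groups in aggregation: {sorted(groups)}")
    stacked = np.stack([d.histogram.pmf for d in dists])
    mean_pmf = stacked.mean(axis=0)
    mean_pmf = mean_pmf / mean_pmf.sum()  # guard float drift only
    return AgeGroupDistribution(
        age_group=groups.pop(),
        variable=variables.pop(),
        pmf=mean_pmf,
        n_patients=len(dists),
    )


def smooth_pmf(pmf: np.ndarray, span: float = 0.05) -> np.ndarray:
    """Locally weighted linear regression (LOWESS) of pmf heights over value.

    Smoothing runs over the contiguous integer range between the first and
    last occupied bin, so a pmf constant over its support is reproduced
    exactly.  Negative fitted heights are clipped to zero and the result is
    renormalized.  ``span`` is the LOWESS fraction of the support width.
    """
    pmf = _check_pmf(pmf)
    if not (0.0 < span <= 1.0):
        raise ValueError(f"span must lie in (0, 1], got {span}")
    occupied = np.nonzero(pmf)[0]
    lo, hi = occupied[0], occupied[-1]
    x = VALUE_BINS[lo : hi + 1].astype(float)
    y = pmf[lo : hi + 1]
    if x.size < 3:
        return pmf.copy()
    # local linear fits need at least 3 points in the window
    frac = max(span, min(1.0, 3.0 / x.size))
    # it=0: robustness reweighting is MAD-based and degenerates on noiseless
    # pmf heights (median |residual| ~ 0), which would suppress smoothing.
    fitted = lowess(y, x, frac=frac, it=0, return_sorted=False)
    fitted = np.clip(fitted, 0.0, None)
    out = np.zeros_like(pmf)
    out[lo : hi + 1] = fitted
    total = out.sum()
    if total <= 0:
        raise ValueError("smoothing annihilated the pmf; decrease the span")
    return out / total


def distribution_moments(pmf: np.ndarray) -> tuple[float, float]:
    """Skewness and excess kurtosis of a pmf over the integer bins.

    skewness = mu3 / sigma^3; excess kurtosis = mu4 / sigma^4 - 3, computed
    from exact central moments of the discrete distribution (no sampling).
    """
    pmf = _check_pmf(pmf)
    mean = float(pmf @ VALUE_BINS)
    centered = VALUE_BINS - mean
    var = float(pmf @ centered**2)
    if var <= 0:
        raise DegenerateDistributionError("zero-variance pmf has undefined shape moments")
    mu3 = float(pmf @ centered**3)
    mu4 = float(pmf @ centered**4)
    sigma = np.sqrt(var)
    return mu3 / sigma**3, mu4 / var**2 - 3.0


def pmf_mean_sd(pmf: np.ndarray) -> tuple[float, float]:
    """Mean and standard deviation of a pmf over the integer bins."""
    pmf = _check_pmf(pmf)
    mean = float(pmf @ VALUE_BINS)
    var = float(pmf @ (VALUE_BINS - mean) ** 2)
    return mean, float(np.sqrt(var))
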