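"""Age partition: the 43 target age groups and observation-to-group assignment.

The analysis conditions every distribution on the patient's age at the instant
each observation was recorded.  Two parallel partitions are used:

* ``day_level`` — one group per day of life for the first 30 days (neonatal
  physiology changes fast enough to warrant daily resolution);
* ``coarse`` — 13 non-overlapping groups spanning 0–18 years
  (0–3 m, 3–6 m, 6–9 m, 9–12 m, 12–18 m, 18–24 m, 2–3 y, 3–4 y, 4–6 y,
  6–8 y, 8–12 y, 12–15 y, 15–18 y).

Group membership uses ``(lower, upper]`` intervals — upper-inclusive, so a
child of exactly 2 years belongs to "18-24 months" and a child a day older
belongs to "2-3 years" — except the first group of each kind, which also
includes its lower bound (age zero).  Month/year boundaries are placed with
the fixed conversions 1 month = 365.25/12 days and 1 year = 365.25 days so
that boundary placement never depends on calendar arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime
from typing import Union

import numpy as np
import pandas as pd

DAYS_PER_MONTH = 365.25 / 12.0
DAYS_PER_YEAR = 365.25
SECONDS_PER_DAY = 86_400.0

#: Oldest age (in days) admitted to the analysis: patients must be younger
#: than 18 years at the time of recording.
MAX_AGE_DAYS = 18.0 * DAYS_PER_YEAR

N_DAY_LEVEL_GROUPS = 30
N_COARSE_GROUPS = 13
N_AGE_GROUPS = N_DAY_LEVEL_GROUPS + N_COARSE_GROUPS


class AgeOutOfRangeError(ValueError):
    """Raised for ages outside [0, 18 years]; callers exclude such samples."""


@dataclass(frozen=True)
class AgeGroup:
    """One age interval ``(lower, upper]`` in days.

    The first group of each kind additionally contains its lower bound, so
    age zero has a home in both partitions.
    """

    label: str
    kind: str  # "day_level" or "coarse"
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower >= self.upper:
            raise ValueError(f"degenerate age group {self.label!r}")

    @property
    def is_first_of_kind(self) -> bool:
        return self.lower == 0.0

    @property
    def midpoint_days(self) -> float:
        return 0.5 * (self.lower + self.upper)

    def contains(self, age_days: float) -> bool:
        if self.is_first_of_kind and age_days == 0.0:
            return True
        return self.lower < age_days <= self.upper


_COARSE_SPEC = [
    ("0-3 months", 0.0, 3 * DAYS_PER_MONTH),
    ("3-6 months", 3 * DAYS_PER_MONTH, 6 * DAYS_PER_MONTH),
    ("6-9 months", 6 * DAYS_PER_MONTH, 9 * DAYS_PER_MONTH),
    ("9-12 months", 9 * DAYS_PER_MONTH, 12 * DAYS_PER_MONTH),
    ("12-18 months", 12 * DAYS_PER_MONTH, 18 * DAYS_PER_MONTH),
    ("18-24 months", 18 * DAYS_PER_MONTH, 24 * DAYS_PER_MONTH),
    ("2-3 years", 2 * DAYS_PER_YEAR, 3 * DAYS_PER_YEAR),
    ("3-4 years", 3 * DAYS_PER_YEAR, 4 * DAYS_PER_YEAR),
    ("4-6 years", 4 * DAYS_PER_YEAR, 6 * DAYS_PER_YEAR),
    ("6-8 years", 6 * DAYS_PER_YEAR, 8 * DAYS_PER_YEAR),
    ("8-12 years", 8 * DAYS_PER_YEAR, 12 * DAYS_PER_YEAR),
    ("12-15 years", 12 * DAYS_PER_YEAR, 15 * DAYS_PER_YEAR),
    ("15-18 years", 15 * DAYS_PER_YEAR, 18 * DAYS_PER_YEAR),
]


def enumerate_age_groups() -> list[AgeGroup]:
    """Return the canonical 43 age groups: 30 day-level then 13 coarse.

    Day-level group ``d`` covers ``(d-1, d]`` days, with day 1 also
    containing age 0.
    """
    groups = [
        AgeGroup(label=f"Day {d}", kind="day_level", lower=float(d - 1), upper=float(d))
        for d in range(1, N_DAY_LEVEL_GROUPS + 1)
    ]
    groups.extend(
        AgeGroup(label=label, kind="coarse", lower=lo, upper=hi)
        for label, lo, hi in _COARSE_SPEC
    )
    return groups


def group_table() -> pd.DataFrame:
    """Canonical group table (label, kind, lower_days, upper_days) for export."""
    return pd.DataFrame(
        [(g.label, g.kind, g.lower, g.upper) for g in enumerate_age_groups()],
        columns=["label", "kind", "lower_days", "upper_days"],
    )


TimeLike = Union[datetime, date, np.datetime64, pd.Timestamp, str]


def _to_timestamp(t: TimeLike) -> pd.Timestamp:
    return pd.Timestamp(t)


def age_in_days(timestamp: TimeLike, date_of_birth: TimeLike) -> float:
    """Exact elapsed age in days: (timestamp - birth) / 86,400 s.

    No calendar-month arithmetic is involved; leap years fall out of the
    date arithmetic automatically.  Raises ``AgeOutOfRangeError`` if the
    timestamp precedes birth.
    """
    t = _to_timestamp(timestamp)
    b = _to_timestamp(date_of_birth)
    seconds = (t - b).total_seconds()
    if seconds < 0:
        raise AgeOutOfRangeError("observation timestamp precedes date of birth")
    return seconds / SECONDS_PER_DAY


def ages_in_days(timestamps: np.ndarray, date_of_birth: TimeLike) -> np.ndarray:
    """Vectorized :func:`age_in_days` for a datetime64 array."""
    b = np.datetime64(_to_timestamp(date_of_birth))
    seconds = (timestamps.astype("datetime64[s]") - b.astype("datetime64[s]")).astype(
        "timedelta64[s]"
    ).astype(np.float64)
    if (seconds < 0).any():
        raise AgeOutOfRangeError("observation timestamp precedes date of birth")
    return seconds / SECONDS_PER_DAY


def assign_age_groups(age_days: float) -> list[str]:
    """Labels of every group containing ``age_days``.

    At most one day-level label (ages <= 30 days) plus exactly one coarse
    label.  Ages beyond 18 years raise ``AgeOutOfRangeError``: the study
    excludes such observations rather than binning them.
    """
    if age_days < 0:
        raise AgeOutOfRangeError("negative age")
    if age_days > MAX_AGE_DAYS:
        raise AgeOutOfRangeError(f"age {age_days:.1f} d exceeds 18 years")
    labels: list[str] = []
    if age_days <= N_DAY_LEVEL_GROUPS:
        # day d covers (d-1, d]; age 0 belongs to day 1
        day = max(1, int(np.ceil(age_days)))
        labels.append(f"Day {day}")
    for label, lo, hi in _COARSE_SPEC:
        if (lo < age_days <= hi) or (age_days == 0.0 and lo == 0.0):
            labels.append(label)
            break
    return labels


def assign_coarse_groups(age_days: np.ndarray) -> np.ndarray:
    """Vectorized coarse-group labels; empty string for out-of-range ages."""
    age_days = np.asarray(age_days, dtype=float)
    edges = np.array([lo for _, lo, _ in _COARSE_SPEC] + [_COARSE_SPEC[-1][2]])
    labels = np.array([label for label, _, _ in _COARSE_SPEC])
    # (lower, upper] intervals: side="left" on the upper edges
    idx = np.searchsorted(edges[1:], age_days, side="left")
    out = np.where(
        (age_days >= 0) & (age_days <= MAX_AGE_DAYS), labels[np.minimum(idx, 12)], ""
    )
    return out


def assign_day_groups(age_days: np.ndarray) -> np.ndarray:
    """Vectorized day-level labels; empty string for ages beyond 30 days."""
    age_days = np.asarray(age_days, dtype=float)
    day = np.maximum(1, np.ceil(age_days)).astype(int)
    in_range = (age_days >= 0) & (age_days <= N_DAY_LEVEL_GROUPS)
    out = np.where(in_range, np.char.add("Day ", day.astype(str)), "")
    return out
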