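"""Comparison against published clinical reference ranges.

Clinical guidelines (e.g., PALS) publish per-age lower/upper cutoffs for
heart rate and a hypotension cutoff (an estimated 5th percentile) for
systolic pressure.  Two comparisons are supported:

* fraction-outside — the probability mass of an age-group distribution that
  falls strictly below the lower cutoff or strictly above the upper cutoff
  (a value equal to a cutoff counts as inside);
* percentile difference — derived percentile minus reference cutoff per age
  group, summarized as mean ± SD across groups.

Reference values are user-supplied CSV input, never constants in code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .ages import enumerate_age_groups
from .centiles import CentileTable
from .distributions import VALUE_BINS, AgeGroupDistribution

logger = logging.getLogger(__name__)

REFERENCE_COLUMNS = ["variable", "age_lo_days", "age_hi_days", "lower", "upper"]

_GROUPS_BY_LABEL = {g.label: g for g in enumerate_age_groups()}


class ReferenceValidationError(ValueError):
    """Malformed reference table: overlaps or inverted cutoffs."""


class ReferenceCoverageError(KeyError):
    """No reference row covers the requested age interval."""


@dataclass
class ReferenceRangeTable:
    """Per-variable, per-age clinical cutoffs; intervals are [age_lo, age_hi)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = set(REFERENCE_COLUMNS) - set(df.columns)
        if missing:
            raise ReferenceValidationError(f"missing columns: {sorted(missing)}")
        for _, row in df.iterrows():
            lo, hi = row["lower"], row["upper"]
            if pd.notna(lo) and pd.notna(hi) and lo >= hi:
                raise ReferenceValidationError(
                    f"lower {lo} >= upper {hi} for {row['variable']} "
                    f"at ages [{row['age_lo_days']}, {row['age_hi_days']})"
                )
        for var, grp in df.groupby("variable"):
            g = grp.sort_values("age_lo_days")
            starts = g["age_lo_days"].to_numpy()
            ends = g["age_hi_days"].to_numpy()
            if np.any(ends <= starts):
                raise ReferenceValidationError(f"empty age interval for {var}")
            if np.any(starts[1:] < ends[:-1]):
                raise ReferenceValidationError(f"overlapping age intervals for {var}")

    def row_covering(
        self, variable: str, age_lo: float, age_hi: float
    ) -> pd.Series:
        """The unique row whose age interval contains [age_lo, age_hi]."""
        sub = self.data[self.data["variable"] == variable]
        hit = sub[(sub["age_lo_days"] <= age_lo) & (sub["age_hi_days"] >= age_hi)]
        if len(hit) == 0:
            raise ReferenceCoverageError(
                f"no reference row for {variable} covering ages "
                f"[{age_lo:.2f}, {age_hi:.2f}] days"
            )
        return hit.iloc[0]


def load_reference_table(path: str | Path) -> ReferenceRangeTable:
    """Read and validate a reference CSV (blank lower/upper = absent cutoff)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("reference table %s is empty", path)
        df = pd.DataFrame(columns=REFERENCE_COLUMNS)
    if len(df) == 0:
        logger.warning("reference table %s has no rows", path)
        df = df.reindex(columns=REFERENCE_COLUMNS)
    table = ReferenceRangeTable(data=df)
    _warn_coverage_gaps(table)
    return table


def write_reference_table(table: ReferenceRangeTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False, columns=REFERENCE_COLUMNS)


def _warn_coverage_gaps(table: ReferenceRangeTable) -> None:
    for var, grp in table.data.groupby("variable"):
        g = grp.sort_values("age_lo_days")
        starts = g["age_lo_days"].to_numpy()
        ends = g["age_hi_days"].to_numpy()
        gaps = starts[1:] > ends[:-1]
        if gaps.any():
            logger.warning("age coverage gaps in reference table for %s", var)


def fraction_outside_range(
    dist: AgeGroupDistribution, reference_row: pd.Series
) -> tuple[float, float, float]:
    """PMF mass strictly below / strictly above the cutoffs, and their sum."""
    lower = reference_row.get("lower")
    upper = reference_row.get("upper")
    below = (
        float(dist.pmf[VALUE_BINS < lower].sum()) if pd.notna(lower) else 0.0
    )
    above = (
        float(dist.pmf[VALUE_BINS > upper].sum()) if pd.notna(upper) else 0.0
    )
    return below, above, below + above


def comparison_report(
    distributions: list[AgeGroupDistribution], table: ReferenceRangeTable
) -> pd.DataFrame:
    """Fraction-outside per age group for one variable's distributions."""
    rows = []
    for dist in distributions:
        group = _GROUPS_BY_LABEL[dist.age_group]
        ref = table.row_covering(dist.variable, group.lower, group.upper)
        below, above, total = fraction_outside_range(dist, ref)
        rows.append(
            {
                "variable": dist.variable,
                "age_group": dist.age_group,
                "fraction_below": below,
                "fraction_above": above,
                "fraction_outside": total,
            }
        )
    return pd.DataFrame(rows)


def reference_percentile_difference(
    centiles: CentileTable,
    table: ReferenceRangeTable,
    level: int = 5,
) -> tuple[pd.DataFrame, float, float]:
    """Signed (derived percentile - reference lower cutoff) per age group.

    Returns the per-group table plus the mean and sample SD across groups —
    the summary a guideline comparison reports as mean ± SD.  Every group
    must be covered by a reference row with a lower cutoff.
    """
    col = f"p{level}"
    if col not in centiles.data.columns:
        raise ValueError(f"level {level} not present in centile table")
    rows = []
    for label in centiles.data.index:
        group = _GROUPS_BY_LABEL[label]
        ref = table.row_covering(centiles.variable, group.lower, group.upper)
        if pd.isna(ref["lower"]):
            raise ReferenceCoverageError(
                f"reference row for {centiles.variable} at {label} has no lower cutoff"
            )
        derived = float(centiles.data.loc[label, col])
        rows.append(
            {
                "age_group": label,
                "derived": derived,
                "reference": float(ref["lower"]),
                "difference": derived - float(ref["lower"]),
            }
        )
    df = pd.DataFrame(rows)
    diffs = df["difference"].to_numpy()
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    return df, mean, sd
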