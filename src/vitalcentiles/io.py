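"""CSV readers and writers for streams, metadata, labels, and centile tables.

All formats are plain CSV with documented headers; timestamps are ISO-8601.
Every writer's output is re-readable by the corresponding reader.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .centiles import PERCENTILE_LEVELS, CentileTable
from .distributions import VARIABLES
from .synthetic import LabeledStream

logger = logging.getLogger(__name__)

OBSERVATION_COLUMNS = ["patient_id", "time", "variable", "value"]
METADATA_COLUMNS = ["patient_id", "dob", "sex"]
LABEL_COLUMNS = ["patient_id", "time", "label"]


class ObservationFormatError(ValueError):
    """Malformed observation CSV; message carries the offending line number."""


def read_observations(path: str | Path) -> pd.DataFrame:
    """Parse an observation CSV, sorted by patient then timestamp.

    Columns: patient_id, time (ISO-8601), variable in {HR, SBP, MBP, DBP},
    integer value.  Malformed values and unknown variables raise
    :class:`ObservationFormatError` naming the 1-based file line.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str, "variable": str})
    missing = set(OBSERVATION_COLUMNS) - set(df.columns)
    if missing:
        raise ObservationFormatError(f"{path}: missing columns {sorted(missing)}")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() | (values != np.floor(values))
    if bad.any():
        line = int(df.index[bad][0]) + 2  # +1 header, +1 zero-based
        raise ObservationFormatError(f"{path}: non-integer value field at line {line}")
    df["value"] = values.astype(np.int64)
    unknown = ~df["variable"].isin(VARIABLES)
    if unknown.any():
        line = int(df.index[unknown][0]) + 2
        raise ObservationFormatError(
            f"{path}: unknown variable {df['variable'][unknown].iloc[0]!r} at line {line}"
        )
    times = pd.to_datetime(df["time"], errors="coerce")
    if times.isna().any():
        line = int(df.index[times.isna()][0]) + 2
        raise ObservationFormatError(f"{path}: unparseable timestamp at line {line}")
    df["time"] = times.astype("datetime64[s]")
    per_patient_sorted = (
        df.groupby("patient_id", sort=False)["time"].apply(lambda s: s.is_monotonic_increasing).all()
    )
    if not per_patient_sorted:
        logger.warning("%s: out-of-order timestamps; sorting per patient", path)
    df = df.sort_values(["patient_id", "time"], kind="stable").reset_index(drop=True)
    return df[OBSERVATION_COLUMNS]


def write_observations(stream: pd.DataFrame, path: str | Path) -> None:
    out = stream.copy()
    out["time"] = pd.to_datetime(out["time"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, columns=OBSERVATION_COLUMNS)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "sex": str})
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ObservationFormatError(f"{path}: missing columns {sorted(missing)}")
    df["dob"] = pd.to_datetime(df["dob"]).astype("datetime64[s]")
    return df[METADATA_COLUMNS]


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    out = metadata.copy()
    out["dob"] = pd.to_datetime(out["dob"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, columns=METADATA_COLUMNS)


def write_labels(stream: LabeledStream, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "patient_id": stream.observations["patient_id"],
            "time": pd.to_datetime(stream.observations["time"]).dt.strftime(
                "%Y-%m-%dT%H:%M:%S"
            ),
            "label": stream.labels,
        }
    )
    out.to_csv(path, index=False, columns=LABEL_COLUMNS)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "label": str})
    df["time"] = pd.to_datetime(df["time"]).astype("datetime64[s]")
    return df[LABEL_COLUMNS]


def write_centile_table(table: CentileTable, path: str | Path) -> None:
    """CentileTable CSV: first column age_group, then p1..p99."""
    out = table.data.copy()
    out.insert(0, "age_group", out.index)
    out.to_csv(path, index=False)


def read_centile_table(path: str | Path, variable: str, smoothed: bool) -> CentileTable:
    df = pd.read_csv(path)
    df = df.set_index("age_group")
    df.index.name = None
    df = df[[f"p{p}" for p in PERCENTILE_LEVELS]]
    return CentileTable(variable=variable, data=df, smoothed=smoothed)
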