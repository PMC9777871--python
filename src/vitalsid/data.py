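"""Reading and normalising anaesthesia-monitor case CSV files.

Case files follow the layout of surgical vital-sign exports: two header
lines (a title line, then the column-name line) followed by one data row per
centisecond (100 Hz), so a full 10-minute segment carries 60,000 data rows.
File names follow ``uq_vsd_caseNN_fulldata_MM.csv`` where ``NN`` is the case
and ``MM`` the 1-based 10-minute segment index (segment 04 covers
30:00.00-39:59.99, segment 07 covers 1:00:00.00-1:09:59.99).

Raw vitals are mapped onto [0, 1] by dividing by a per-channel divisor and
capping at 1.0.  Two divisor conventions are supported:

* **comprehensive** — the divisor is the channel maximum over *all* patients'
  training segments (e.g. a heart rate of 53 bpm against a cohort maximum of
  135 bpm normalises to 0.393);
* **isolated** — the divisor is the maximum within the target patient's own
  training segment.

The blood-pressure channel of real exports carries several pressure columns;
the column mapping is configurable and defaults to the mean arterial
pressure.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .network import CHANNELS

__all__ = [
    "DEFAULT_COLUMNS",
    "TEST_FILE_LINES",
    "VitalsSeries",
    "ConversionSpec",
    "read_case_file",
    "compute_divisors",
    "normalize",
    "normalize_rows",
    "select_rows",
    "parse_time_offset",
    "format_time_offset",
]

#: Default CSV column names for each canonical channel.
DEFAULT_COLUMNS: dict[str, str] = {
    "time": "Time",
    "heart_rate": "Heart Rate",
    "etco2": "ETCO2",
    "resp_rate": "Respiratory Rate",
    "blood_pressure": "Mean Arterial Pressure",
}

#: 1-based file-line numbers of the seven evaluation rows (lines 1-2 are
#: headers, so line 3 is the first data row, then every 10,000th file line).
TEST_FILE_LINES = (3, 10_000, 20_000, 30_000, 40_000, 50_000, 60_000)

_CASE_NAME_RE = re.compile(r"uq_vsd_case(\d+)_fulldata_(\d+)\.csv$")

_TIME_RE = re.compile(r"^(?:(\d+):)?(\d+):(\d{2})\.(\d{2})$")


def parse_time_offset(text: str) -> int:
    """Parse ``MM:SS.CC`` or ``H:MM:SS.CC`` into integer centiseconds."""
    m = _TIME_RE.match(text.strip())
    if not m:
        raise ValueError(f"unparseable time offset {text!r}")
    hours = int(m.group(1)) if m.group(1) else 0
    minutes, seconds, centis = int(m.group(2)), int(m.group(3)), int(m.group(4))
    return ((hours * 60 + minutes) * 60 + seconds) * 100 + centis


def format_time_offset(centiseconds: int) -> str:
    """Inverse of :func:`parse_time_offset`; hours shown only when nonzero."""
    cs = int(centiseconds)
    seconds, centis = divmod(cs, 100)
    minutes, seconds = divmod(seconds, 60)
    hours, minutes = divmod(minutes, 60)
    if hours:
        return f"{hours}:{minutes:02d}:{seconds:02d}.{centis:02d}"
    return f"{minutes:02d}:{seconds:02d}.{centis:02d}"


@dataclass
class VitalsSeries:
    """One patient's four-channel series for one 10-minute file segment.

    ``data`` holds columns ``time_cs`` (integer centiseconds from procedure
    start) plus the four canonical channels in engineering units.
    """

    patient_id: str
    segment_id: int
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("time_cs", *CHANNELS) if c not in self.data.columns]
        if missing:
            raise ValueError(f"series is missing columns {missing}")
        t = self.data["time_cs"].to_numpy()
        if len(t) > 1 and not (np.diff(t) > 0).all():
            raise ValueError("time offsets must be strictly increasing")
        vals = self.data[list(CHANNELS)].to_numpy()
        if (vals < 0).any():
            raise ValueError("vital-sign values must be non-negative")

    def __len__(self) -> int:
        return len(self.data)

    def channel(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


@dataclass(frozen=True)
class ConversionSpec:
    """Per-channel divisors realising one normalisation method."""

    method: str  # comprehensive | isolated
    divisors: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.method not in ("comprehensive", "isolated"):
            raise ValueError(f"unknown conversion method {self.method!r}")
        for ch in CHANNELS:
            d = self.divisors.get(ch)
            if d is None or d <= 0:
                raise ValueError(f"divisor for {ch} must be positive, got {d}")


def read_case_file(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    patient_id: str | None = None,
    segment_id: int | None = None,
) -> VitalsSeries:
    """Parse a two-header-line case CSV into a :class:`VitalsSeries`.

    The first file line is a free-text title and is skipped; the second line
    names the columns.  Data therefore begins at file line 3, matching the
    1-based row-numbering convention used for evaluation-row selection.
    Extra columns are tolerated and ignored.
    """
    path = Path(path)
    columns = dict(DEFAULT_COLUMNS, **(columns or {}))
    df = pd.read_csv(path, skiprows=1, dtype=str)
    if df.empty:
        warnings.warn(f"{path.name}: no data rows", stacklevel=2)
    for key in ("time", *CHANNELS):
        col = columns[key]
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing column {col!r}")
    out = pd.DataFrame()
    if len(df):
        out["time_cs"] = df[columns["time"]].map(parse_time_offset)
        for ch in CHANNELS:
            raw = df[columns[ch]]
            vals = pd.to_numeric(raw, errors="coerce")
            if vals.isna().any():
                i = int(vals.index[vals.isna()][0])
                raise ValueError(
                    f"{path.name}: non-numeric value {raw.iloc[i]!r} in column "
                    f"{columns[ch]!r} at file line {i + 3}"
                )
            out[ch] = vals.astype(float)
    else:
        out = pd.DataFrame({c: [] for c in ("time_cs", *CHANNELS)})
    if patient_id is None or segment_id is None:
        m = _CASE_NAME_RE.search(path.name)
        if m:
            patient_id = patient_id or f"case{m.group(1)}"
            segment_id = segment_id if segment_id is not None else int(m.group(2))
        else:
            patient_id = patient_id or path.stem
            segment_id = segment_id if segment_id is not None else 0
    return VitalsSeries(patient_id, segment_id, out)


def compute_divisors(
    cohort: Iterable[VitalsSeries],
    method: str,
    target_patient: str | None = None,
) -> ConversionSpec:
    """Derive per-channel divisors from a set of training segments.

    ``comprehensive`` takes each channel's maximum over every series given;
    ``isolated`` restricts the maxima to the target patient's own series.
    """
    series = list(cohort)
    if not series:
        raise ValueError("cohort must contain at least one series")
    if method == "isolated":
        if target_patient is None:
            raise ValueError("isolated conversion requires a target patient")
        series = [s for s in series if s.patient_id == target_patient]
        if not series:
            raise ValueError(f"no series for target patient {target_patient!r}")
    elif method != "comprehensive":
        raise ValueError(f"unknown conversion method {method!r}")
    divisors: dict[str, float] = {}
    for ch in CHANNELS:
        mx = max(float(s.channel(ch).max()) for s in series if len(s))
        if mx <= 0:
            raise ValueError(
                f"channel {ch} is zero everywhere; divisor would be 0"
            )
        divisors[ch] = mx
    return ConversionSpec(method, divisors)


def normalize(value: float, divisor: float) -> float:
    """``min(value / divisor, 1.0)``; e.g. ``normalize(53, 135) == 0.3925...``"""
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    if value < 0:
        raise ValueError("cannot normalise a negative vital-sign value")
    return min(float(value) / float(divisor), 1.0)


def normalize_rows(rows: pd.DataFrame, spec: ConversionSpec) -> np.ndarray:
    """Vectorised normalisation of a row block to an ``(n, 4)`` array
    in canonical channel order."""
    cols = []
    for ch in CHANNELS:
        v = rows[ch].to_numpy(dtype=float)
        if (v < 0).any():
            raise ValueError(f"negative values in channel {ch}")
        cols.append(np.minimum(v / spec.divisors[ch], 1.0))
    return np.column_stack(cols)


def select_rows(series: VitalsSeries, purpose: str) -> pd.DataFrame:
    """Select the rows a given experiment stage consumes.

    ``training`` returns every row of the segment in time order.  ``test``
    returns exactly the seven rows at file lines
    ``3, 10000, 20000, ..., 60000`` (1-based lines counting the two header
    lines), i.e. 0-based data indices ``line - 3``.
    """
    if purpose == "training":
        return series.data
    if purpose != "test":
        raise ValueError(f"unknown row-selection purpose {purpose!r}")
    idx = [line - 3 for line in TEST_FILE_LINES]
    missing = [
        line for line, i in zip(TEST_FILE_LINES, idx) if i >= len(series)
    ]
    if missing:
        raise ValueError(
            f"segment {series.segment_id} of {series.patient_id} has only "
            f"{len(series)} rows; file lines {missing} are out of range"
        )
    return series.data.iloc[idx]
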