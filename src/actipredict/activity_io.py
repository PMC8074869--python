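"""Minute-granularity wearable activity records: reading, day segmentation, yield.

The unit of raw data is one minute of device output: a step count, a heart
rate (missing whenever the device was not worn or not syncing), and an
optional sleep-stage code.  Days are segmented at local midnight and carry a
*yield* — the fraction of the 1440 expected per-minute heart-rate readings
actually recorded — which is the standard proxy for device wear time.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440

#: sleep stage coding used throughout the package (fixed, documented in the
#: CSV dialect): awake=0, light=1, deep=2, REM=3
SLEEP_STAGES = {"awake": 0, "light": 1, "deep": 2, "rem": 3}

#: yield at or above which a day counts as having high data availability
HIGH_AVAILABILITY_YIELD = 0.5


class ActivityCSVError(ValueError):
    """Malformed activity CSV (bad timestamp, duplicate minute, ...)."""


@dataclass(frozen=True)
class MinuteRecord:
    """One minute of wearable output.

    heart_rate is NaN when the reading is missing; steps is NaN only when the
    device was provably off that minute (no heart rate either), otherwise an
    absent steps cell with heart rate present is read as 0 (a worn device
    reports zero steps, not a gap).
    """

    timestamp: dt.datetime
    steps: float
    heart_rate: float
    sleep_stage: float  # NaN outside sleep episodes

    def __post_init__(self) -> None:
        if not np.isnan(self.steps) and self.steps < 0:
            raise ValueError(f"negative step count at {self.timestamp}")
        if not np.isnan(self.heart_rate) and not (20 < self.heart_rate < 250):
            raise ValueError(
                f"heart rate {self.heart_rate} outside (20, 250) at {self.timestamp}"
            )


@dataclass
class ActivityDay:
    """One calendar day as fixed 1440-slot arrays indexed by minute of day.

    Missing minutes hold NaN in every channel.  ``data_yield`` and
    ``high_availability`` are derived from the heart-rate channel.
    """

    date: dt.date
    steps: np.ndarray
    heart_rate: np.ndarray
    sleep_stage: np.ndarray

    def __post_init__(self) -> None:
        for name in ("steps", "heart_rate", "sleep_stage"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (MINUTES_PER_DAY,):
                raise ValueError(f"{name} must have {MINUTES_PER_DAY} slots")
            setattr(self, name, arr)

    @property
    def data_yield(self) -> float:
        """Fraction of the 1440 expected heart-rate readings present."""
        return float(np.count_nonzero(~np.isnan(self.heart_rate))) / MINUTES_PER_DAY

    @property
    def high_availability(self) -> bool:
        return self.data_yield >= HIGH_AVAILABILITY_YIELD

    def n_records(self) -> int:
        return int(np.count_nonzero(~np.isnan(self.heart_rate) | ~np.isnan(self.steps)
                                    | ~np.isnan(self.sleep_stage)))

    def copy(self) -> "ActivityDay":
        return ActivityDay(self.date, self.steps.copy(), self.heart_rate.copy(),
                           self.sleep_stage.copy())


@dataclass
class PatientRecord:
    """A study participant: clinical characteristics, monitored days, label."""

    patient_id: str
    clinical: dict = field(default_factory=dict)
    days: list = field(default_factory=list)
    outcome: object | None = None  # OutcomeLabel once labeled

    @property
    def monitoring_span(self) -> int:
        if not self.days:
            return 0
        dates = [d.date for d in self.days]
        return (max(dates) - min(dates)).days + 1


def compute_daily_yield(day: ActivityDay) -> float:
    """Fraction of the 1440 expected heart-rate readings present in a day."""
    return day.data_yield


def _parse_float(cell, default=np.nan) -> float:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return default
    return float(cell)


def read_activity_csv(path) -> dict[str, list[MinuteRecord]]:
    """Read a minute-level activity CSV into per-patient sorted record lists.

    Expected columns: patient_id, timestamp (ISO-8601 local), steps,
    heart_rate, sleep_stage.  Empty heart_rate cells mean a missing reading.
    An empty steps cell is 0 if a heart rate is present that minute (device
    worn) and missing otherwise.  Duplicate (patient, timestamp) pairs and
    unparseable timestamps raise :class:`ActivityCSVError` naming the rows.
    """
    df = pd.read_csv(
        path,
        dtype={"patient_id": str},
        keep_default_na=True,
    )
    required = {"patient_id", "timestamp", "steps", "heart_rate", "sleep_stage"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ActivityCSVError(f"missing columns: {sorted(missing_cols)}")

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        # +2: header line plus 1-based indexing
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise ActivityCSVError(f"unparseable timestamp at line(s) {lines}")

    dup_mask = df.assign(_ts=ts).duplicated(subset=["patient_id", "_ts"], keep=False)
    if dup_mask.any():
        idx = np.flatnonzero(dup_mask.to_numpy())
        lines = ", ".join(str(i + 2) for i in idx[:10])
        raise ActivityCSVError(f"duplicate (patient, timestamp) at lines {lines}")

    out: dict[str, list[MinuteRecord]] = {}
    order = np.lexsort((ts.to_numpy(), df["patient_id"].to_numpy()))
    for i in order:
        row = df.iloc[i]
        hr = _parse_float(row["heart_rate"])
        steps = _parse_float(row["steps"])
        if np.isnan(steps) and not np.isnan(hr):
            steps = 0.0
        stage = _parse_float(row["sleep_stage"])
        rec = MinuteRecord(
            timestamp=ts.iloc[i].to_pydatetime().replace(tzinfo=None, second=0,
                                                         microsecond=0),
            steps=steps,
            heart_rate=hr,
            sleep_stage=stage,
        )
        out.setdefault(str(row["patient_id"]), []).append(rec)
    return out


def segment_days(records: list[MinuteRecord]) -> list[ActivityDay]:
    """Partition sorted minute records into calendar days (split at midnight).

    Every record lands in exactly one day; total record count is conserved.
    """
    days: dict[dt.date, ActivityDay] = {}
    for rec in records:
        date = rec.timestamp.date()
        day = days.get(date)
        if day is None:
            nan = np.full(MINUTES_PER_DAY, np.nan)
            day = ActivityDay(date, nan.copy(), nan.copy(), nan.copy())
            days[date] = day
        minute = rec.timestamp.hour * 60 + rec.timestamp.minute
        day.steps[minute] = rec.steps
        day.heart_rate[minute] = rec.heart_rate
        day.sleep_stage[minute] = rec.sleep_stage
    return [days[d] for d in sorted(days)]


def read_clinical_csv(path) -> pd.DataFrame:
    """Read the one-row-per-patient clinical characteristics table."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise ValueError("clinical CSV requires a patient_id column")
    return df.set_index("patient_id")


def write_activity_csv(path, patients: list[PatientRecord]) -> None:
    """Write patients' minute records in the package's activity CSV dialect."""
    rows = []
    for p in patients:
        for day in p.days:
            present = ~np.isnan(day.heart_rate) | ~np.isnan(day.steps) \
                | ~np.isnan(day.sleep_stage)
            for m in np.flatnonzero(present):
                t = dt.datetime.combine(day.date, dt.time(int(m) // 60, int(m) % 60))
                rows.append(
                    (p.patient_id, t.isoformat(),
                     "" if np.isnan(day.steps[m]) else int(day.steps[m]),
                     "" if np.isnan(day.heart_rate[m]) else round(day.heart_rate[m], 1),
                     "" if np.isnan(day.sleep_stage[m]) else int(day.sleep_stage[m]))
                )
    pd.DataFrame(rows, columns=["patient_id", "timestamp", "steps", "heart_rate",
                                "sleep_stage"]).to_csv(path, index=False)
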