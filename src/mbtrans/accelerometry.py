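"""From epoch- or day-level accelerometer records to participant-week compositions.

Epoch-level ENMO (Euclidean Norm Minus One g, in milli-gravitational units)
is classified into sedentary behaviour and light/moderate/vigorous physical
activity with wrist cut-points; epochs inside the supplied sleep window count
as sleep regardless of acceleration, and nonwear epochs are excluded. Days
failing wear-time validity criteria are dropped, and the remaining days are
averaged into one schoolday and one weekend composition per participant.

Raw .gt3x decoding, autocalibration, nonwear detection and algorithmic sleep
detection are upstream concerns: sleep windows and wear flags are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compositions import DAY_MINUTES, PART_NAMES, close

# Wrist ENMO cut-points (mg): SB < 35.6, LPA 35.6-201.4, MPA 201.4-707, VPA > 707
CUTPOINT_LPA = 35.6
CUTPOINT_MPA = 201.4
CUTPOINT_VPA = 707.0

# Day-level wear-time validity thresholds
MIN_SLEEP_MIN = 180.0
MIN_WAKE_MIN = 240.0
MIN_WEAR_MIN = 960.0
MIN_SLEEP_EFFICIENCY = 0.5

__all__ = [
    "DayRecord",
    "ParticipantWeek",
    "classify_intensity",
    "summarise_day",
    "apply_validity",
    "build_participant_week",
    "build_weeks_table",
]


@dataclass
class DayRecord:
    """One participant-day of behaviour minutes plus validity metadata."""

    participant_id: str
    day_type: str  # "schoolday" | "weekend"
    vpa: float
    mpa: float
    lpa: float
    sb: float
    sleep: float
    wear_minutes: float = DAY_MINUTES
    wake_minutes: float | None = None
    sleep_efficiency: float = 1.0
    valid: bool | None = None
    date: object = None

    def __post_init__(self) -> None:
        for name in ("vpa", "mpa", "lpa", "sb", "sleep", "wear_minutes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.sleep_efficiency <= 1.0:
            raise ValueError("sleep_efficiency must be in [0, 1]")
        if self.wake_minutes is None:
            self.wake_minutes = self.vpa + self.mpa + self.lpa + self.sb

    @property
    def minutes(self) -> np.ndarray:
        return np.array([self.vpa, self.mpa, self.lpa, self.sb, self.sleep])


@dataclass
class ParticipantWeek:
    """Averaged schoolday and weekend compositions for one included participant."""

    participant_id: str
    schoolday_composition: np.ndarray
    weekend_composition: np.ndarray
    n_valid_school: int
    n_valid_weekend: int


def classify_intensity(enmo_mg):
    """Classify ENMO values (mg) into behaviour labels by cut-points.

    Vectorised; returns 'sb', 'lpa', 'mpa' or 'vpa' per value. Bins are
    [0, 35.6) -> SB, [35.6, 201.4) -> LPA, [201.4, 707] -> MPA,
    (707, inf) -> VPA. Sleep is handled by the caller via the sleep window.
    """
    e = np.asarray(enmo_mg, dtype=float)
    if np.any(e < 0):
        raise ValueError("ENMO must be nonnegative")
    labels = np.full(e.shape, "sb", dtype=object)
    labels[(e >= CUTPOINT_LPA) & (e < CUTPOINT_MPA)] = "lpa"
    labels[(e >= CUTPOINT_MPA) & (e <= CUTPOINT_VPA)] = "mpa"
    labels[e > CUTPOINT_VPA] = "vpa"
    if np.isscalar(enmo_mg) or np.ndim(enmo_mg) == 0:
        return labels.item()
    return labels


def summarise_day(
    participant_id: str,
    day_type: str,
    enmo_mg: np.ndarray,
    epoch_seconds: float,
    sleep_mask: np.ndarray,
    wear_mask: np.ndarray | None = None,
    sleep_efficiency: float = 1.0,
    date=None,
) -> DayRecord:
    """Aggregate one day's epoch series into a DayRecord.

    ``sleep_mask`` marks epochs inside the sleep window (onset to wake);
    sleep dominates: those epochs are never intensity-classified. Nonwear
    epochs (``wear_mask`` False) contribute to neither wear time nor any
    behaviour. Behaviour minutes are epoch counts times epoch length.
    """
    e = np.asarray(enmo_mg, dtype=float)
    n = e.size
    if n * epoch_seconds > 24 * 3600 + 1e-9:
        raise ValueError("epoch series longer than 24 h")
    sleep_mask = np.asarray(sleep_mask, dtype=bool)
    if wear_mask is None:
        wear_mask = np.ones(n, dtype=bool)
    wear_mask = np.asarray(wear_mask, dtype=bool)
    if sleep_mask.size != n or wear_mask.size != n:
        raise ValueError("mask lengths must match the epoch series")

    per_min = epoch_seconds / 60.0
    awake_worn = wear_mask & ~sleep_mask
    labels = classify_intensity(e[awake_worn])
    counts = {b: float(np.sum(labels == b)) for b in ("vpa", "mpa", "lpa", "sb")}
    sleep_min = float(np.sum(sleep_mask)) * per_min
    wear_min = float(np.sum(wear_mask)) * per_min
    return DayRecord(
        participant_id=participant_id,
        day_type=day_type,
        vpa=counts["vpa"] * per_min,
        mpa=counts["mpa"] * per_min,
        lpa=counts["lpa"] * per_min,
        sb=counts["sb"] * per_min,
        sleep=sleep_min,
        wear_minutes=wear_min,
        wake_minutes=float(np.sum(awake_worn)) * per_min,
        sleep_efficiency=sleep_efficiency,
        date=date,
    )


def apply_validity(day: DayRecord) -> DayRecord:
    """Set the day's validity flag from the wear-time criteria.

    A day is invalid if sleep < 180 min, wake time < 240 min, total wear
    < 960 min, or sleep efficiency < 0.5. Idempotent.
    """
    day.valid = not (
        day.sleep < MIN_SLEEP_MIN
        or (day.wake_minutes or 0.0) < MIN_WAKE_MIN
        or day.wear_minutes < MIN_WEAR_MIN
        or day.sleep_efficiency < MIN_SLEEP_EFFICIENCY
    )
    return day


def build_participant_week(days: list[DayRecord]) -> ParticipantWeek | None:
    """Average one participant's valid days into schoolday/weekend compositions.

    Inclusion requires at least 5 valid days with at least 3 valid schooldays
    and both weekend days. Averaging is arithmetic per behaviour over valid
    days of each day type, then closed to 1440 min. Returns None for an
    excluded participant.
    """
    if not days:
        return None
    pid = days[0].participant_id
    if any(d.participant_id != pid for d in days):
        raise ValueError("days from multiple participants")
    dates = [d.date for d in days if d.date is not None]
    if len(dates) != len(set(dates)):
        raise ValueError("duplicate dates for participant " + str(pid))
    for d in days:
        if d.valid is None:
            apply_validity(d)
    valid = [d for d in days if d.valid]
    school = [d for d in valid if d.day_type == "schoolday"]
    weekend = [d for d in valid if d.day_type == "weekend"]
    if len(valid) < 5 or len(school) < 3 or len(weekend) < 2:
        return None
    school_mean = close(np.mean([d.minutes for d in school], axis=0))
    weekend_mean = close(np.mean([d.minutes for d in weekend], axis=0))
    return ParticipantWeek(
        participant_id=pid,
        schoolday_composition=school_mean,
        weekend_composition=weekend_mean,
        n_valid_school=len(school),
        n_valid_weekend=len(weekend),
    )


def build_weeks_table(day_df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised participant-week construction from a day-level table.

    Expects columns participant_id, date, day_type, vpa_min, mpa_min,
    lpa_min, sb_min, sleep_min and optionally wear_min, wake_min, sleep_eff.
    Returns one row per included participant with schoolday_/weekend_
    prefixed behaviour columns (minutes, closed to 1440).
    """
    df = day_df.copy()
    for col, default in (("wear_min", DAY_MINUTES), ("sleep_eff", 1.0)):
        if col not in df:
            df[col] = default
    if "wake_min" not in df:
        df["wake_min"] = df[["vpa_min", "mpa_min", "lpa_min", "sb_min"]].sum(axis=1)
    rows = []
    for pid, grp in df.groupby("participant_id", sort=True):
        days = [
            DayRecord(
                participant_id=str(pid),
                day_type=r.day_type,
                vpa=r.vpa_min,
                mpa=r.mpa_min,
                lpa=r.lpa_min,
                sb=r.sb_min,
                sleep=r.sleep_min,
                wear_minutes=r.wear_min,
                wake_minutes=r.wake_min,
                sleep_efficiency=r.sleep_eff,
                date=r.date if "date" in df else None,
            )
            for r in grp.itertuples()
        ]
        week = build_participant_week(days)
        if week is None:
            continue
        row = {"participant_id": str(pid)}
        for prefix, comp in (
            ("schoolday", week.schoolday_composition),
            ("weekend", week.weekend_composition),
        ):
            for name, val in zip(PART_NAMES, comp):
                row[f"{prefix}_{name}_min"] = val
        row["n_valid_school"] = week.n_valid_school
        row["n_valid_weekend"] = week.n_valid_weekend
        rows.append(row)
    return pd.DataFrame(rows)
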