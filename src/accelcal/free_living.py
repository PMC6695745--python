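"""Free-living epoch classification and time-in-intensity summaries.

Processing rules: explicit non-wear flags take precedence, otherwise a
low-variance run rule (>= 60 min with all raw-axis SD < 3 mg) marks
non-wear; epochs starting in the [23:00, 06:00) night window are removed;
a day is valid with >= 720 wear minutes. Intensity intervals are closed on
the left: an epoch at exactly a cut-point belongs to that level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CutPointTable, LEVELS
from .errors import ConfigError, DataError
from .signal_processing import EpochSeries, TriaxialRecording

#: All intensity levels, lowest first (SED = below the LPA cut-point).
ALL_LEVELS = ("SED",) + LEVELS
MVPA_LEVELS = ("MPA", "VPA", "VVPA")

#: Free-living age -> cut-point group mapping (calibration groups).
def cutpoint_group_for_age(age: float) -> str:
    if age < 13:
        return "children"
    if age <= 16:
        return "adolescents"
    return "adults"


#: Free-living reporting categories.
def age_category(age: float) -> str:
    if age < 13:
        return "children"
    if age <= 16:
        return "adolescents"
    if age < 50:
        return "adults_lt50"
    return "adults_ge50"


AGE_CATEGORIES = ("children", "adolescents", "adults_lt50", "adults_ge50")


@dataclass
class WearDay:
    subject_id: str
    date: object  # datetime.date
    wear_minutes: float
    minutes_by_level: dict[str, float]
    valid: bool

    def __post_init__(self) -> None:
        total = sum(self.minutes_by_level.values())
        if abs(total - self.wear_minutes) > 1e-6:
            raise DataError(
                f"level minutes {total} != wear minutes {self.wear_minutes}")

    def percent_by_level(self) -> dict[str, float]:
        if self.wear_minutes == 0:
            return {lv: 0.0 for lv in ALL_LEVELS}
        return {lv: 100.0 * m / self.wear_minutes
                for lv, m in self.minutes_by_level.items()}


@dataclass
class GroupSummary:
    """Mean (SD) daily minutes and % of wear time per level per age category."""

    n_by_category: dict[str, int]
    mean_minutes: dict[str, dict[str, float]]  # category -> level -> min/d
    sd_minutes: dict[str, dict[str, float]]
    mean_percent: dict[str, dict[str, float]]
    sd_percent: dict[str, dict[str, float]]
    mvpa_minutes: dict[str, float] = field(default_factory=dict)
    mvpa_percent: dict[str, float] = field(default_factory=dict)


def mvpa_total(by_level: Mapping[str, float]) -> float:
    """MVPA aggregation rule: MPA + VPA + VVPA."""
    return float(sum(by_level[lv] for lv in MVPA_LEVELS))


def detect_nonwear(series: EpochSeries,
                   raw: TriaxialRecording | None = None,
                   explicit: np.ndarray | None = None,
                   min_run_minutes: float = 60.0,
                   sd_threshold_mg: float = 3.0) -> EpochSeries:
    """Set wear flags on ``series``.

    An ``explicit`` per-epoch non-wear flag (True = non-wear) takes
    precedence. Otherwise, per-epoch raw-axis standard deviations are
    computed from ``raw`` and epochs inside any run of at least
    ``min_run_minutes`` where all three axes stay below ``sd_threshold_mg``
    are flagged non-wear. Without either input the series is returned
    unchanged.
    """
    if explicit is not None:
        explicit = np.asarray(explicit, dtype=bool)
        if len(explicit) != len(series):
            raise DataError("explicit non-wear flags length mismatch")
        return EpochSeries(series.epoch_length, series.times,
                           series.intensity, ~explicit)
    if raw is None:
        return series

    spe = int(round(series.epoch_length * raw.sample_rate))
    n = min(len(series), len(raw) // spe)
    axes = raw.axes()[: n * spe].reshape(n, spe, 3)
    sds_mg = axes.std(axis=1) * 1000.0
    low = (sds_mg < sd_threshold_mg).all(axis=1)

    wear = series.wear.copy()
    min_run = int(np.ceil(min_run_minutes * 60.0 / series.epoch_length))
    # find runs of consecutive low-variance epochs
    padded = np.concatenate([[False], low, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            wear[s:e] = False
    return EpochSeries(series.epoch_length, series.times, series.intensity, wear)


def exclude_night(series: EpochSeries,
                  night: tuple[int, int] = (23, 6)) -> EpochSeries:
    """Drop epochs whose start falls in the half-open night window.

    The window runs from ``night[0]:00`` (inclusive) to ``night[1]:00``
    (exclusive), crossing midnight when start > end.
    """
    times = pd.DatetimeIndex(series.times)
    start_h, end_h = night
    sec = times.hour * 3600 + times.minute * 60 + times.second
    lo, hi = start_h * 3600, end_h * 3600
    if lo > hi:  # crosses midnight
        in_night = (sec >= lo) | (sec < hi)
    else:
        in_night = (sec >= lo) & (sec < hi)
    return series.subset(~np.asarray(in_night))


def classify_epochs(series: EpochSeries,
                    cutpoints: Mapping[str, float]) -> np.ndarray:
    """Per-epoch intensity level from mg thresholds (closed on the left).

    ``cutpoints`` maps LPA/MPA/VPA/VVPA to mg thresholds; intensity below
    the LPA threshold is SED. Returns an array of level names.
    """
    thresholds = np.array([cutpoints[lv] for lv in LEVELS], dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ConfigError(f"cut-points must be strictly increasing: {cutpoints}")
    idx = np.searchsorted(thresholds, series.intensity, side="right")
    return np.asarray(ALL_LEVELS, dtype=object)[idx]


def summarize_day(subject_id: str, date, levels: Sequence[str],
                  wear: np.ndarray, epoch_length: float,
                  valid_minutes: float = 720.0) -> WearDay:
    """Minutes per level over wear epochs of one calendar day."""
    levels = np.asarray(levels, dtype=object)
    wear = np.asarray(wear, dtype=bool)
    if len(levels) != len(wear):
        raise DataError("levels and wear flags length mismatch")
    per_epoch_min = epoch_length / 60.0
    minutes = {lv: float(np.sum(wear & (levels == lv))) * per_epoch_min
               for lv in ALL_LEVELS}
    wear_min = float(wear.sum()) * per_epoch_min
    return WearDay(subject_id, date, wear_min, minutes,
                   valid=wear_min >= valid_minutes)


def summarize_days(series: EpochSeries, levels: np.ndarray, subject_id: str,
                   valid_minutes: float = 720.0) -> list[WearDay]:
    """Split a classified epoch series into calendar-day summaries."""
    days = np.asarray(series.times, dtype="datetime64[ns]").astype("datetime64[D]")
    out = []
    for day in np.unique(days):
        m = days == day
        out.append(summarize_day(subject_id, pd.Timestamp(day).date(),
                                 levels[m], series.wear[m],
                                 series.epoch_length, valid_minutes))
    return out


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    if len(values) == 0:
        return float("nan"), float("nan")
    if len(values) == 1:
        return float(values[0]), 0.0
    return float(values.mean()), float(values.std(ddof=1))


def summarize_group(days: Iterable[WearDay],
                    ages: Mapping[str, float],
                    min_valid_days: int = 1) -> GroupSummary:
    """Per-subject mean over valid days, then mean (SD) per age category.

    Subjects with fewer than ``min_valid_days`` valid days are excluded.
    """
    import warnings

    by_subject: dict[str, list[WearDay]] = {}
    for d in days:
        if d.valid:
            by_subject.setdefault(d.subject_id, []).append(d)

    subject_rows: dict[str, tuple[str, dict[str, float], dict[str, float]]] = {}
    for sid, age in ages.items():
        valid = by_subject.get(sid, [])
        if len(valid) < min_valid_days:
            warnings.warn(f"subject {sid}: {len(valid)} valid day(s), excluded")
            continue
        mins = {lv: float(np.mean([d.minutes_by_level[lv] for d in valid]))
                for lv in ALL_LEVELS}
        pcts = {lv: float(np.mean([d.percent_by_level()[lv] for d in valid]))
                for lv in ALL_LEVELS}
        subject_rows[sid] = (age_category(age), mins, pcts)

    summary = GroupSummary({}, {}, {}, {}, {})
    for cat in AGE_CATEGORIES:
        rows = [(m, p) for c, m, p in subject_rows.values() if c == cat]
        if not rows:
            continue
        summary.n_by_category[cat] = len(rows)
        summary.mean_minutes[cat] = {}
        summary.sd_minutes[cat] = {}
        summary.mean_percent[cat] = {}
        summary.sd_percent[cat] = {}
        for lv in ALL_LEVELS:
            mu, sd = _mean_sd(np.array([m[lv] for m, _ in rows]))
            summary.mean_minutes[cat][lv] = mu
            summary.sd_minutes[cat][lv] = sd
            mu, sd = _mean_sd(np.array([p[lv] for _, p in rows]))
            summary.mean_percent[cat][lv] = mu
            summary.sd_percent[cat][lv] = sd
        summary.mvpa_minutes[cat] = mvpa_total(summary.mean_minutes[cat])
        summary.mvpa_percent[cat] = mvpa_total(summary.mean_percent[cat])
    return summary


def classify_subject_week(series: EpochSeries, age: float,
                          table: CutPointTable, method: str,
                          placement: str = "hip",
                          subject_id: str = "",
                          night: tuple[int, int] = (23, 6),
                          valid_minutes: float = 720.0) -> list[WearDay]:
    """Night-exclude, classify and summarize one subject's epoch series."""
    group = cutpoint_group_for_age(age)
    cuts = table.cell(placement, group, method)
    day_series = exclude_night(series, night)
    wear_series = day_series.subset(day_series.wear)
    levels = classify_epochs(wear_series, cuts)
    return summarize_days(wear_series, levels, subject_id, valid_minutes)
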