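"""Dark-cycle activity features and the Digital Arthritis Index (DAI).

The DAI converts continuous home-cage speed traces into a per-animal,
per-day disease score.  For each study day a *salient feature* is
extracted from the dark-cycle (lights-off) speed samples — by default
the 99th percentile of per-minute speeds, a robust stand-in for the
maximum speed of motion.  Each animal's features are normalized to its
own pre/post-induction baseline window (study days -2..5 excluding the
induction day 0), and the DAI on day *d* is

    DAI_d = max(0, K * (1 - feature_d / baseline)),    K = 20 by default

so DAI = 0 at baseline activity and rises as activity falls; the
disease-calling threshold of 5 corresponds to a 25% activity drop.

Night attribution: the dark period that begins at lights-off on the
calendar date of study day *d* belongs entirely to day *d*, including
the post-midnight portion.
"""
from __future__ import annotations

import math
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .config import FeatureConfig, LightSchedule, StudyCalendar
from .containers import ActivityTrace, BaselineStats
from .errors import BaselineError, ConfigurationError, DaindexError

__all__ = [
    "assign_study_day",
    "label_samples",
    "nearest_rank_percentile",
    "daily_salient_feature",
    "daily_features",
    "baseline_feature",
    "compute_dai",
    "dai_series",
    "mean_night_motion",
    "percent_decrease",
]


def _minutes_of_day(times: pd.DatetimeIndex) -> np.ndarray:
    return times.hour * 60 + times.minute + times.second / 60.0


def label_samples(
    timestamps: pd.DatetimeIndex | pd.Series,
    calendar: StudyCalendar,
    schedule: LightSchedule,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (study_day, is_dark) labels for sample timestamps.

    Dark samples after midnight are attributed to the study day whose
    night they belong to (the previous calendar day for a schedule whose
    dark period spans midnight).
    """
    ts = pd.DatetimeIndex(pd.to_datetime(timestamps))
    if schedule.lights_on == schedule.lights_off:
        raise ConfigurationError("degenerate light schedule")
    on = schedule.lights_on.hour * 60 + schedule.lights_on.minute
    off = schedule.lights_off.hour * 60 + schedule.lights_off.minute
    tod = _minutes_of_day(ts)
    day = (ts.normalize() - pd.Timestamp(calendar.induction_date)).days.to_numpy()
    if on < off:
        # dark period wraps midnight: [off, 24h) belongs to this day,
        # [0, on) to the previous day's night
        evening = tod >= off
        morning = tod < on
        dark = evening | morning
        day = np.where(morning, day - 1, day)
    else:
        dark = (tod >= off) & (tod < on)
    return day.astype(int), np.asarray(dark)


def assign_study_day(
    timestamp,
    calendar: StudyCalendar,
    schedule: LightSchedule,
) -> int:
    """Study day an instant belongs to (night hours follow their lights-off day).

    Raises ``DaindexError`` for timestamps before the study range.
    """
    day, _ = label_samples(pd.DatetimeIndex([pd.Timestamp(timestamp)]), calendar, schedule)
    d = int(day[0])
    if d < calendar.study_start_day:
        raise DaindexError(f"timestamp {timestamp} precedes study day {calendar.study_start_day}")
    return d


def nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th smallest value."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        return math.nan
    k = max(1, math.ceil(pct / 100.0 * n))
    return float(v[k - 1])


_METHODS = {
    "q99": lambda v: nearest_rank_percentile(v, 99),
    "max": lambda v: float(np.max(v)),
    "mean": lambda v: float(np.mean(v)),
}


def _per_minute_dark(
    trace: ActivityTrace, calendar: StudyCalendar, schedule: LightSchedule
) -> pd.DataFrame:
    """Per-minute mean dark-cycle speeds with study-day labels."""
    s = trace.samples
    ts = pd.DatetimeIndex(pd.to_datetime(s["timestamp"]))
    day, dark = label_samples(ts, calendar, schedule)
    sub = pd.DataFrame(
        {
            "study_day": day[dark],
            "minute": ts[dark].floor("min"),
            "speed": s["speed_mm_s"].to_numpy(dtype=float)[dark],
        }
    )
    return sub.groupby(["study_day", "minute"], as_index=False)["speed"].mean()


def daily_features(
    trace: ActivityTrace,
    calendar: StudyCalendar,
    schedule: LightSchedule,
    method: str = "q99",
    min_coverage: float = 0.5,
    days: Optional[Iterable[int]] = None,
) -> pd.DataFrame:
    """Daily salient features for all (or the given) study days.

    Returns a DataFrame (animal_id, study_day, value, coverage); the
    value is NaN when dark-cycle coverage falls below ``min_coverage``.
    """
    if method not in _METHODS:
        raise ConfigurationError(f"unknown feature method {method!r}")
    feat = _METHODS[method]
    expected = schedule.dark_minutes
    per_min = _per_minute_dark(trace, calendar, schedule)
    if days is None:
        days = range(calendar.study_start_day, calendar.final_day + 1)
    grouped = {int(d): g["speed"].to_numpy() for d, g in per_min.groupby("study_day")}
    rows = []
    for d in days:
        v = grouped.get(int(d), np.empty(0))
        coverage = len(v) / expected
        value = feat(v) if (len(v) and coverage >= min_coverage) else math.nan
        rows.append((trace.animal_id, int(d), value, coverage))
    return pd.DataFrame(rows, columns=["animal_id", "study_day", "value", "coverage"])


def daily_salient_feature(
    trace: ActivityTrace,
    day: int,
    calendar: StudyCalendar,
    schedule: LightSchedule,
    method: str = "q99",
    min_coverage: float = 0.5,
) -> pd.Series:
    """Salient feature for a single study day (row of :func:`daily_features`)."""
    if not len(trace.samples):
        raise DaindexError("empty activity trace")
    df = daily_features(trace, calendar, schedule, method, min_coverage, days=[day])
    return df.iloc[0]


def baseline_feature(
    features: pd.DataFrame,
    calendar: StudyCalendar,
    min_baseline_days: int = 3,
) -> BaselineStats:
    """Baseline aggregate: mean of non-missing window features, day 0 excluded.

    Raises :class:`BaselineError` when fewer than ``min_baseline_days``
    usable days exist (the animal must be excluded from DAI scoring).
    """
    window = set(calendar.baseline_days)
    sub = features[features["study_day"].isin(window)]
    vals = sub["value"].dropna()
    if len(vals) < min_baseline_days:
        raise BaselineError(
            f"{_animal_of(features)}: only {len(vals)} usable baseline days "
            f"(need {min_baseline_days})"
        )
    baseline = float(vals.mean())
    if baseline <= 0:
        raise BaselineError(f"{_animal_of(features)}: non-positive baseline feature")
    return BaselineStats(_animal_of(features), baseline, int(len(vals)))


def _animal_of(features: pd.DataFrame) -> str:
    return str(features["animal_id"].iloc[0]) if len(features) else "?"


def compute_dai(value: float, baseline_value: float, scale_k: float = 20.0) -> float:
    """DAI for one day: ``max(0, K * (1 - value/baseline))``.

    A missing (NaN) daily value propagates to a missing DAI.
    """
    if baseline_value <= 0:
        raise DaindexError("baseline_value must be positive")
    if math.isnan(value):
        return math.nan
    return max(0.0, scale_k * (1.0 - value / baseline_value))


def dai_series(
    features: pd.DataFrame,
    baseline: BaselineStats,
    scale_k: float = 20.0,
) -> pd.DataFrame:
    """Per-day DAI table (animal_id, study_day, dai, coverage)."""
    out = features.copy()
    out["dai"] = [
        compute_dai(v, baseline.baseline_value, scale_k) for v in out["value"]
    ]
    return out[["animal_id", "study_day", "dai", "coverage"]]


def mean_night_motion(
    trace: ActivityTrace,
    days: Iterable[int],
    calendar: StudyCalendar,
    schedule: LightSchedule,
) -> float:
    """Mean dark-cycle speed pooled over the listed study days (mm/s)."""
    s = trace.samples
    ts = pd.DatetimeIndex(pd.to_datetime(s["timestamp"]))
    day, dark = label_samples(ts, calendar, schedule)
    mask = dark & np.isin(day, list(days))
    v = s["speed_mm_s"].to_numpy(dtype=float)[mask]
    return float(np.mean(v)) if len(v) else math.nan


def percent_decrease(before: float, after: float) -> int:
    """Percent drop from *before* to *after*, rounded half-up to an integer."""
    if before <= 0:
        raise DaindexError("before must be positive")
    return int(math.floor(100.0 * (before - after) / before + 0.5))


def compute_dai_table(
    traces: dict[str, ActivityTrace],
    calendar: StudyCalendar,
    schedule: LightSchedule,
    feature_cfg: FeatureConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[str]]:
    """Run feature extraction + DAI for a whole cohort.

    Returns (features, dai, baselines, excluded_ids); animals without a
    valid baseline are excluded and listed rather than failing the run.
    """
    feats, dais, bases, excluded = [], [], [], []
    for animal_id in sorted(traces):
        f = daily_features(
            traces[animal_id], calendar, schedule,
            method=feature_cfg.method, min_coverage=feature_cfg.min_coverage,
        )
        feats.append(f)
        try:
            b = baseline_feature(f, calendar, feature_cfg.min_baseline_days)
        except BaselineError:
            excluded.append(animal_id)
            continue
        bases.append({"animal_id": animal_id, "baseline_value": b.baseline_value,
                      "n_days_used": b.n_days_used})
        dais.append(dai_series(f, b, feature_cfg.scale_k))
    features = pd.concat(feats, ignore_index=True) if feats else pd.DataFrame(
        columns=["animal_id", "study_day", "value", "coverage"])
    dai = pd.concat(dais, ignore_index=True) if dais else pd.DataFrame(
        columns=["animal_id", "study_day", "dai", "coverage"])
    baselines = pd.DataFrame(bases, columns=["animal_id", "baseline_value", "n_days_used"])
    return features, dai, baselines, excluded
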