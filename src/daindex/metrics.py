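"""Threshold-based disease calling for any per-day metric.

Incidence, onset, severity, cumulative burden, and humane-endpoint
censoring are defined identically for the DAI, ankle joint size and the
arthritis score; only the threshold and the severity convention differ:

* incidence — the metric is *strictly* greater than its threshold on
  any observed study day;
* onset — the earliest day the metric is consistently above threshold,
  operationalized as above on day d and on day d+1 (or d is the last
  observed day);
* severity — the metric value on the final study day or at humane
  endpoint; joint-size severity is the change from induction day 0.
"""
from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd

from .config import EndpointRule, StudyCalendar, ThresholdConfig
from .containers import AnimalOutcome, ClinicalRecord
from .errors import DaindexError

__all__ = [
    "detect_onset",
    "call_incidence",
    "severity_at_end",
    "cumulative_over_threshold",
    "apply_humane_endpoint",
    "animal_outcomes",
]


def _clean(series: pd.Series) -> pd.Series:
    s = pd.Series(series).dropna().sort_index()
    if s.empty:
        raise DaindexError("metric series has no observed days")
    return s


def detect_onset(series: pd.Series, threshold: float) -> Optional[int]:
    """Earliest day consistently above threshold, or None.

    "Consistently" means above on day d and on the next calendar day
    d+1; a final observed day above threshold also qualifies (no later
    observation can contradict it).  An unsustained single-day blip is
    never an onset.
    """
    s = _clean(series)
    days = s.index.to_numpy()
    vals = s.to_numpy(dtype=float)
    for i, d in enumerate(days):
        if vals[i] > threshold:
            if i == len(days) - 1:
                return int(d)
            if days[i + 1] == d + 1 and vals[i + 1] > threshold:
                return int(d)
    return None


def call_incidence(series: pd.Series, threshold: float) -> bool:
    """True iff any observed value is strictly above the threshold."""
    s = _clean(series)
    return bool((s.to_numpy(dtype=float) > threshold).any())


def severity_at_end(
    series: pd.Series,
    censor_day: Optional[int],
    metric_kind: str = "value",
    final_day: Optional[int] = None,
) -> float:
    """Metric value at the last study day or at humane endpoint.

    ``metric_kind="joint_size"`` reports the change from induction day 0
    instead of the raw value; day 0 must then be observed.  When the end
    day itself is unobserved the last prior observation is used.
    """
    s = _clean(series)
    end = censor_day
    if end is None:
        end = final_day if final_day is not None else int(s.index.max())
    upto = s[s.index <= end]
    if upto.empty:
        raise DaindexError(f"no observation at or before end day {end}")
    value = float(upto.iloc[-1])
    if metric_kind == "joint_size":
        if 0 not in s.index:
            raise DaindexError("joint-size severity needs a day-0 measurement")
        return value - float(s.loc[0])
    return value


def cumulative_over_threshold(series: pd.Series, threshold: float) -> float:
    """Sum over observed days of the excess above threshold (clamped at 0)."""
    s = pd.Series(series).dropna()
    if s.empty:
        return 0.0
    return float(np.maximum(0.0, s.to_numpy(dtype=float) - threshold).sum())


def apply_humane_endpoint(
    record: ClinicalRecord, rule: EndpointRule
) -> Optional[int]:
    """Earliest humane-endpoint day for an animal, or None.

    Criteria: either ankle joint >= ``joint_limit_in`` (inclusive); any
    hind paw at the maximal score 4 on ``max_score_days`` consecutive
    daily observations (>48 h, censored at the run's last required day);
    or body weight below (1 - weight_loss_fraction) of the baseline
    (day-0, else earliest) weight.
    """
    candidates: list[int] = []

    left = record.metric_series("joint_left_in")
    right = record.metric_series("joint_right_in")
    joint = pd.concat([left, right], axis=1).max(axis=1).dropna()
    hits = joint[joint >= rule.joint_limit_in]
    if not hits.empty:
        candidates.append(int(hits.index.min()))

    pl = record.metric_series("paw_score_left")
    pr = record.metric_series("paw_score_right")
    maxed = (
        pd.concat([pl, pr], axis=1)
        .max(axis=1)
        .dropna()
        .eq(4.0)
    )
    run = 0
    prev_day = None
    for day, flag in maxed.items():
        run = run + 1 if (flag and prev_day is not None and day == prev_day + 1) else (1 if flag else 0)
        prev_day = int(day)
        if run >= rule.max_score_days:
            candidates.append(int(day))
            break

    weight = record.metric_series("body_weight_g").dropna()
    if not weight.empty:
        base = float(weight.loc[0]) if 0 in weight.index else float(weight.iloc[0])
        low = weight[weight < (1.0 - rule.weight_loss_fraction) * base]
        if not low.empty:
            candidates.append(int(low.index.min()))

    return min(candidates) if candidates else None


def _metric_day_series(
    animal_id: str,
    metric: str,
    dai: pd.DataFrame,
    record: Optional[ClinicalRecord],
) -> pd.Series:
    from .clinical import arthritis_score_series, joint_size_series  # local: avoid cycle

    if metric == "dai":
        sub = dai[dai["animal_id"] == animal_id]
        return pd.Series(sub["dai"].to_numpy(), index=sub["study_day"].to_numpy())
    if record is None:
        raise DaindexError(f"{animal_id}: no clinical record for metric {metric}")
    if metric == "joint_size":
        return joint_size_series(record)
    if metric == "arthritis_score":
        return arthritis_score_series(record)
    raise DaindexError(f"unknown metric {metric!r}")


def animal_outcomes(
    dai: pd.DataFrame,
    clinical: dict[str, ClinicalRecord],
    thresholds: ThresholdConfig,
    endpoint: EndpointRule,
    calendar: StudyCalendar,
    animal_ids: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Per-animal, per-metric outcome table.

    Columns: animal_id, metric, arthritic, onset_day, severity,
    censor_day.  Series are truncated at the censor day before calling
    incidence and onset, so post-euthanasia values never contribute.
    """
    if animal_ids is None:
        animal_ids = sorted(set(dai["animal_id"]).union(clinical))
    rows: list[AnimalOutcome] = []
    for animal_id in animal_ids:
        record = clinical.get(animal_id)
        censor = apply_humane_endpoint(record, endpoint) if record is not None else None
        for metric in ("dai", "joint_size", "arthritis_score"):
            try:
                series = _metric_day_series(animal_id, metric, dai, record)
            except DaindexError:
                continue
            series = series.dropna()
            if censor is not None:
                series = series[series.index <= censor]
            if series.empty:
                continue
            threshold = thresholds.for_metric(metric)
            arthritic = call_incidence(series, threshold)
            onset = detect_onset(series, threshold)
            kind = "joint_size" if metric == "joint_size" else "value"
            try:
                severity = severity_at_end(series, censor, kind, calendar.final_day)
            except DaindexError:
                severity = math.nan
            rows.append(
                AnimalOutcome(animal_id, metric, arthritic, onset, severity, censor)
            )
    return pd.DataFrame(
        [r.__dict__ for r in rows],
        columns=["animal_id", "metric", "arthritic", "onset_day", "severity", "censor_day"],
    )
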