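"""Standard clinical measures: arthritis scores, joint sizes, histopathology.

The arthritis rubric scores each hind paw 0 (normal) to 4 (maximally
inflamed limb); the two paw scores are summed to the 0-8 total score.
Histopathology scores five features of the tibiotarsal joint —
inflammation, pannus formation, cartilage damage, bone resorption and
periosteal bone formation — each 0-5 for a side total of at most 25;
left and right sides are scored separately and averaged per animal.
"""
from __future__ import annotations

import logging
import math
from typing import Iterable, Optional

import pandas as pd

from .containers import HISTO_SUBSCORES, ClinicalRecord
from .errors import InputValidationError

log = logging.getLogger(__name__)

__all__ = [
    "total_arthritis_score",
    "histopath_total",
    "animal_histopath",
    "max_joint_size",
    "arthritis_score_series",
    "joint_size_series",
    "validate_measurements",
]


def _check_ordinal(value: float, bound: int, what: str) -> int:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise InputValidationError(f"{what} is missing")
    if float(value) != int(value) or not (0 <= int(value) <= bound):
        raise InputValidationError(f"{what} must be an integer in [0, {bound}], got {value}")
    return int(value)


def total_arthritis_score(left: float, right: float) -> int:
    """Sum of the two hind-paw scores (each 0-4), range 0-8."""
    return _check_ordinal(left, 4, "left paw score") + _check_ordinal(
        right, 4, "right paw score"
    )


def histopath_total(subscores: Iterable[float]) -> int:
    """Sum of the five 0-5 subscores for one side, maximum 25."""
    vals = list(subscores)
    if len(vals) != len(HISTO_SUBSCORES):
        raise InputValidationError(
            f"expected {len(HISTO_SUBSCORES)} subscores, got {len(vals)}"
        )
    return sum(
        _check_ordinal(v, 5, f"{name} subscore")
        for v, name in zip(vals, HISTO_SUBSCORES)
    )


def animal_histopath(
    left_total: Optional[float], right_total: Optional[float]
) -> float:
    """Mean of left/right side totals; falls back to the measured side.

    Early-euthanized animals may have one joint unscored; the available
    side is used alone and the fallback is logged for audit.
    """

    def _valid(total, side):
        if total is None or (isinstance(total, float) and math.isnan(total)):
            return None
        if float(total) != int(total) or not (0 <= total <= 25):
            raise InputValidationError(f"{side} side total must be an integer in [0, 25]")
        return float(total)

    lt, rt = _valid(left_total, "left"), _valid(right_total, "right")
    if lt is None and rt is None:
        raise InputValidationError("no histopathology sides measured")
    if lt is None or rt is None:
        only = lt if rt is None else rt
        log.warning("histopathology one-sided; using the measured side (total %.0f)", only)
        return only
    return (lt + rt) / 2.0


def max_joint_size(left_in: Optional[float], right_in: Optional[float]) -> float:
    """Maximum of the measured ankle sides (inches); NaN if none measured."""
    vals = [
        v
        for v in (left_in, right_in)
        if v is not None and not (isinstance(v, float) and math.isnan(v))
    ]
    return max(vals) if vals else math.nan


def arthritis_score_series(record: ClinicalRecord) -> pd.Series:
    """Per-day total arthritis score (0-8), indexed by study day."""
    left = record.metric_series("paw_score_left")
    right = record.metric_series("paw_score_right")
    days = sorted(set(left.index).intersection(right.index))
    return pd.Series(
        [total_arthritis_score(left.loc[d], right.loc[d]) for d in days],
        index=days,
        dtype=float,
    )


def joint_size_series(record: ClinicalRecord) -> pd.Series:
    """Per-day maximum of left/right ankle size (inches)."""
    left = record.metric_series("joint_left_in")
    right = record.metric_series("joint_right_in")
    days = sorted(set(left.index).union(right.index))
    return pd.Series(
        [
            max_joint_size(
                left.get(d, math.nan), right.get(d, math.nan)
            )
            for d in days
        ],
        index=days,
        dtype=float,
    ).dropna()


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format measurement table; raises on bad ordinals."""
    for col in ("animal_id", "study_day", "metric", "value"):
        if col not in df.columns:
            raise InputValidationError(f"measurement table missing column {col!r}")
    scores = df[df["metric"].isin(["paw_score_left", "paw_score_right"])]
    for _, row in scores.iterrows():
        _check_ordinal(
            row["value"], 4, f"{row['animal_id']} day {row['study_day']} {row['metric']}"
        )
    joints = df[df["metric"].isin(["joint_left_in", "joint_right_in"])]
    bad = joints[(joints["value"] < 0) | (joints["value"] > 1.0)]
    if len(bad):
        raise InputValidationError(
            f"implausible joint sizes (inches): {bad['value'].tolist()[:5]}"
        )
    return df
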