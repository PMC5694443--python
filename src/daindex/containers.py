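"""In-memory containers for study data.

Tabular payloads are plain pandas DataFrames with fixed column sets;
the dataclasses here just bind them to an animal or a study and carry
validation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import StudyConfig
from .errors import InputValidationError

TRACE_COLUMNS = ["animal_id", "timestamp", "speed_mm_s"]
MEASUREMENT_METRICS = (
    "joint_left_in",
    "joint_right_in",
    "paw_score_left",
    "paw_score_right",
    "body_weight_g",
)
HISTO_SUBSCORES = (
    "inflammation",
    "pannus",
    "cartilage_damage",
    "bone_resorption",
    "periosteal_bone_formation",
)


@dataclass
class ActivityTrace:
    """Timestamped speed samples (mm/s) for one animal."""

    animal_id: str
    samples: pd.DataFrame  # columns: timestamp (datetime64), speed_mm_s (float)

    def validate(self) -> "ActivityTrace":
        s = self.samples
        if not {"timestamp", "speed_mm_s"}.issubset(s.columns):
            raise InputValidationError("trace needs timestamp and speed_mm_s columns")
        ts = pd.to_datetime(s["timestamp"])
        if len(ts) and not ts.is_monotonic_increasing:
            raise InputValidationError(f"{self.animal_id}: timestamps not increasing")
        if len(ts) and ts.duplicated().any():
            raise InputValidationError(f"{self.animal_id}: duplicate timestamps")
        v = s["speed_mm_s"].to_numpy(dtype=float)
        if len(v) and (not np.isfinite(v).all() or (v < 0).any()):
            raise InputValidationError(f"{self.animal_id}: speeds must be finite and >= 0")
        return self


@dataclass
class ClinicalRecord:
    """Longitudinal clinical measurements and endpoint histopathology for
    one animal.

    ``measurements`` is long-format with columns (study_day, metric,
    value) where metric is one of ``MEASUREMENT_METRICS``.
    ``histopath`` has one row per side with the five ordinal subscores.
    """

    animal_id: str
    measurements: pd.DataFrame
    histopath: Optional[pd.DataFrame] = None

    def metric_series(self, metric: str) -> pd.Series:
        """Per-day values of one metric, indexed by study day."""
        m = self.measurements
        sub = m[m["metric"] == metric]
        return pd.Series(
            sub["value"].to_numpy(dtype=float),
            index=sub["study_day"].to_numpy(dtype=int),
        ).sort_index()


@dataclass(frozen=True)
class BaselineStats:
    """Per-animal baseline aggregate of the daily salient feature."""

    animal_id: str
    baseline_value: float
    n_days_used: int


@dataclass(frozen=True)
class AnimalOutcome:
    """Disease call for one animal under one metric."""

    animal_id: str
    metric: str
    arthritic: bool
    onset_day: Optional[int]
    severity: float
    censor_day: Optional[int]


@dataclass
class StudyDataset:
    """A full study: traces plus clinical records plus group assignments.

    ``animals`` columns: animal_id, group, induced, treatment_effect,
    compound, dose.
    """

    animals: pd.DataFrame
    traces: dict[str, ActivityTrace]
    clinical: dict[str, ClinicalRecord]
    config: Optional[StudyConfig] = None
    states: list = field(default_factory=list)  # latent truth, kept for tests

    def validate(self) -> "StudyDataset":
        ids = list(self.animals["animal_id"])
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputValidationError(f"duplicate animal ids: {dupes}")
        for name, mapping in (("traces", self.traces), ("clinical", self.clinical)):
            missing = set(mapping) - set(ids)
            if missing:
                raise InputValidationError(f"{name} reference unknown animals: {sorted(missing)}")
        for trace in self.traces.values():
            trace.validate()
        return self
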