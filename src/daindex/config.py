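"""Study configuration models.

All knobs of a study run live here: the light schedule, the study
calendar (induction, booster, dosing, endpoint), disease-calling
thresholds, humane-endpoint censoring rules, the activity-feature
settings, and the synthetic-cohort generator parameters.  Everything is
a pydantic model so a YAML study file is validated on load with field
names that match the published schema in ``docs/``.
"""
from __future__ import annotations

import datetime as dt
import hashlib
import json
from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator


class LightSchedule(BaseModel):
    """Vivarium light-dark cycle given as wall-clock times.

    Default is a 12-h cycle with lights on 06:00-18:00, so the dark
    (active) cycle runs 18:00-06:00, spanning midnight.
    """

    model_config = {"frozen": True}

    lights_on: dt.time = dt.time(6, 0)
    lights_off: dt.time = dt.time(18, 0)

    @model_validator(mode="after")
    def _distinct(self) -> "LightSchedule":
        if self.lights_on == self.lights_off:
            raise ValueError("lights_on and lights_off must differ")
        return self

    @property
    def dark_minutes(self) -> int:
        """Length of one dark cycle in minutes."""
        on = self.lights_on.hour * 60 + self.lights_on.minute
        off = self.lights_off.hour * 60 + self.lights_off.minute
        return (on - off) % (24 * 60)


class StudyCalendar(BaseModel):
    """Key study days, anchored at the induction date (study day 0)."""

    model_config = {"frozen": True}

    induction_date: dt.date = dt.date(2017, 1, 9)
    study_start_day: int = -3
    booster_day: int = 7
    dosing_start_day: int = 9
    final_day: int = 17
    baseline_start: int = -2
    baseline_end: int = 5

    @model_validator(mode="after")
    def _ordered(self) -> "StudyCalendar":
        if not (self.study_start_day <= self.baseline_start <= self.baseline_end <= self.final_day):
            raise ValueError("baseline window must lie inside the study range")
        if self.final_day <= self.dosing_start_day:
            raise ValueError("final_day must be after dosing_start_day")
        return self

    @property
    def baseline_days(self) -> list[int]:
        """Baseline-window study days; induction day 0 is always excluded."""
        return [d for d in range(self.baseline_start, self.baseline_end + 1) if d != 0]

    def date_of(self, study_day: int) -> dt.date:
        return self.induction_date + dt.timedelta(days=study_day)


class ThresholdConfig(BaseModel):
    """Disease-calling thresholds; an animal is arthritic when a metric is
    strictly greater than its threshold on any study day."""

    model_config = {"frozen": True}

    joint_size_in: float = Field(0.25, gt=0)
    arthritis_score: float = Field(4.0, gt=0)
    dai: float = Field(5.0, gt=0)

    def for_metric(self, metric: str) -> float:
        return {"joint_size": self.joint_size_in,
                "arthritis_score": self.arthritis_score,
                "dai": self.dai}[metric]


class EndpointRule(BaseModel):
    """Humane-endpoint censoring criteria.

    An animal is censored at the earliest day its ankle joint reaches
    ``joint_limit_in`` (inclusive), a hind paw holds the maximal score of
    4 for ``max_score_days`` consecutive daily observations (>48 h), or
    body weight drops by more than ``weight_loss_fraction`` of baseline.
    """

    model_config = {"frozen": True}

    joint_limit_in: float = Field(0.4, gt=0)
    max_score_days: int = Field(3, ge=2)
    weight_loss_fraction: float = Field(0.20, gt=0, lt=1)


class FeatureConfig(BaseModel):
    """Salient-feature extraction and DAI scaling settings."""

    model_config = {"frozen": True}

    method: Literal["q99", "max", "mean"] = "q99"
    scale_k: float = Field(20.0, gt=0)
    min_coverage: float = Field(0.5, gt=0, le=1)
    min_baseline_days: int = Field(3, ge=1)


class GroupSpec(BaseModel):
    """One experimental group for the synthetic-cohort generator."""

    model_config = {"frozen": True}

    name: str
    n: int = Field(9, gt=0)
    induced: bool = True
    treatment_effect: float = Field(1.0, ge=0, le=1)
    compound: Optional[str] = None
    dose: Optional[str] = None


class SimulationConfig(BaseModel):
    """Parameters of the synthetic study-cohort generator.

    Activity defaults are calibrated to healthy Lewis-rat home-cage
    baselines (nightly motion ~22 mm/s, between-animal SD ~2.4 mm/s) and
    to collagen-induced arthritis dynamics: detectable onset around study
    day 13 and an endpoint dark-cycle activity suppression of up to 45%.
    ``onset_day_mean``/``onset_day_sd`` describe the day disease becomes
    *detectable* by the DAI threshold; the latent severity ramp is
    anchored so that the noise-free DAI crosses ``dai_detect_threshold``
    at the drawn onset day.
    """

    model_config = {"frozen": True}

    n_per_group: int = Field(9, gt=0)
    seed: int = 0

    # activity model
    baseline_dark_speed_mean: float = Field(22.0, gt=0)   # mm/s
    baseline_dark_speed_sd: float = Field(2.4, ge=0)      # between-animal, mm/s
    within_noise_cv: float = Field(0.3, ge=0)             # per-minute CV
    light_speed_fraction: float = Field(0.3, gt=0, lt=1)
    max_activity_reduction: float = Field(0.45, ge=0, lt=1)

    # latent disease trajectory
    onset_day_mean: float = 13.0
    onset_day_sd: float = Field(1.0, ge=0)
    endpoint_severity_mean: float = Field(0.95, gt=0, le=1)
    endpoint_severity_sd: float = Field(0.05, ge=0)
    ramp_days: float = Field(4.0, gt=0)
    dai_detect_threshold: float = Field(5.0, gt=0)
    dai_scale_k: float = Field(20.0, gt=0)

    # clinical measurement model
    joint_baseline_in: float = Field(0.22, gt=0)
    joint_gain_in: float = Field(0.12, ge=0)
    joint_noise_in: float = Field(0.005, ge=0)
    score_gain: float = Field(3.8, gt=0, le=4)
    score_noise: float = Field(0.3, ge=0)
    histo_noise: float = Field(0.4, ge=0)
    weight_baseline_g: float = Field(190.0, gt=0)
    weight_baseline_sd_g: float = Field(8.0, ge=0)
    weight_loss_max: float = Field(0.08, ge=0, lt=1)
    weight_noise_g: float = Field(2.0, ge=0)

    sample_period_s: int = Field(60, gt=0)

    @model_validator(mode="after")
    def _onset_in_range(self) -> "SimulationConfig":
        # checked against the default calendar span; a custom calendar is
        # re-checked at simulation time
        if not (-3 <= self.onset_day_mean <= 30):
            raise ValueError("onset_day_mean outside a plausible study range")
        return self


class StudyConfig(BaseModel):
    """Top-level study configuration (YAML-facing)."""

    model_config = {"frozen": True}

    calendar: StudyCalendar = StudyCalendar()
    schedule: LightSchedule = LightSchedule()
    thresholds: ThresholdConfig = ThresholdConfig()
    endpoint: EndpointRule = EndpointRule()
    feature: FeatureConfig = FeatureConfig()
    simulation: SimulationConfig = SimulationConfig()
    groups: list[GroupSpec] = [
        GroupSpec(name="CIA", n=9, induced=True),
        GroupSpec(name="Control", n=9, induced=False),
    ]

    def config_hash(self) -> str:
        """Stable SHA-256 digest of the full configuration."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()
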