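import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import daindex as dx

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def calendar():
    return dx.StudyCalendar()


@pytest.fixture(scope="session")
def schedule():
    return dx.LightSchedule()


@pytest.fixture(scope="session")
def feature_cfg():
    return dx.FeatureConfig()


@pytest.fixture(scope="session")
def thresholds():
    return dx.ThresholdConfig()


@pytest.fixture(scope="session")
def endpoint_rule():
    return dx.EndpointRule()


def noise_free_config(**overrides) -> dx.SimulationConfig:
    """Simulator configuration with every dispersion at zero."""
    base = dict(
        baseline_dark_speed_sd=0.0,
        within_noise_cv=0.0,
        onset_day_sd=0.0,
        endpoint_severity_sd=0.0,
        joint_noise_in=0.0,
        score_noise=0.0,
        histo_noise=0.0,
        weight_baseline_sd_g=0.0,
        weight_noise_g=0.0,
    )
    base.update(overrides)
    return dx.SimulationConfig(**base)


def night_trace(speeds, day, calendar, schedule, animal_id="r1") -> dx.ActivityTrace:
    """A trace with one per-minute sample per entry of ``speeds``, covering
    the dark cycle of the given study day from lights-off onward."""
    start = pd.Timestamp(calendar.date_of(day)) + pd.Timedelta(
        hours=schedule.lights_off.hour, minutes=schedule.lights_off.minute
    )
    ts = pd.date_range(start, periods=len(speeds), freq="1min")
    return dx.ActivityTrace(
        animal_id, pd.DataFrame({"timestamp": ts, "speed_mm_s": np.asarray(speeds, float)})
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort shared by I/O and pipeline tests."""
    cfg = dx.SimulationConfig(seed=3)
    groups = [
        dx.GroupSpec(name="CIA", n=4, induced=True),
        dx.GroupSpec(name="Control", n=4, induced=False),
    ]
    return dx.simulate_cohort(cfg, groups)
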