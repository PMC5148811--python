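import dataclasses

import pytest
from hypothesis import HealthCheck, settings

import circawarn as cw

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast cohort: 3 patients, 2 weeks, frequent events."""
    return cw.SimulationConfig(
        n_patients=3,
        n_days=14,
        courses_per_patient=2,
        course_spacing_days=5,
        first_course_day=4,
        course_duration_days=2,
        event_probability_per_course=0.5,
        event_delay_range=(2, 4),
        event_duration_range=(2, 3),
        deterioration=dataclasses.replace(
            cw.Deterioration(), onset_lag_days=4
        ),
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return cw.simulate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_timeline(tiny_cohort):
    return cw.assemble_timeline(tiny_cohort)


@pytest.fixture(scope="session")
def bench_cohort():
    """One strong-signal benchmark cohort with its timeline/features."""
    cohort = cw.simulate_cohort(cw.strong_signal_config(seed=1))
    timeline = cw.assemble_timeline(cohort)
    features = cw.assemble_features(timeline, cohort.events)
    return cohort, timeline, features
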