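"""Synthetic telemonitoring cohorts.

Generates cohorts with the statistical structure the analysis pipeline
assumes: per-minute wrist-activity counts with a circadian profile and
an in-bed window, daily self-measured body weight, daily 19-item MDASI
self-reports, chemotherapy courses (some given in hospital), and
occasional unplanned toxicity-related admissions preceded by a
multi-day deterioration of circadian rhythm, weight and selected
symptoms.

Activity counts are negative-binomial (over-dispersed Poisson), with a
sinusoidal modulation of the daytime mean.  Missingness is
missing-completely-at-random per parameter per day.  Each patient draws
from an independent random stream derived from ``(seed,
patient_index)``, so a patient's data do not depend on cohort size.

The generator emulates: a cohort of ~31 patients monitored ~60 days
each; healthy dichotomy-index values almost always >= 98%; roughly 3
chemotherapy courses per patient with ~10% of courses followed by an
unplanned admission; per-parameter daily missingness in the 18-25%
range; and no home data during hospital stays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .actigraphy import MINUTES_PER_DAY, EpochSeries
from .errors import ConfigError
from .schema import MDASI_ITEMS

__all__ = [
    "Deterioration",
    "Missingness",
    "SimulationConfig",
    "PatientData",
    "SyntheticCohort",
    "simulate_patient",
    "simulate_cohort",
    "strong_signal_config",
]

# Typical item levels used as simulation baselines (0-10 scale); chosen
# to resemble the mix of mild symptom severities and moderate
# interference scores seen in advanced-cancer telemonitoring cohorts.
MDASI_BASELINES = {
    "pain": 2, "fatigue": 4, "nausea": 0, "disturbed_sleep": 2, "distress": 3,
    "shortness_of_breath": 2, "remembering": 1, "lack_of_appetite": 2,
    "drowsiness": 2, "dry_mouth": 1, "sadness": 2, "vomiting": 0,
    "numbness_tingling": 1, "general_activity": 4, "mood": 2, "work": 5,
    "relations_with_others": 2, "walking": 3, "enjoyment_of_life": 3,
}

# Items that drift upward during the pre-admission deterioration
# (symptoms and role/physical/social interference tied to circadian
# disruption); memory problems deliberately stay flat.
DEFAULT_DRIFT_ITEMS = (
    "fatigue",
    "lack_of_appetite",
    "general_activity",
    "work",
    "relations_with_others",
)


@dataclass(frozen=True)
class Deterioration:
    """Pre-admission deterioration ramp.

    The ramp runs over the ``onset_lag_days`` days before an unplanned
    admission with a quadratic profile ``f = (t / lag)**2`` (slow early
    decline, steepest immediately before admission).  At ramp level
    ``f``: the in-bed activity mean is multiplied by ``1 +
    night_activity_effect * f`` and the out-of-bed mean by ``1 -
    day_activity_effect * f`` (lowering I<O); body weight drops by
    ``weight_loss_pct * f`` percent of baseline; affected MDASI items
    gain ``mdasi_drift * f`` points (clipped to [0, 10]).
    """

    onset_lag_days: int = 14
    night_activity_effect: float = 8.0
    day_activity_effect: float = 0.3
    weight_loss_pct: float = 3.0
    mdasi_drift: float = 3.0
    drift_items: tuple[str, ...] = DEFAULT_DRIFT_ITEMS

    def zeroed(self) -> "Deterioration":
        return replace(
            self,
            night_activity_effect=0.0,
            day_activity_effect=0.0,
            weight_loss_pct=0.0,
            mdasi_drift=0.0,
        )


@dataclass(frozen=True)
class Missingness:
    """Daily MCAR missingness probabilities per parameter group."""

    weight: float = 0.18
    mdasi: float = 0.22
    actigraphy: float = 0.25

    def zeroed(self) -> "Missingness":
        return Missingness(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generation parameters; ``seed`` fully determines output."""

    n_patients: int = 31
    n_days: int = 60
    epoch_minutes: int = 1
    bed_window: tuple[str, str] = ("23:00", "07:00")
    day_activity_mean: float = 150.0
    day_activity_dispersion: float = 3.0
    night_activity_mean: float = 10.0
    night_activity_dispersion: float = 0.4
    circadian_amplitude: float = 0.3
    event_probability_per_course: float = 0.10
    courses_per_patient: int = 3
    course_spacing_days: int = 14
    first_course_day: int = 5
    course_duration_days: int = 4
    hospital_course_fraction: float = 0.35
    event_delay_range: tuple[int, int] = (3, 10)
    event_duration_range: tuple[int, int] = (2, 9)
    deterioration: Deterioration = field(default_factory=Deterioration)
    missingness: Missingness = field(default_factory=Missingness)
    start_date: str = "2012-01-02"
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients", "must be >= 0")
        if self.n_days < 7:
            raise ConfigError("n_days", "must be >= 7")
        if self.epoch_minutes < 1 or MINUTES_PER_DAY % self.epoch_minutes:
            raise ConfigError("epoch_minutes", "must divide 1440")
        for name in ("day_activity_mean", "night_activity_mean"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "must be >= 0")
        for name in ("day_activity_dispersion", "night_activity_dispersion"):
            if getattr(self, name) <= 0:
                raise ConfigError(name, "must be > 0")
        if not 0.0 <= self.circadian_amplitude <= 1.0:
            raise ConfigError("circadian_amplitude", "must be in [0, 1]")
        for name in ("event_probability_per_course", "hospital_course_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(name, "must be a probability in [0, 1]")
        for name in ("weight", "mdasi", "actigraphy"):
            p = getattr(self.missingness, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"missingness.{name}", "must be in [0, 1]")
        if self.deterioration.onset_lag_days < 1:
            raise ConfigError("deterioration.onset_lag_days", "must be >= 1")
        for name in (
            "night_activity_effect", "day_activity_effect",
            "weight_loss_pct", "mdasi_drift",
        ):
            if getattr(self.deterioration, name) < 0:
                raise ConfigError(f"deterioration.{name}", "must be >= 0")
        if not 0.0 <= self.deterioration.day_activity_effect <= 1.0:
            raise ConfigError("deterioration.day_activity_effect", "must be in [0, 1]")
        if self.courses_per_patient < 0:
            raise ConfigError("courses_per_patient", "must be >= 0")
        if self.course_spacing_days < 1:
            raise ConfigError("course_spacing_days", "must be >= 1")
        if self.first_course_day < 1:
            raise ConfigError("first_course_day", "must be >= 1")
        lo, hi = self.event_delay_range
        if lo < 1 or hi < lo:
            raise ConfigError("event_delay_range", "must satisfy 1 <= lo <= hi")
        lo, hi = self.event_duration_range
        if lo < 1 or hi < lo:
            raise ConfigError("event_duration_range", "must satisfy 1 <= lo <= hi")


@dataclass
class PatientData:
    """One synthetic patient: epochs plus the three daily-level tables."""

    patient_id: str
    epochs: EpochSeries
    daily: pd.DataFrame
    events: pd.DataFrame
    courses: pd.DataFrame


@dataclass
class SyntheticCohort:
    """Synthetic cohort as four tidy tables (and per-patient views)."""

    patients: list[PatientData]

    @property
    def daily(self) -> pd.DataFrame:
        return self._concat("daily")

    @property
    def events(self) -> pd.DataFrame:
        return self._concat("events")

    @property
    def courses(self) -> pd.DataFrame:
        return self._concat("courses")

    @property
    def epochs(self) -> pd.DataFrame:
        frames = []
        for p in self.patients:
            e = p.epochs
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": p.patient_id,
                        "timestamp": e.timestamps,
                        "activity_count": e.counts,
                        "in_bed": e.in_bed.astype(int),
                        "observed": e.observed.astype(int),
                    }
                )
            )
        if not frames:
            return pd.DataFrame(
                columns=["patient_id", "timestamp", "activity_count", "in_bed", "observed"]
            )
        return pd.concat(frames, ignore_index=True)

    def _concat(self, attr: str) -> pd.DataFrame:
        frames = [getattr(p, attr) for p in self.patients]
        frames = [f for f in frames if not f.empty]
        if not frames:
            template = getattr(self.patients[0], attr) if self.patients else None
            cols = list(template.columns) if template is not None else []
            return pd.DataFrame(columns=cols)
        return pd.concat(frames, ignore_index=True)


def _bed_minutes(config: SimulationConfig) -> np.ndarray:
    """Boolean in-bed mask over the minutes of one calendar day."""
    h0, m0 = map(int, config.bed_window[0].split(":"))
    h1, m1 = map(int, config.bed_window[1].split(":"))
    a, b = h0 * 60 + m0, h1 * 60 + m1
    minutes = np.arange(0, MINUTES_PER_DAY, config.epoch_minutes)
    if a <= b:
        return (minutes >= a) & (minutes < b)
    return (minutes >= a) | (minutes < b)


def _plan_courses(config: SimulationConfig, rng) -> pd.DataFrame:
    starts, locations = [], []
    day = config.first_course_day
    for _ in range(config.courses_per_patient):
        end = day + config.course_duration_days - 1
        if end > config.n_days:
            break
        starts.append(day)
        locations.append(
            "hospital" if rng.random() < config.hospital_course_fraction else "home"
        )
        day += config.course_spacing_days
    return pd.DataFrame(
        {
            "start_day": starts,
            "end_day": [s + config.course_duration_days - 1 for s in starts],
            "location": locations,
        }
    )


def _plan_events(config: SimulationConfig, courses: pd.DataFrame, rng) -> list[dict]:
    """Emergency admissions (after some courses) and planned hospital
    stays (hospital-located courses)."""
    events: list[dict] = []
    for _, c in courses.iterrows():
        if c["location"] == "hospital":
            events.append(
                {"admission": int(c["start_day"]), "discharge": int(c["end_day"]),
                 "planned": True}
            )
    last_emergency_discharge = 0
    for _, c in courses.iterrows():
        # Bernoulli draw happens for every course so the per-course
        # event rate matches the configured probability exactly.
        hit = rng.random() < config.event_probability_per_course
        delay = int(rng.integers(config.event_delay_range[0],
                                 config.event_delay_range[1] + 1))
        duration = int(rng.integers(config.event_duration_range[0],
                                    config.event_duration_range[1] + 1))
        if not hit:
            continue
        admission = int(c["end_day"]) + delay
        if admission > config.n_days or admission <= last_emergency_discharge:
            continue  # off the monitored span, or still hospitalized
        discharge = min(admission + duration - 1, config.n_days)
        events.append({"admission": admission, "discharge": discharge, "planned": False})
        last_emergency_discharge = discharge
    return events


def _ramp_level(config: SimulationConfig, events: list[dict]) -> np.ndarray:
    """Deterioration level f in [0, 1] per day (1-indexed -> index 0)."""
    lag = config.deterioration.onset_lag_days
    f = np.zeros(config.n_days)
    for ev in events:
        if ev["planned"]:
            continue
        adm = ev["admission"]
        for day in range(max(1, adm - lag), adm):
            level = ((day - (adm - lag) + 1) / lag) ** 2
            f[day - 1] = max(f[day - 1], level)
    return f


def simulate_patient(config: SimulationConfig, patient_index: int) -> PatientData:
    """Generate one patient's epochs, daily records, events and courses.

    The patient's random stream is derived from ``(config.seed,
    patient_index)`` only, so output is reproducible regardless of how
    many other patients the cohort holds.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, patient_index])
    pid = f"P{patient_index + 1:03d}"
    n_days = config.n_days
    start = pd.Timestamp(config.start_date)
    dates = pd.date_range(start, periods=n_days, freq="D")

    courses = _plan_courses(config, rng)
    events = _plan_events(config, courses, rng)
    ramp = _ramp_level(config, events)

    hospitalized = np.zeros(n_days, dtype=bool)
    for ev in events:
        hospitalized[ev["admission"] - 1 : ev["discharge"]] = True

    # --- actigraphy -------------------------------------------------
    bed_day = _bed_minutes(config)
    epochs_per_day = bed_day.size
    in_bed = np.tile(bed_day, n_days)
    minute_of_day = np.tile(
        np.arange(0, MINUTES_PER_DAY, config.epoch_minutes), n_days
    )
    day_idx = np.repeat(np.arange(n_days), epochs_per_day)

    hours = minute_of_day / 60.0
    modulation = 1.0 + config.circadian_amplitude * np.cos(
        2 * np.pi * (hours - 14.0) / 24.0
    )
    f_epoch = ramp[day_idx]
    det = config.deterioration
    mean = np.where(
        in_bed,
        config.night_activity_mean * (1.0 + det.night_activity_effect * f_epoch),
        config.day_activity_mean * modulation
        * (1.0 - det.day_activity_effect * f_epoch),
    )
    dispersion = np.where(
        in_bed, config.night_activity_dispersion, config.day_activity_dispersion
    )
    counts = rng.negative_binomial(
        dispersion, dispersion / (dispersion + mean)
    ).astype(float)

    acti_missing_day = rng.random(n_days) < config.missingness.actigraphy
    observed = ~(acti_missing_day | hospitalized)[day_idx]
    counts[~observed] = np.nan

    epochs = EpochSeries(
        patient_id=pid,
        start=start,
        counts=counts,
        in_bed=in_bed,
        observed=observed,
        epoch_minutes=config.epoch_minutes,
    )

    # --- daily weight -----------------------------------------------
    baseline_weight = float(np.clip(rng.normal(70.0, 10.0), 45.0, 110.0))
    walk = np.cumsum(rng.normal(0.0, 0.1, n_days))
    weight = baseline_weight + walk - baseline_weight * (
        det.weight_loss_pct / 100.0
    ) * ramp
    weight = np.round(weight, 1)

    # --- daily MDASI ------------------------------------------------
    offsets = {item: rng.normal(0.0, 0.8) for item in MDASI_ITEMS}
    mdasi = {}
    for item in MDASI_ITEMS:
        drift = det.mdasi_drift * ramp if item in det.drift_items else 0.0
        vals = MDASI_BASELINES[item] + offsets[item] + rng.normal(0.0, 1.0, n_days) + drift
        mdasi[item] = np.clip(np.round(vals), 0, 10).astype(float)

    # --- missingness and hospitalization blanking -------------------
    weight_missing = (rng.random(n_days) < config.missingness.weight) | hospitalized
    mdasi_missing = (rng.random(n_days) < config.missingness.mdasi) | hospitalized
    weight = np.where(weight_missing, np.nan, weight)
    for item in MDASI_ITEMS:
        mdasi[item] = np.where(mdasi_missing, np.nan, mdasi[item])

    daily = pd.DataFrame({"patient_id": pid, "date": dates, "weight_kg": weight})
    for item in MDASI_ITEMS:
        daily[f"mdasi_{item}"] = mdasi[item]
    daily["hospitalized"] = hospitalized.astype(int)

    events_df = pd.DataFrame(
        {
            "patient_id": pid,
            "admission_date": [dates[e["admission"] - 1] for e in events],
            "discharge_date": [dates[e["discharge"] - 1] for e in events],
            "planned": [int(e["planned"]) for e in events],
        }
    ).sort_values("admission_date", kind="stable").reset_index(drop=True)
    courses_df = pd.DataFrame(
        {
            "patient_id": pid,
            "start_date": [dates[s - 1] for s in courses["start_day"]],
            "end_date": [dates[e - 1] for e in courses["end_day"]],
            "location": courses["location"],
        }
    )
    return PatientData(pid, epochs, daily, events_df, courses_df)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate ``config.n_patients`` independent patients."""
    config.validate()
    return SyntheticCohort(
        [simulate_patient(config, i) for i in range(config.n_patients)]
    )


def strong_signal_config(seed: int = 0) -> SimulationConfig:
    """Compact benchmark scenario with a strong planted deterioration.

    A small cohort with frequent events, a short steep pre-admission
    ramp and large effect sizes, used to verify that the pipeline
    recovers a signal it is known to contain.
    """
    return SimulationConfig(
        n_patients=10,
        n_days=40,
        courses_per_patient=3,
        course_spacing_days=10,
        first_course_day=5,
        event_probability_per_course=0.6,
        event_delay_range=(3, 8),
        deterioration=Deterioration(
            onset_lag_days=5,
            night_activity_effect=12.0,
            day_activity_effect=0.4,
            weight_loss_pct=5.0,
            mdasi_drift=5.0,
        ),
        seed=seed,
    )
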