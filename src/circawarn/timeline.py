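"""Per-patient daily timelines, compliance accounting and descriptives.

The assembled timeline is a tidy per-patient-per-day table combining
body weight (as % change from a pre-treatment baseline), the 19 MDASI
items, the dichotomy index I<O from the trailing 3-day actigraphy
window, hospitalization flags, and per-parameter availability flags
used by the compliance accounting.

Compliance follows the platform-use definition: the number of days on
which a parameter was transmitted divided by the theoretical number of
monitored days, where days spent in hospital (elective or emergency) do
not count toward the denominator.  "Full" compliance requires all three
parameter groups on the same day (the MDASI questionnaire counts as one
parameter); the rolling rate asks for at least one fully complete day
within a trailing 3-day window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .actigraphy import sliding_io
from .errors import BaselineUnavailableError, DataError
from .schema import MDASI_COLUMNS

__all__ = [
    "BaselineWeight",
    "baseline_weight",
    "weight_change_pct",
    "assemble_timeline",
    "ComplianceReport",
    "compliance_rates",
    "rate",
    "describe_parameters",
    "summarize_preevent",
    "longitudinal_compliance",
]


@dataclass
class BaselineWeight:
    """Pre-treatment reference weight (kg) with a reliability flag."""

    value: float
    n_days: int
    low_confidence: bool  # fewer than 3 pre-course measurements


def baseline_weight(pre_course_weights) -> BaselineWeight:
    """Arithmetic mean of the weights measured before the first course.

    The protocol asks for at least three pre-treatment days; with fewer
    the baseline is still computed but flagged low-confidence.

    Raises
    ------
    BaselineUnavailableError
        If no pre-course weight exists.
    """
    w = np.asarray(list(pre_course_weights), dtype=float)
    w = w[~np.isnan(w)]
    if w.size == 0:
        raise BaselineUnavailableError("no weight measured before the first course")
    return BaselineWeight(
        value=float(w.mean()), n_days=int(w.size), low_confidence=w.size < 3
    )


def weight_change_pct(weight: float, baseline: float) -> float:
    """Daily body-weight change, percent of the baseline weight."""
    if not baseline > 0:
        raise DataError(f"baseline weight must be positive, got {baseline}")
    return 100.0 * (weight - baseline) / baseline


def rate(numerator: int, denominator: int) -> float:
    """A compliance rate in percent; the denominator must be positive."""
    if denominator <= 0:
        raise DataError("compliance rate needs a positive denominator")
    return 100.0 * numerator / denominator


def _hospital_mask(dates: pd.DatetimeIndex, events: pd.DataFrame) -> np.ndarray:
    mask = np.zeros(len(dates), dtype=bool)
    if events is None or events.empty:
        return mask
    for _, ev in events.iterrows():
        a = pd.Timestamp(ev["admission_date"]).normalize()
        d = pd.Timestamp(ev["discharge_date"]).normalize()
        mask |= np.asarray((dates >= a) & (dates <= d))
    return mask


def assemble_timeline(
    cohort,
    window_days: int = 3,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Assemble the cohort-level daily timeline.

    ``cohort`` provides per-patient epochs plus the ``daily``,
    ``events`` and ``courses`` tables (a
    :class:`~circawarn.simulate.SyntheticCohort` or any object with the
    same attributes).  Adds: day numbers (1 = first monitored day),
    I<O and its window coverage, weight change vs. the pre-course
    baseline, hospitalization flags (from the event table), and
    per-parameter availability flags.

    If a patient has no observed weight before their first course, the
    first observed weight overall is used as baseline and flagged; a
    patient with no weight at all gets an all-missing weight-change
    series.
    """
    frames = []
    for p in cohort.patients:
        daily = p.daily.sort_values("date").reset_index(drop=True)
        dates = pd.DatetimeIndex(pd.to_datetime(daily["date"])).normalize()
        io_df = sliding_io(p.epochs, window_days=window_days, min_coverage=min_coverage)
        io_df = io_df.assign(date=pd.to_datetime(io_df["date"]))

        tl = daily.copy()
        tl["date"] = dates
        tl["day"] = np.arange(1, len(tl) + 1)
        tl = tl.merge(
            io_df[["date", "io", "coverage_in_bed", "coverage_out_of_bed"]],
            on="date",
            how="left",
        )

        hospitalized = _hospital_mask(dates, p.events)
        if "hospitalized" in daily:
            hospitalized |= daily["hospitalized"].to_numpy(dtype=bool)
        tl["hospitalized"] = hospitalized

        weights = tl["weight_kg"].to_numpy(dtype=float)
        first_course = (
            pd.to_datetime(p.courses["start_date"]).min()
            if p.courses is not None and not p.courses.empty
            else None
        )
        pre_mask = (
            np.asarray(dates < first_course)
            if first_course is not None
            else np.zeros(len(dates), dtype=bool)
        )
        try:
            bl = baseline_weight(weights[pre_mask])
        except BaselineUnavailableError:
            observed = weights[~np.isnan(weights)]
            if observed.size:
                bl = BaselineWeight(float(observed[0]), 1, True)
                warnings.warn(
                    f"patient {p.patient_id}: no pre-course weight; using first "
                    "observed weight as baseline",
                    stacklevel=2,
                )
            else:
                bl = None
        if bl is None:
            tl["weight_change"] = np.nan
            tl["baseline_weight_kg"] = np.nan
        else:
            tl["weight_change"] = 100.0 * (weights - bl.value) / bl.value
            tl["baseline_weight_kg"] = bl.value

        # availability flags for compliance
        tl["weight_available"] = ~np.isnan(weights)
        mdasi_vals = tl[list(MDASI_COLUMNS)].to_numpy(dtype=float)
        tl["mdasi_available"] = ~np.isnan(mdasi_vals).all(axis=1)
        obs_epochs = p.epochs.observed & ~np.isnan(p.epochs.counts)
        day_off = p.epochs.day_offsets()
        acti_by_day = np.zeros(len(tl), dtype=bool)
        days_with_data = np.unique(day_off[obs_epochs])
        acti_by_day[days_with_data[days_with_data < len(tl)]] = True
        tl["actigraphy_available"] = acti_by_day
        frames.append(tl)

    if not frames:
        return pd.DataFrame()
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["patient_id", "date"]).reset_index(drop=True)


@dataclass
class ComplianceReport:
    """Platform-use compliance over a monitoring period.

    All rates are percentages of theoretical patient-days (monitored
    days in the period minus hospitalization days).
    """

    period: tuple[int, int]
    theoretical_days: int
    weight_rate: float
    mdasi_rate: float
    actigraphy_rate: float
    full_rate: float
    at_least_one_rate: float
    rolling3_full_rate: float
    weight_days: int
    mdasi_days: int
    actigraphy_days: int
    full_days: int
    at_least_one_days: int
    rolling3_full_days: int
    per_patient: pd.DataFrame

    def check_invariants(self) -> None:
        lo = min(self.weight_rate, self.mdasi_rate, self.actigraphy_rate)
        hi = max(self.weight_rate, self.mdasi_rate, self.actigraphy_rate)
        tol = 1e-9
        assert self.full_rate <= lo + tol
        assert hi <= self.at_least_one_rate + tol
        for r in (
            self.weight_rate, self.mdasi_rate, self.actigraphy_rate,
            self.full_rate, self.at_least_one_rate, self.rolling3_full_rate,
        ):
            assert -tol <= r <= 100 + tol

    def to_dict(self) -> dict:
        return {
            "period": list(self.period),
            "theoretical_days": self.theoretical_days,
            "weight_rate": self.weight_rate,
            "mdasi_rate": self.mdasi_rate,
            "actigraphy_rate": self.actigraphy_rate,
            "full_rate": self.full_rate,
            "at_least_one_rate": self.at_least_one_rate,
            "rolling3_full_rate": self.rolling3_full_rate,
        }


def compliance_rates(
    timeline: pd.DataFrame,
    period: tuple[int, int] = (1, 30),
    window_days: int = 3,
) -> ComplianceReport:
    """Compliance accounting over day numbers ``period`` (inclusive).

    Hospitalization days are excluded from the denominator.  A day
    counts for a parameter when that parameter was transmitted; "full"
    requires weight, MDASI and actigraphy together; the rolling rate is
    the fraction of theoretical patient-days with at least one fully
    complete day within the trailing ``window_days`` window (truncated
    at the start of monitoring).
    """
    if timeline.empty:
        raise DataError("empty timeline")
    lo, hi = period
    if hi < lo:
        raise DataError("empty period")

    tl = timeline.copy()
    tl["full"] = (
        tl["weight_available"] & tl["mdasi_available"] & tl["actigraphy_available"]
    )
    # rolling full within the trailing window, computed on the whole
    # monitored span so early period days may look back before `lo`
    tl["rolling_full"] = (
        tl.groupby("patient_id", sort=False)["full"]
        .transform(lambda s: s.rolling(window_days, min_periods=1).max())
        .astype(bool)
    )

    in_period = (tl["day"] >= lo) & (tl["day"] <= hi)
    th = tl[in_period & ~tl["hospitalized"]]

    per_patient = (
        th.groupby("patient_id")
        .agg(
            theoretical_days=("day", "size"),
            weight_days=("weight_available", "sum"),
            mdasi_days=("mdasi_available", "sum"),
            actigraphy_days=("actigraphy_available", "sum"),
            full_days=("full", "sum"),
        )
        .reset_index()
    )
    per_patient["full_rate"] = 100.0 * per_patient["full_days"] / per_patient[
        "theoretical_days"
    ]

    n = len(th)
    if n == 0:
        warnings.warn("period has zero theoretical patient-days", stacklevel=2)
        empty = ComplianceReport(
            period=period, theoretical_days=0,
            weight_rate=np.nan, mdasi_rate=np.nan, actigraphy_rate=np.nan,
            full_rate=np.nan, at_least_one_rate=np.nan, rolling3_full_rate=np.nan,
            weight_days=0, mdasi_days=0, actigraphy_days=0, full_days=0,
            at_least_one_days=0, rolling3_full_days=0, per_patient=per_patient,
        )
        return empty

    at_least_one = th["weight_available"] | th["mdasi_available"] | th[
        "actigraphy_available"
    ]
    report = ComplianceReport(
        period=period,
        theoretical_days=n,
        weight_rate=rate(int(th["weight_available"].sum()), n),
        mdasi_rate=rate(int(th["mdasi_available"].sum()), n),
        actigraphy_rate=rate(int(th["actigraphy_available"].sum()), n),
        full_rate=rate(int(th["full"].sum()), n),
        at_least_one_rate=rate(int(at_least_one.sum()), n),
        rolling3_full_rate=rate(int(th["rolling_full"].sum()), n),
        weight_days=int(th["weight_available"].sum()),
        mdasi_days=int(th["mdasi_available"].sum()),
        actigraphy_days=int(th["actigraphy_available"].sum()),
        full_days=int(th["full"].sum()),
        at_least_one_days=int(at_least_one.sum()),
        rolling3_full_days=int(th["rolling_full"].sum()),
        per_patient=per_patient,
    )
    report.check_invariants()
    return report


def longitudinal_compliance(timeline: pd.DataFrame, max_day: int = 60) -> pd.DataFrame:
    """Per-day availability rates across patients (longitudinal view):
    for each day number, the % of non-hospitalized monitored patients
    with any data that day and the % with a full set available at least
    once in the trailing 3 days."""
    tl = timeline.copy()
    tl["full"] = (
        tl["weight_available"] & tl["mdasi_available"] & tl["actigraphy_available"]
    )
    tl["any"] = (
        tl["weight_available"] | tl["mdasi_available"] | tl["actigraphy_available"]
    )
    tl["rolling_full"] = (
        tl.groupby("patient_id", sort=False)["full"]
        .transform(lambda s: s.rolling(3, min_periods=1).max())
        .astype(bool)
    )
    tl = tl[(tl["day"] <= max_day) & ~tl["hospitalized"]]
    out = (
        tl.groupby("day")
        .agg(
            n_patients=("patient_id", "nunique"),
            any_rate=("any", "mean"),
            rolling3_full_rate=("rolling_full", "mean"),
        )
        .reset_index()
    )
    out["any_rate"] *= 100.0
    out["rolling3_full_rate"] *= 100.0
    return out


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    """Median and quartiles, linear interpolation between order
    statistics (the common 'type 7' rule)."""
    q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def describe_parameters(timeline: pd.DataFrame) -> pd.DataFrame:
    """Median, quartiles and range of each collected parameter over all
    observed patient-days (weight change, I<O, each MDASI item).

    All-missing parameters are omitted with a warning.
    """
    params: dict[str, np.ndarray] = {
        "weight_change": timeline["weight_change"].to_numpy(dtype=float),
        "io": timeline["io"].to_numpy(dtype=float),
    }
    # weight change only counts where weight was actually measured
    params["weight_change"] = np.where(
        timeline["weight_available"].to_numpy(dtype=bool),
        params["weight_change"],
        np.nan,
    )
    for col in MDASI_COLUMNS:
        params[col.removeprefix("mdasi_")] = timeline[col].to_numpy(dtype=float)

    rows = []
    for name, vals in params.items():
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            warnings.warn(f"parameter {name!r} has no observed value; omitted",
                          stacklevel=2)
            continue
        med, q1, q3 = _quartiles(vals)
        rows.append(
            {
                "parameter": name,
                "median": med,
                "q1": q1,
                "q3": q3,
                "min": float(vals.min()),
                "max": float(vals.max()),
                "n": int(vals.size),
            }
        )
    return pd.DataFrame(rows)


def summarize_preevent(
    timeline: pd.DataFrame,
    events: pd.DataFrame,
    lookback_days: int = 14,
) -> pd.DataFrame:
    """Mean and SEM of each parameter by day relative to admission.

    For offsets ``-lookback_days .. -1`` before each unplanned
    admission, averages the observed parameter values across events
    (missing values excluded pairwise).  SEM is the sample standard
    deviation over events divided by sqrt(n); with a single
    contributing event it is undefined and reported missing.  Returns
    an empty frame when there is no unplanned event.
    """
    value_cols = {"weight_change": "weight_change", "io": "io"}
    for col in MDASI_COLUMNS:
        value_cols[col.removeprefix("mdasi_")] = col

    unplanned = (
        events[~events["planned"].astype(bool)]
        if events is not None and not events.empty
        else pd.DataFrame()
    )
    if unplanned.empty:
        return pd.DataFrame(columns=["parameter", "offset", "mean", "sem", "n"])

    tl = timeline.set_index(["patient_id", "date"])
    records: dict[tuple[str, int], list[float]] = {}
    for _, ev in unplanned.iterrows():
        adm = pd.Timestamp(ev["admission_date"]).normalize()
        pid = ev["patient_id"]
        for off in range(-lookback_days, 0):
            key = (pid, adm + pd.Timedelta(days=off))
            if key not in tl.index:
                continue
            row = tl.loc[key]
            for name, col in value_cols.items():
                v = row[col]
                if pd.notna(v):
                    records.setdefault((name, off), []).append(float(v))

    rows = []
    for (name, off), vals in sorted(records.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        arr = np.asarray(vals)
        sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else np.nan
        rows.append(
            {
                "parameter": name,
                "offset": off,
                "mean": float(arr.mean()),
                "sem": sem,
                "n": int(arr.size),
            }
        )
    return pd.DataFrame(rows)
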