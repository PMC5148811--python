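"""Timeline assembly, compliance accounting, descriptives, pre-event curves."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import circawarn as cw
from circawarn.errors import BaselineUnavailableError, DataError
from circawarn.timeline import (
    baseline_weight,
    compliance_rates,
    describe_parameters,
    longitudinal_compliance,
    rate,
    summarize_preevent,
    weight_change_pct,
)


def test_baseline_weight_examples():
    bl = baseline_weight([70, 71, 72])
    assert bl.value == pytest.approx(71.0)
    assert not bl.low_confidence
    bl = baseline_weight([68.5])
    assert bl.value == pytest.approx(68.5)
    assert bl.low_confidence  # under-3-days warning flag
    with pytest.raises(BaselineUnavailableError):
        baseline_weight([])
    with pytest.raises(BaselineUnavailableError):
        baseline_weight([np.nan, np.nan])


def test_weight_change_examples():
    assert weight_change_pct(63, 70) == pytest.approx(-10.0)
    assert weight_change_pct(70, 70) == pytest.approx(0.0)
    assert weight_change_pct(74.2, 70) == pytest.approx(6.0)
    with pytest.raises(DataError):
        weight_change_pct(70, 0)


def test_weight_change_scale_invariance():
    """Scaling all weights and the baseline by a common factor leaves
    the percentage unchanged."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        w, b, k = rng.uniform(40, 120), rng.uniform(40, 120), rng.uniform(0.5, 2)
        assert weight_change_pct(k * w, k * b) == pytest.approx(
            weight_change_pct(w, b)
        )


def test_rate_rejects_zero_denominator():
    with pytest.raises(DataError):
        rate(1, 0)


def _toy_timeline(avail):
    """Timeline from a dict patient -> list of (w, m, a, hosp) per day."""
    rows = []
    for pid, days in avail.items():
        for i, (w, m, a, h) in enumerate(days):
            rows.append(
                {
                    "patient_id": pid,
                    "date": pd.Timestamp("2012-01-02") + pd.Timedelta(days=i),
                    "day": i + 1,
                    "weight_available": bool(w),
                    "mdasi_available": bool(m),
                    "actigraphy_available": bool(a),
                    "hospitalized": bool(h),
                }
            )
    return pd.DataFrame(rows)


def test_compliance_counts_by_hand():
    tl = _toy_timeline(
        {
            "A": [(1, 1, 1, 0), (1, 0, 1, 0), (0, 0, 0, 0), (1, 1, 1, 1)],
            "B": [(1, 1, 1, 0), (1, 1, 1, 0), (1, 1, 0, 0), (0, 0, 0, 0)],
        }
    )
    rep = compliance_rates(tl, period=(1, 4))
    # 7 theoretical days (one hospitalized excluded)
    assert rep.theoretical_days == 7
    assert rep.full_days == 3
    assert rep.full_rate == pytest.approx(100 * 3 / 7)
    assert rep.at_least_one_days == 5
    assert rep.weight_rate == pytest.approx(100 * 5 / 7)
    # rolling 3-day full: A days 1,2,3 look back to a full day; A day 4
    # excluded (hosp); B days 1-4: day 4 window covers days 2-4 (full on 2)
    assert rep.rolling3_full_days == 7
    rep.check_invariants()


def test_compliance_rate_ordering_invariant_random():
    rng = np.random.default_rng(8)
    for _ in range(20):
        avail = {
            f"P{k}": [
                tuple(rng.integers(0, 2, 4))
                for _ in range(int(rng.integers(4, 12)))
            ]
            for k in range(3)
        }
        tl = _toy_timeline(avail)
        th = tl[~tl["hospitalized"]]
        if th.empty:
            continue
        rep = compliance_rates(tl, period=(1, 12))
        rep.check_invariants()


def test_per_patient_rates_aggregate_to_cohort(tiny_timeline):
    rep = compliance_rates(tiny_timeline, period=(1, 14))
    pp = rep.per_patient
    agg = 100.0 * pp["full_days"].sum() / pp["theoretical_days"].sum()
    assert agg == pytest.approx(rep.full_rate)


def test_empty_period_flagged():
    tl = _toy_timeline({"A": [(1, 1, 1, 1)]})  # only a hospitalized day
    with pytest.warns(UserWarning, match="zero theoretical"):
        rep = compliance_rates(tl, period=(1, 1))
    assert rep.theoretical_days == 0
    assert np.isnan(rep.full_rate)


def test_longitudinal_compliance_shape(tiny_timeline):
    lon = longitudinal_compliance(tiny_timeline, max_day=14)
    assert set(lon.columns) >= {"day", "any_rate", "rolling3_full_rate"}
    assert ((lon["any_rate"] >= 0) & (lon["any_rate"] <= 100)).all()


def test_describe_parameters_examples_and_oracle(tiny_timeline):
    desc = describe_parameters(tiny_timeline).set_index("parameter")
    # constant series: median=q1=q3=min=max
    tl = tiny_timeline.copy()
    tl["mdasi_pain"] = 3.0
    d2 = describe_parameters(tl).set_index("parameter")
    row = d2.loc["pain"]
    assert row["median"] == row["q1"] == row["q3"] == row["min"] == row["max"] == 3.0
    # sort-based quantile oracle (linear interpolation convention)
    vals = tiny_timeline["mdasi_fatigue"].dropna().to_numpy()
    srt = np.sort(vals)

    def q(p):
        h = (len(srt) - 1) * p
        lo = int(np.floor(h))
        return srt[lo] + (h - lo) * (srt[min(lo + 1, len(srt) - 1)] - srt[lo])

    assert desc.loc["fatigue", "median"] == pytest.approx(q(0.5))
    assert desc.loc["fatigue", "q1"] == pytest.approx(q(0.25))
    assert desc.loc["fatigue", "q3"] == pytest.approx(q(0.75))
    assert desc.loc["fatigue", "min"] == srt[0]
    assert desc.loc["fatigue", "max"] == srt[-1]


def test_describe_simple_sequence():
    tl = _toy_timeline({"A": [(1, 1, 1, 0)] * 5})
    tl["weight_change"] = [0, 1, 2, 3, 4]
    tl["io"] = np.nan
    for col in (f"mdasi_{i}" for i in cw.MDASI_ITEMS):
        tl[col] = np.nan
    with pytest.warns(UserWarning):  # all-missing parameters omitted
        desc = describe_parameters(tl).set_index("parameter")
    assert desc.loc["weight_change", "median"] == 2
    assert desc.loc["weight_change", "min"] == 0
    assert desc.loc["weight_change", "max"] == 4
    assert "io" not in desc.index


def _event(pid, admission, planned=0):
    return {
        "patient_id": pid,
        "admission_date": pd.Timestamp(admission),
        "discharge_date": pd.Timestamp(admission) + pd.Timedelta(days=2),
        "planned": planned,
    }


def test_preevent_summary_sem_rules(tiny_timeline):
    # single event: SEM undefined -> missing
    ev = pd.DataFrame([_event("P001", "2012-01-12")])
    summary = summarize_preevent(tiny_timeline, ev, lookback_days=5)
    assert summary["sem"].isna().all()
    assert (summary["n"] == 1).all()
    # two events over identical data (same patient, same admission):
    # SEM exactly 0
    ev2 = pd.DataFrame([_event("P001", "2012-01-12"), _event("P001", "2012-01-12")])
    s2 = summarize_preevent(tiny_timeline, ev2, lookback_days=5)
    assert np.allclose(s2["sem"].dropna(), 0.0)
    # no unplanned events -> empty
    ev3 = pd.DataFrame([_event("P001", "2012-01-12", planned=1)])
    assert summarize_preevent(tiny_timeline, ev3).empty


def test_planted_decline_gives_decreasing_preevent_io_curve():
    """With a deterioration ramp planted, the mean pre-admission I<O
    curve decreases toward the event."""
    cfg = dataclasses.replace(
        cw.strong_signal_config(2),
        n_patients=6,
        deterioration=dataclasses.replace(
            cw.strong_signal_config(2).deterioration, onset_lag_days=10
        ),
        missingness=cw.Missingness(0.05, 0.05, 0.05),
    )
    cohort = cw.simulate_cohort(cfg)
    timeline = cw.assemble_timeline(cohort)
    summary = summarize_preevent(timeline, cohort.events, lookback_days=10)
    io = summary[summary["parameter"] == "io"].sort_values("offset")
    assert len(io) >= 6
    early = io[io["offset"] <= -7]["mean"].mean()
    late = io[io["offset"] >= -3]["mean"].mean()
    assert late < early - 2.0


def test_assembled_timeline_consistency(tiny_cohort, tiny_timeline):
    tl = tiny_timeline
    assert (tl.groupby("patient_id")["day"].diff().dropna() == 1).all()
    # weight change is 0 where the weight equals the baseline
    base_rows = tl[np.isclose(tl["weight_kg"], tl["baseline_weight_kg"])]
    if not base_rows.empty:
        np.testing.assert_allclose(base_rows["weight_change"], 0.0, atol=1e-9)
    # io in range
    io = tl["io"].dropna()
    assert ((io >= 0) & (io <= 100)).all()
    # availability flags match raw data
    assert (tl["weight_available"] == tl["weight_kg"].notna()).all()
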