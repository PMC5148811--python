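"""Daily time-series features for hospitalization prediction.

Each patient contributes 21 daily series: the 19 MDASI items, the body
weight change (%), and the dichotomy index I<O.  Missing days are
interpolated (edge gaps copy the nearest measured value; interior gaps
are filled linearly), then each series is reduced to its short-term
dynamics: the value of the day minus the mean of the same parameter on
the three previous days.  The binary target marks the days falling in a
fixed window (default 3 days) before an unplanned hospital admission.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError, InterpolationImpossibleError
from .schema import FEATURE_NAMES, MDASI_COLUMNS

__all__ = [
    "interpolate_series",
    "dynamics_transform",
    "label_prehospital_days",
    "assemble_features",
    "FeatureSet",
]

DYNAMICS_LOOKBACK = 3  # days averaged to form the reference level


def interpolate_series(values) -> np.ndarray:
    """Fill missing values of a daily series.

    Missing values at the beginning (end) of the series take the first
    (last) measured value; interior gaps are filled by linear
    interpolation between the flanking measured values.  Observed
    values are returned unchanged; a complete series is returned as-is.

    Raises
    ------
    InterpolationImpossibleError
        If the series contains no observed value.
    """
    x = np.asarray(values, dtype=float).ravel()
    observed = ~np.isnan(x)
    if not observed.any():
        raise InterpolationImpossibleError("series has no observed value")
    if observed.all():
        return x.copy()
    idx = np.arange(x.size)
    # np.interp clips outside the observed support, which realizes the
    # edge-fill rule exactly.
    return np.interp(idx, idx[observed], x[observed])


def dynamics_transform(values) -> tuple[np.ndarray, np.ndarray]:
    """Short-term dynamic change of a complete daily series.

    ``d[t] = x[t] - mean(x[t-1], x[t-2], x[t-3])``.  The first three
    days have no defined value: they are returned as ``nan`` with a
    false validity flag (warm-up).  A series shorter than 4 days yields
    an all-invalid output.
    """
    x = np.asarray(values, dtype=float).ravel()
    if np.isnan(x).any():
        raise DataError("dynamics_transform requires a complete series")
    d = np.full(x.size, np.nan)
    valid = np.zeros(x.size, dtype=bool)
    if x.size >= DYNAMICS_LOOKBACK + 1:
        k = DYNAMICS_LOOKBACK
        d[k:] = x[k:] - (x[k - 1 : -1] + x[k - 2 : -2] + x[: -k]) / 3.0
        valid[k:] = True
    return d, valid


def label_prehospital_days(
    events: pd.DataFrame,
    dates: pd.Series | pd.DatetimeIndex,
    window_days: int = 3,
) -> np.ndarray:
    """Mark the days preceding each unplanned admission.

    A day ``d`` is positive iff an unplanned admission exists at date
    ``a`` with ``1 <= a - d <= window_days``.  The admission day itself
    is never labelled (the patient is then in hospital), planned
    admissions never generate positives, and overlapping windows from
    nearby admissions are counted once.  Events whose admission window
    lies entirely outside the monitored dates are ignored with a
    warning.
    """
    dates = pd.DatetimeIndex(pd.to_datetime(dates)).normalize()
    labels = np.zeros(len(dates), dtype=bool)
    if events is None or events.empty:
        return labels
    monitored_min, monitored_max = dates.min(), dates.max()
    for _, ev in events.iterrows():
        if bool(ev["planned"]):
            continue
        admission = pd.Timestamp(ev["admission_date"]).normalize()
        lo = admission - pd.Timedelta(days=window_days)
        hi = admission - pd.Timedelta(days=1)
        if hi < monitored_min or lo > monitored_max:
            warnings.warn(
                f"unplanned admission {admission.date()} outside the monitored "
                "range; ignored for labelling",
                stacklevel=2,
            )
            continue
        labels |= np.asarray((dates >= lo) & (dates <= hi))
    # days spent in hospital are never labelled: the patient is not at
    # home, so they cannot be early-warning target days
    for _, ev in events.iterrows():
        admission = pd.Timestamp(ev["admission_date"]).normalize()
        discharge = ev.get("discharge_date")
        discharge = (
            pd.Timestamp(discharge).normalize()
            if discharge is not None and pd.notna(discharge)
            else admission
        )
        labels &= ~np.asarray((dates >= admission) & (dates <= discharge))
    return labels


@dataclass
class FeatureSet:
    """Feature matrix plus labels, one row per patient-day.

    ``matrix`` carries ``patient_id``, ``date``, ``day``, the 21 named
    feature columns (fixed order: 13 MDASI symptoms, 6 MDASI
    interference items, weight change, I<O), a boolean ``label`` and a
    boolean ``valid`` flag.  Warm-up days (no dynamics defined) and
    hospitalized days are marked invalid; modelling uses valid rows
    only.
    """

    matrix: pd.DataFrame
    feature_names: tuple[str, ...] = FEATURE_NAMES

    @property
    def X(self) -> pd.DataFrame:
        return self.matrix.loc[self.matrix["valid"], list(self.feature_names)]

    @property
    def y(self) -> np.ndarray:
        return self.matrix.loc[self.matrix["valid"], "label"].to_numpy(dtype=bool)

    def valid_rows(self) -> pd.DataFrame:
        return self.matrix[self.matrix["valid"]].reset_index(drop=True)


def _patient_features(
    tl: pd.DataFrame,
    events: pd.DataFrame,
    window_days: int,
    use_raw_io: bool,
) -> pd.DataFrame | None:
    tl = tl.sort_values("date").reset_index(drop=True)
    dates = pd.DatetimeIndex(pd.to_datetime(tl["date"])).normalize()
    if len(dates) > 1:
        gaps = np.diff(dates.to_numpy()) != np.timedelta64(1, "D")
        if gaps.any():
            bad = dates[1:][gaps]
            raise AlignmentError(
                f"non-contiguous dates in timeline: {[str(d.date()) for d in bad]}"
            )

    raw = {}
    for item, col in zip(FEATURE_NAMES[:19], MDASI_COLUMNS):
        raw[item] = tl[col].to_numpy(dtype=float)
    raw["weight_change"] = tl["weight_change"].to_numpy(dtype=float)
    raw["io"] = tl["io"].to_numpy(dtype=float)

    out = pd.DataFrame(
        {
            "patient_id": tl["patient_id"].to_numpy(),
            "date": dates,
            "day": np.arange(1, len(tl) + 1)
            if "day" not in tl
            else tl["day"].to_numpy(),
        }
    )
    valid = np.ones(len(tl), dtype=bool)
    for name in FEATURE_NAMES:
        try:
            filled = interpolate_series(raw[name])
        except InterpolationImpossibleError:
            warnings.warn(
                f"patient {tl['patient_id'].iloc[0]!r}: series {name!r} has no "
                "observed value; patient excluded from the feature matrix",
                stacklevel=2,
            )
            return None
        if use_raw_io and name == "io":
            out[name] = filled
            continue
        d, ok = dynamics_transform(filled)
        out[name] = d
        valid &= ok

    hospitalized = tl["hospitalized"].to_numpy(dtype=bool)
    valid &= ~hospitalized
    out["label"] = label_prehospital_days(events, dates, window_days)
    out["valid"] = valid
    return out


def assemble_features(
    timeline: pd.DataFrame,
    events: pd.DataFrame,
    window_days: int = 3,
    use_raw_io: bool = False,
) -> FeatureSet:
    """Build the cohort feature matrix and labels from a daily timeline.

    ``timeline`` is the assembled per-day table (one row per patient and
    calendar day, contiguous within each patient) carrying the 19 MDASI
    columns, ``weight_change``, ``io`` and ``hospitalized``.
    Interpolation and the dynamics transform are applied per patient and
    per series; rows for hospitalized days and the 3-day warm-up are
    masked out.  Row order is deterministic (patient, then date).

    ``use_raw_io=True`` keeps the interpolated I<O level itself instead
    of its dynamic change (alternative feature definition; the default
    treats all 21 series identically).
    """
    required = {"patient_id", "date", "weight_change", "io", "hospitalized"}
    missing = required - set(timeline.columns)
    if missing:
        raise AlignmentError(f"timeline lacks columns: {sorted(missing)}")

    pieces = []
    for pid in sorted(timeline["patient_id"].unique()):
        tl = timeline[timeline["patient_id"] == pid]
        ev = (
            events[events["patient_id"] == pid]
            if events is not None and not events.empty
            else pd.DataFrame(columns=["planned", "admission_date"])
        )
        piece = _patient_features(tl, ev, window_days, use_raw_io)
        if piece is not None:
            pieces.append(piece)
    if not pieces:
        cols = ["patient_id", "date", "day", *FEATURE_NAMES, "label", "valid"]
        return FeatureSet(pd.DataFrame(columns=cols))
    matrix = pd.concat(pieces, ignore_index=True)
    matrix = matrix.sort_values(["patient_id", "date"]).reset_index(drop=True)
    return FeatureSet(matrix)
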