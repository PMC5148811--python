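"""Circadian rest-activity metrics from epoch-level actigraphy.

The central statistic is the dichotomy index I<O: the percentage of
in-bed activity epochs whose counts fall strictly below the median
activity level of the out-of-bed epochs.  Values approach 100% when
sleep is restful and daytime activity is lively; in healthy adults I<O
rarely drops below 98%.  Here I<O is evaluated over 72-hour records
using 3-day sliding windows, one value per monitored day.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, EmptyInBedError, EmptyOutOfBedError

__all__ = [
    "EpochSeries",
    "dichotomy_index",
    "sliding_io",
    "bed_window_mask",
]

MINUTES_PER_DAY = 1440


@dataclass
class EpochSeries:
    """Per-minute wrist-activity counts for one patient.

    Parameters
    ----------
    patient_id
        Subject identifier.
    start
        Timestamp of the first epoch (minute resolution).
    epoch_minutes
        Epoch duration in minutes (1 for the wrist actigraph used here).
    counts
        Activity counts per epoch; ``nan`` where not observed.
    in_bed
        Per-epoch flag: subject was in bed.  This annotation comes from
        the input data; see :func:`bed_window_mask` for the clock-time
        fallback.
    observed
        Per-epoch wear/transmission flag.  ``counts`` may only be
        present where ``observed`` is true.
    """

    patient_id: str
    start: pd.Timestamp
    counts: np.ndarray
    in_bed: np.ndarray
    observed: np.ndarray
    epoch_minutes: int = 1

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.counts = np.asarray(self.counts, dtype=float)
        self.in_bed = np.asarray(self.in_bed, dtype=bool)
        self.observed = np.asarray(self.observed, dtype=bool)
        n = self.counts.size
        if self.in_bed.size != n or self.observed.size != n:
            raise DataError("EpochSeries sequences must have equal length")
        if self.epoch_minutes < 1 or MINUTES_PER_DAY % self.epoch_minutes:
            raise DataError("epoch_minutes must be a divisor of 1440")
        if np.any(~np.isnan(self.counts) & ~self.observed):
            raise DataError("counts present on epochs flagged unobserved")
        if np.any(self.counts[~np.isnan(self.counts)] < 0):
            raise DataError("negative activity counts")

    def __len__(self) -> int:
        return self.counts.size

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(len(self)) * self.epoch_minutes, unit="min"
        )

    def day_offsets(self) -> np.ndarray:
        """Calendar-day index of each epoch, 0 for the first monitored day."""
        ts = self.timestamps
        return (ts.normalize() - ts[0].normalize()).days.to_numpy()


def dichotomy_index(in_bed_counts, out_of_bed_counts) -> float:
    """Percentage of in-bed epochs strictly below the out-of-bed median.

    Both inputs must be complete (the caller filters to observed
    epochs).  The inequality is strict: an in-bed count exactly equal to
    the out-of-bed median does not contribute.

    Raises
    ------
    EmptyInBedError, EmptyOutOfBedError
        If either side of the window is empty.
    """
    a = np.asarray(in_bed_counts, dtype=float).ravel()
    b = np.asarray(out_of_bed_counts, dtype=float).ravel()
    if a.size == 0:
        raise EmptyInBedError("no in-bed epochs in window")
    if b.size == 0:
        raise EmptyOutOfBedError("no out-of-bed epochs in window")
    if np.isnan(a).any() or np.isnan(b).any():
        raise DataError("dichotomy_index requires complete sequences")
    median_out = float(np.median(b))
    return 100.0 * int(np.count_nonzero(a < median_out)) / a.size


def sliding_io(
    epochs: EpochSeries,
    window_days: int = 3,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Dichotomy index over trailing multi-day windows, one row per day.

    For each monitored day ``d`` with at least ``window_days`` days of
    history (itself included), I<O is computed from all observed epochs
    in the window of ``window_days`` calendar days ending with day
    ``d``, and assigned to day ``d``.  The window trails rather than
    centres so that a day's value never uses future data.

    The value is missing when the observed fraction of either the
    in-bed or the out-of-bed epochs within the window falls below
    ``min_coverage`` (or when a side is empty altogether).

    Returns
    -------
    DataFrame with columns ``date``, ``io``, ``coverage_in_bed``,
    ``coverage_out_of_bed``.  A series shorter than one window yields
    all-missing ``io``.
    """
    if window_days < 1:
        raise DataError("window_days must be >= 1")
    if not 0.0 <= min_coverage <= 1.0:
        raise DataError("min_coverage must be in [0, 1]")

    day = epochs.day_offsets()
    n_days = int(day.max()) + 1 if len(epochs) else 0
    first_date = epochs.start.normalize()

    have_count = ~np.isnan(epochs.counts)
    obs_in = epochs.observed & epochs.in_bed & have_count
    obs_out = epochs.observed & ~epochs.in_bed & have_count

    # Per-day epoch index ranges (epochs are in chronological order).
    rows = []
    counts = epochs.counts
    in_bed = epochs.in_bed
    per_day = [np.flatnonzero(day == d) for d in range(n_days)]
    for d in range(n_days):
        date = (first_date + pd.Timedelta(days=d)).date()
        if d < window_days - 1:
            rows.append((date, np.nan, np.nan, np.nan))
            continue
        idx = np.concatenate(per_day[d - window_days + 1 : d + 1])
        flagged_in = int(np.count_nonzero(in_bed[idx]))
        flagged_out = idx.size - flagged_in
        n_obs_in = int(np.count_nonzero(obs_in[idx]))
        n_obs_out = int(np.count_nonzero(obs_out[idx]))
        cov_in = n_obs_in / flagged_in if flagged_in else np.nan
        cov_out = n_obs_out / flagged_out if flagged_out else np.nan
        usable = (
            n_obs_in > 0
            and n_obs_out > 0
            and cov_in >= min_coverage
            and cov_out >= min_coverage
        )
        if usable:
            io = dichotomy_index(
                counts[idx[obs_in[idx]]], counts[idx[obs_out[idx]]]
            )
        else:
            io = np.nan
        rows.append((date, io, cov_in, cov_out))

    return pd.DataFrame(
        rows, columns=["date", "io", "coverage_in_bed", "coverage_out_of_bed"]
    )


def bed_window_mask(
    timestamps: pd.DatetimeIndex, bed_window: tuple[str, str] = ("23:00", "07:00")
) -> np.ndarray:
    """Fallback in-bed annotation from a fixed clock-time interval.

    This is a heuristic stand-in for use only when the input carries no
    explicit per-epoch in-bed flag (e.g. no diary or sleep scoring was
    available).  The interval may span midnight.
    """
    start = pd.Timestamp(f"2000-01-01 {bed_window[0]}")
    end = pd.Timestamp(f"2000-01-01 {bed_window[1]}")
    minutes = np.asarray(timestamps.hour) * 60 + np.asarray(timestamps.minute)
    m0 = start.hour * 60 + start.minute
    m1 = end.hour * 60 + end.minute
    if m0 <= m1:
        return (minutes >= m0) & (minutes < m1)
    return (minutes >= m0) | (minutes < m1)


def epoch_series_from_frame(frame: pd.DataFrame, patient_id=None) -> EpochSeries:
    """Build an :class:`EpochSeries` from an epochs table (one patient)."""
    df = frame
    if patient_id is not None:
        df = df[df["patient_id"] == patient_id]
    if df.empty:
        raise DataError(f"no epochs for patient {patient_id!r}")
    df = df.sort_values("timestamp")
    ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
    pid = str(df["patient_id"].iloc[0])
    step = 1
    if len(ts) > 1:
        step = int((ts[1] - ts[0]).total_seconds() // 60)
    return EpochSeries(
        patient_id=pid,
        start=ts[0],
        counts=df["activity_count"].to_numpy(dtype=float),
        in_bed=df["in_bed"].to_numpy(dtype=bool),
        observed=df["observed"].to_numpy(dtype=bool),
        epoch_minutes=max(step, 1),
    )


# dataclasses.replace is handy for tests that perturb one field
replace = dataclasses.replace
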