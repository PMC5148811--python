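"""CSV file contracts, validation and configuration loading.

All tables are comma-separated UTF-8 with a mandatory header row,
ISO 8601 timestamps (minute resolution) and dates, and empty fields for
missing values.  Every file written by the pipeline starts with a
comment line declaring the producing command and a hash of the
effective configuration; readers skip ``#`` comment lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .actigraphy import EpochSeries, epoch_series_from_frame
from .errors import ConfigError, DataError, SchemaError
from .schema import (
    COURSES_COLUMNS,
    DAILY_COLUMNS,
    EPOCHS_COLUMNS,
    EVENTS_COLUMNS,
    MDASI_COLUMNS,
)
from .simulate import Deterioration, Missingness, PatientData, SimulationConfig, SyntheticCohort

__all__ = [
    "read_table",
    "write_table",
    "read_epochs",
    "read_daily",
    "read_events",
    "read_courses",
    "write_cohort",
    "load_cohort",
    "load_simulation_config",
    "config_hash",
]


def _n_leading_comments(path: Path) -> int:
    n = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                n += 1
            else:
                break
    return n


def read_table(path, required_columns: tuple[str, ...]) -> pd.DataFrame:
    """Read a contract CSV, checking the header columns."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataError(f"{path}: malformed CSV: {exc}") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def _data_line(path: Path, row_index: int) -> int:
    """1-based file line of a data row (header + leading comments)."""
    return row_index + 2 + _n_leading_comments(Path(path))


def read_epochs(path) -> pd.DataFrame:
    df = read_table(path, EPOCHS_COLUMNS)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    bad = df.index[
        df["activity_count"].notna() & (df["activity_count"] < 0)
    ]
    if len(bad):
        raise SchemaError(
            f"{path}: negative activity_count at line {_data_line(path, bad[0])}"
        )
    present_unobserved = df.index[
        df["activity_count"].notna() & (df["observed"].astype(int) == 0)
    ]
    if len(present_unobserved):
        raise SchemaError(
            f"{path}: activity_count present on unobserved epoch at line "
            f"{_data_line(path, present_unobserved[0])}"
        )
    return df


def read_daily(path) -> pd.DataFrame:
    df = read_table(path, DAILY_COLUMNS)
    df["date"] = pd.to_datetime(df["date"])
    for col in MDASI_COLUMNS:
        vals = df[col]
        bad = df.index[vals.notna() & ((vals < 0) | (vals > 10))]
        if len(bad):
            raise SchemaError(
                f"{path}: {col} out of range [0, 10] at line "
                f"{_data_line(path, bad[0])}"
            )
    bad_w = df.index[df["weight_kg"].notna() & (df["weight_kg"] <= 0)]
    if len(bad_w):
        raise SchemaError(
            f"{path}: nonpositive weight_kg at line {_data_line(path, bad_w[0])}"
        )
    return df


def read_events(path) -> pd.DataFrame:
    df = read_table(path, EVENTS_COLUMNS)
    for col in ("admission_date", "discharge_date"):
        df[col] = pd.to_datetime(df[col])
    bad = df.index[df["discharge_date"] < df["admission_date"]]
    if len(bad):
        raise SchemaError(
            f"{path}: discharge before admission at line {_data_line(path, bad[0])}"
        )
    return df


def read_courses(path) -> pd.DataFrame:
    df = read_table(path, COURSES_COLUMNS)
    for col in ("start_date", "end_date"):
        df[col] = pd.to_datetime(df[col])
    return df


def config_hash(config) -> str:
    """Short stable hash of a configuration object or mapping."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = dataclasses.asdict(config)
    else:
        payload = dict(config)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, command: str, cfg_hash: str = "-") -> None:
    """Write a contract CSV with the provenance header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# circawarn:{command} config={cfg_hash}\n")
        df.to_csv(fh, index=False, date_format="%Y-%m-%dT%H:%M")
    # dates without time keep plain ISO dates via pandas; timestamps keep minutes


def write_cohort(cohort: SyntheticCohort, out_dir, command: str, cfg_hash: str) -> dict:
    """Write the four cohort tables; returns the path map."""
    out = Path(out_dir)
    daily = cohort.daily.copy()
    daily["date"] = pd.to_datetime(daily["date"]).dt.strftime("%Y-%m-%d")
    events = cohort.events.copy()
    courses = cohort.courses.copy()
    for frame, cols in ((events, ("admission_date", "discharge_date")),
                        (courses, ("start_date", "end_date"))):
        for col in cols:
            if not frame.empty:
                frame[col] = pd.to_datetime(frame[col]).dt.strftime("%Y-%m-%d")
    paths = {
        "epochs": out / "epochs.csv",
        "daily": out / "daily.csv",
        "events": out / "events.csv",
        "courses": out / "courses.csv",
    }
    write_table(cohort.epochs, paths["epochs"], command, cfg_hash)
    write_table(daily, paths["daily"], command, cfg_hash)
    write_table(events, paths["events"], command, cfg_hash)
    write_table(courses, paths["courses"], command, cfg_hash)
    return paths


def load_cohort(data_dir) -> SyntheticCohort:
    """Load a cohort from the four contract CSVs in ``data_dir``."""
    data_dir = Path(data_dir)
    epochs = read_epochs(data_dir / "epochs.csv")
    daily = read_daily(data_dir / "daily.csv")
    events = read_events(data_dir / "events.csv")
    courses = read_courses(data_dir / "courses.csv")

    patients = []
    for pid in sorted(daily["patient_id"].unique()):
        pe = epochs[epochs["patient_id"] == pid]
        series = (
            epoch_series_from_frame(pe)
            if not pe.empty
            else EpochSeries(
                patient_id=str(pid),
                start=pd.to_datetime(daily[daily["patient_id"] == pid]["date"]).min(),
                counts=np.array([], dtype=float),
                in_bed=np.array([], dtype=bool),
                observed=np.array([], dtype=bool),
            )
        )
        patients.append(
            PatientData(
                patient_id=str(pid),
                epochs=series,
                daily=daily[daily["patient_id"] == pid].reset_index(drop=True),
                events=events[events["patient_id"] == pid].reset_index(drop=True),
                courses=courses[courses["patient_id"] == pid].reset_index(drop=True),
            )
        )
    return SyntheticCohort(patients)


_SIM_SCALAR_FIELDS = {
    f.name for f in dataclasses.fields(SimulationConfig)
    if f.name not in ("deterioration", "missingness")
}


def load_simulation_config(path) -> SimulationConfig:
    """Read a simulation config from a flat key-value (YAML) file.

    Nested groups use dotted keys, e.g. ``missingness.weight: 0.2`` or
    ``deterioration.onset_lag_days: 10``.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config", "config file must be a flat key-value mapping")
    det_kwargs, miss_kwargs, scalar = {}, {}, {}
    for key, value in raw.items():
        if key.startswith("deterioration."):
            det_kwargs[key.split(".", 1)[1]] = value
        elif key.startswith("missingness."):
            miss_kwargs[key.split(".", 1)[1]] = value
        elif key in _SIM_SCALAR_FIELDS:
            if key in ("bed_window", "event_delay_range", "event_duration_range"):
                value = tuple(value)
            scalar[key] = value
        else:
            raise ConfigError(key, "unknown configuration key")
    try:
        det = Deterioration(**det_kwargs)
        miss = Missingness(**miss_kwargs)
        cfg = SimulationConfig(deterioration=det, missingness=miss, **scalar)
    except TypeError as exc:
        raise ConfigError("config", str(exc)) from exc
    cfg.validate()
    return cfg
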