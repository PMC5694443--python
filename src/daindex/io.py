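"""CSV dialects and YAML study-configuration loading.

All tabular artifacts are RFC-4180 CSV with a fixed column order;
trace timestamps are ISO-8601 in local study time.  Pipeline outputs
carry the study-configuration hash as a leading ``# config_hash=``
comment line.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .config import StudyConfig
from .containers import (
    HISTO_SUBSCORES,
    TRACE_COLUMNS,
    ActivityTrace,
    ClinicalRecord,
    StudyDataset,
)
from .errors import InputValidationError

log = logging.getLogger(__name__)

ANIMAL_COLUMNS = ["animal_id", "group", "induced", "treatment_effect", "compound", "dose"]
HISTO_COLUMNS = ["animal_id", "side", *HISTO_SUBSCORES]
MEASUREMENT_COLUMNS = ["animal_id", "study_day", "metric", "value"]


def write_traces(traces: dict[str, ActivityTrace], path: str | Path) -> Path:
    """Write all traces to one CSV (animal_id, timestamp, speed_mm_s)."""
    path = Path(path)
    frames = []
    for animal_id in sorted(traces):
        df = traces[animal_id].samples.copy()
        df.insert(0, "animal_id", animal_id)
        frames.append(df[TRACE_COLUMNS])
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRACE_COLUMNS)
    out = out.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)
    return path


def read_traces(path: str | Path) -> dict[str, ActivityTrace]:
    """Read a trace CSV; malformed rows are rejected with line numbers."""
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != TRACE_COLUMNS:
        raise InputValidationError(
            f"{path}: expected header {','.join(TRACE_COLUMNS)}, got {','.join(df.columns)}"
        )
    if df.empty:
        log.warning("%s: no data rows, returning empty trace set", path)
        return {}
    # +2: one for the header, one for 0- vs 1-based indexing
    lines = df.index.to_numpy() + 2
    speed = pd.to_numeric(df["speed_mm_s"], errors="coerce")
    bad = df.index[speed.isna() | (speed < 0)]
    if len(bad):
        where = ", ".join(str(lines[i]) for i in bad[:10])
        raise InputValidationError(f"{path}: invalid speed values at line(s) {where}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    bad = df.index[ts.isna()]
    if len(bad):
        where = ", ".join(str(lines[i]) for i in bad[:10])
        raise InputValidationError(f"{path}: unparseable timestamps at line(s) {where}")

    traces: dict[str, ActivityTrace] = {}
    offenders = []
    for animal_id, sub in df.assign(timestamp=ts, speed_mm_s=speed).groupby(
        "animal_id", sort=True
    ):
        t = sub["timestamp"]
        if not (t.is_monotonic_increasing and not t.duplicated().any()):
            offenders.append(str(animal_id))
            continue
        traces[str(animal_id)] = ActivityTrace(
            str(animal_id),
            sub[["timestamp", "speed_mm_s"]].reset_index(drop=True),
        )
    if offenders:
        raise InputValidationError(
            f"{path}: non-monotone timestamps for animal(s) {', '.join(offenders)}"
        )
    return traces


def write_measurements(clinical: dict[str, ClinicalRecord], path: str | Path) -> Path:
    frames = [clinical[a].measurements[MEASUREMENT_COLUMNS] for a in sorted(clinical)]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=MEASUREMENT_COLUMNS
    )
    out.to_csv(path, index=False)
    return Path(path)


def write_histopath(clinical: dict[str, ClinicalRecord], path: str | Path) -> Path:
    frames = [
        clinical[a].histopath[HISTO_COLUMNS]
        for a in sorted(clinical)
        if clinical[a].histopath is not None
    ]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=HISTO_COLUMNS
    )
    out.to_csv(path, index=False)
    return Path(path)


def read_clinical(
    measurements_path: str | Path, histopath_path: Optional[str | Path] = None
) -> dict[str, ClinicalRecord]:
    """Assemble per-animal clinical records from the long-format CSVs."""
    m = pd.read_csv(measurements_path)
    missing = set(MEASUREMENT_COLUMNS) - set(m.columns)
    if missing:
        raise InputValidationError(f"measurements missing columns {sorted(missing)}")
    histo = None
    if histopath_path is not None and Path(histopath_path).exists():
        histo = pd.read_csv(histopath_path)
    records: dict[str, ClinicalRecord] = {}
    for animal_id, sub in m.groupby("animal_id", sort=True):
        h = None
        if histo is not None:
            h = histo[histo["animal_id"] == animal_id].reset_index(drop=True)
            if h.empty:
                h = None
        records[str(animal_id)] = ClinicalRecord(
            str(animal_id), sub.reset_index(drop=True), h
        )
    return records


def write_dataset(dataset: StudyDataset, out_dir: str | Path) -> Path:
    """Write a study dataset (traces/measurements/histopath/animals CSVs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_traces(dataset.traces, out / "traces.csv")
    write_measurements(dataset.clinical, out / "measurements.csv")
    write_histopath(dataset.clinical, out / "histopath.csv")
    dataset.animals[ANIMAL_COLUMNS].to_csv(out / "animals.csv", index=False)
    return out


def read_dataset(data_dir: str | Path, config: Optional[StudyConfig] = None) -> StudyDataset:
    data = Path(data_dir)
    traces = read_traces(data / "traces.csv")
    clinical = read_clinical(data / "measurements.csv", data / "histopath.csv")
    animals_path = data / "animals.csv"
    if animals_path.exists():
        animals = pd.read_csv(animals_path)
    else:
        ids = sorted(set(traces) | set(clinical))
        animals = pd.DataFrame(
            {"animal_id": ids, "group": "all", "induced": True,
             "treatment_effect": 1.0, "compound": None, "dose": None}
        )
    return StudyDataset(animals, traces, clinical, config).validate()


def load_study_config(path: Optional[str | Path]) -> StudyConfig:
    """Load a YAML study configuration; absent sections fall back to
    package defaults (logged), and ``None`` loads the defaults wholesale."""
    if path is None:
        log.info("no config file given; using package defaults")
        return StudyConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise InputValidationError(f"{path}: top level must be a mapping")
    defaults = {
        "thresholds": "thresholds (0.25 in / 4 / 5)",
        "calendar": "study calendar",
        "schedule": "light schedule 06:00-18:00",
        "endpoint": "humane-endpoint rule",
        "feature": "feature settings (q99, K=20)",
        "simulation": "simulator parameters",
    }
    for key, desc in defaults.items():
        if key not in raw:
            log.warning("config %s missing %r; falling back to default %s", path, key, desc)
    return StudyConfig.model_validate(raw)


def write_csv_with_hash(df: pd.DataFrame, path: str | Path, config_hash: str) -> Path:
    """Write a pipeline CSV prefixed with a ``# config_hash=`` comment line."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)
    return path


def read_csv_with_hash(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
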