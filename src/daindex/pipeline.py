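"""End-to-end study pipeline: data -> features -> DAI -> outcomes -> tables.

``run_pipeline`` produces a fixed set of deterministic artifacts in the
output directory (features.csv, dai.csv, outcomes.csv,
group_summary.csv, correlations.csv, ranks.csv, run.json); every CSV
carries the configuration hash, and rerunning with identical inputs is
byte-identical.  Any stage failure removes partial outputs and raises
:class:`PipelineError` tagged with the stage name.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .clinical import animal_histopath, histopath_total
from .config import StudyConfig
from .containers import HISTO_SUBSCORES, StudyDataset
from .errors import DaindexError, PipelineError
from .features import compute_dai_table
from .io import read_dataset, write_csv_with_hash, write_dataset
from .metrics import animal_outcomes
from .simulate import simulate_cohort
from .stats import correlation_table, rank_compounds, summarize_groups

log = logging.getLogger(__name__)

RANK_METHODS = ["total_score", "dai", "inflammation", "arthritis_score", "delta_joint_in"]


def simulate_study(config: StudyConfig) -> StudyDataset:
    """Simulate the study described by the configuration's groups."""
    dataset = simulate_cohort(
        config.simulation, config.groups, config.calendar, config.schedule
    )
    dataset.config = config
    return dataset


def severity_table(outcomes: pd.DataFrame, dataset: StudyDataset) -> pd.DataFrame:
    """One row per animal: endpoint severities plus histopathology scores."""
    pivot = outcomes.pivot_table(
        index="animal_id", columns="metric", values="severity", aggfunc="first"
    )
    pivot = pivot.rename(columns={"joint_size": "delta_joint_in"})
    rows = []
    for animal_id in pivot.index:
        row = {"animal_id": animal_id}
        for col in ("dai", "delta_joint_in", "arthritis_score"):
            row[col] = pivot.loc[animal_id].get(col)
        record = dataset.clinical.get(animal_id)
        if record is not None and record.histopath is not None and len(record.histopath):
            h = record.histopath.set_index("side")
            for name in HISTO_SUBSCORES:
                row[name] = float(h[name].mean())
            totals = {
                side: histopath_total(h.loc[side, list(HISTO_SUBSCORES)])
                for side in h.index
            }
            row["total_score"] = animal_histopath(
                totals.get("left"), totals.get("right")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def compound_rank_table(severity: pd.DataFrame, animals: pd.DataFrame) -> pd.DataFrame:
    """Per-compound severity means with competition ranks, Table-4 shape.

    Animals without a compound assignment (vehicle, naive controls) are
    excluded from ranking.
    """
    merged = severity.merge(
        animals[["animal_id", "compound"]], on="animal_id"
    )
    merged = merged[merged["compound"].notna()]
    methods = [m for m in RANK_METHODS if m in merged.columns]
    if merged["compound"].nunique() < 2 or not methods:
        return pd.DataFrame(columns=["compound"])
    means = merged.groupby("compound")[methods].mean()
    sds = merged.groupby("compound")[methods].std(ddof=1)
    ranks = rank_compounds(means)
    out = pd.DataFrame({"compound": means.index})
    for m in methods:
        out[f"{m}_mean"] = means[m].to_numpy()
        out[f"{m}_sd"] = sds[m].to_numpy()
        out[f"{m}_rank"] = ranks[m].to_numpy(dtype=float)
    return out.sort_values(methods[0] + "_mean", kind="stable").reset_index(drop=True)


def run_pipeline(
    config: StudyConfig,
    out_dir: str | Path,
    data_dir: Optional[str | Path] = None,
    dataset: Optional[StudyDataset] = None,
) -> Path:
    """Run every stage and write the artifact set to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    chash = config.config_hash()
    stage = "load"
    try:
        if dataset is None:
            if data_dir is not None:
                dataset = read_dataset(data_dir, config)
            else:
                stage = "simulate"
                dataset = simulate_study(config)

        stage = "features"
        features, dai, baselines, excluded = compute_dai_table(
            dataset.traces, config.calendar, config.schedule, config.feature
        )
        if excluded:
            log.warning("excluded animals without usable baseline: %s", excluded)
        written.append(write_csv_with_hash(features, out / "features.csv", chash))
        written.append(write_csv_with_hash(dai, out / "dai.csv", chash))

        stage = "outcomes"
        outcomes = animal_outcomes(
            dai, dataset.clinical, config.thresholds, config.endpoint, config.calendar,
            animal_ids=sorted(dataset.animals["animal_id"]),
        )
        written.append(write_csv_with_hash(outcomes, out / "outcomes.csv", chash))

        stage = "summarize"
        summary = summarize_groups(outcomes, dataset.animals)
        written.append(write_csv_with_hash(summary, out / "group_summary.csv", chash))

        stage = "correlate"
        severity = severity_table(outcomes, dataset)
        corr = correlation_table(severity)
        corr_out = corr.reset_index(names="measure")
        written.append(write_csv_with_hash(corr_out, out / "correlations.csv", chash))

        stage = "rank"
        ranks = compound_rank_table(severity, dataset.animals)
        written.append(write_csv_with_hash(ranks, out / "ranks.csv", chash))

        stage = "log"
        run_info = {
            "config_hash": chash,
            "seed": config.simulation.seed,
            "package_version": __version__,
            "n_animals": int(len(dataset.animals)),
            "excluded_animals": excluded,
            "artifacts": sorted(p.name for p in written),
        }
        log_path = out / "run.json"
        log_path.write_text(json.dumps(run_info, indent=2, sort_keys=True) + "\n")
        written.append(log_path)
    except DaindexError as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
    except Exception as exc:  # pragma: no cover - defensive cleanup
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, f"{type(exc).__name__}: {exc}") from exc
    return out
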