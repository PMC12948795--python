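"""Figures and run manifests for a fitted analysis.

Outputs mirror the study's summary graphics: total 7-day activity and mean
peak-activity time by chronotype group, and model-implied reaction-time
trajectories across the day per group evaluated from the fitted mixed
model (fan-shaped, converging toward evening, when the chronotype x time
interaction opposes the chronotype main effect). Every run also writes a
JSON manifest (seed, config hash, exclusion counts) so results are
traceable to their configuration; identical config + seed give a
byte-identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from chronocog.chronotype import GROUP_LABELS, ChronotypeAssignment


def config_hash(config) -> str:
    """Stable sha256 over the (dataclass) configuration."""
    if dataclasses.is_dataclass(config):
        payload = dataclasses.asdict(config)
    else:
        payload = dict(config)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(
    out_dir: str | Path,
    config,
    seed: int,
    exclusion_counts: Mapping[str, int] | None = None,
    extra: Mapping | None = None,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": int(seed),
        "config_hash": config_hash(config),
        "exclusion_counts": dict(exclusion_counts or {}),
        **(dict(extra) if extra else {}),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n", "utf-8")
    return path


def _group_frame(features: pd.DataFrame, assignments: Sequence[ChronotypeAssignment]) -> pd.DataFrame:
    groups = pd.DataFrame(
        [(a.participant_id, a.group) for a in assignments],
        columns=["participant_id", "chronotype_group"],
    )
    return features.merge(groups, on="participant_id")


def plot_activity_by_group(
    features: pd.DataFrame,
    assignments: Sequence[ChronotypeAssignment],
    out_dir: str | Path,
) -> list[Path]:
    """Bar plots of total 7-day AUC and mean peak time per chronotype group."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = _group_frame(features[features["included"]], assignments)
    order = [g for g in GROUP_LABELS[::-1] if g in set(df["chronotype_group"])]  # early first
    paths = []
    for col, ylabel, fname in (
        ("total_auc_7day", "7-day total AUC (arbitrary units)", "fig_total_auc_by_group.png"),
        ("mean_peak_time_h", "Mean peak activity time (h)", "fig_peak_time_by_group.png"),
    ):
        stats_df = df.groupby("chronotype_group")[col].agg(["mean", "sem"]).reindex(order)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(stats_df.index, stats_df["mean"], yerr=stats_df["sem"], capsize=4, color="#4878a8")
        ax.set_ylabel(ylabel)
        ax.set_xlabel("Chronotype group")
        ax.tick_params(axis="x", rotation=30)
        fig.tight_layout()
        p = out / fname
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths


def plot_model_trajectories(
    lmm_result,
    table: pd.DataFrame,
    assignments: Sequence[ChronotypeAssignment],
    out_dir: str | Path,
    time_grid: np.ndarray | None = None,
) -> Path:
    """Model-implied outcome versus time of day, one line per chronotype group.

    Each line evaluates the fixed effects at the group's mean chronotype
    score with the remaining covariates at their sample means.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if time_grid is None:
        time_grid = np.linspace(7.0, 23.0, 50)
    score_by_group: dict[str, list[int]] = {}
    for a in assignments:
        score_by_group.setdefault(a.group, []).append(a.score)
    cov = table.drop_duplicates(["participant_id", "task", "time_of_day_h"])
    age, male, caf, auc = (
        float(cov["age"].mean()),
        float(cov["sex_male"].mean()),
        float(cov["caffeine_yes"].mean()),
        float(cov["activity_prior_60min"].mean()),
    )
    fig, ax = plt.subplots(figsize=(6, 4))
    for group in [g for g in GROUP_LABELS[::-1] if g in score_by_group]:
        c = float(np.mean(score_by_group[group]))
        y = lmm_result.predict_fixed(time_grid, c, age, male, caf, auc)
        ax.plot(time_grid, y, label=group)
    ax.set_xlabel("Time of day (h)")
    ax.set_ylabel(f"Model-implied {lmm_result.outcome_name} ({lmm_result.task})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    p = out / f"fig_trajectories_{lmm_result.task}_{lmm_result.outcome_name}.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    return p


def report_figures(
    out_dir: str | Path,
    config,
    seed: int,
    features: pd.DataFrame,
    assignments: Sequence[ChronotypeAssignment],
    table: pd.DataFrame,
    lmm_results: Mapping[str, object] | None = None,
    exclusion_counts: Mapping[str, int] | None = None,
) -> dict[str, Path]:
    """Emit all report artifacts; returns name -> path."""
    out = Path(out_dir)
    paths: dict[str, Path] = {}
    for p in plot_activity_by_group(features, assignments, out):
        paths[p.stem] = p
    for key, res in (lmm_results or {}).items():
        p = plot_model_trajectories(res, table, assignments, out)
        paths[p.stem] = p
    paths["manifest"] = write_manifest(out, config, seed, exclusion_counts)
    return paths
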