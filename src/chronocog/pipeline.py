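"""End-to-end reproducible runs: simulate -> score -> actigraphy ->
cognition -> assemble -> fit -> report.

`RunConfig` collects every stage parameter; its defaults are the study's
stated settings (60-min rolling window, 90% wear requirement, 125/5000 ms
RT validity bounds, 8/10 engagement error thresholds, 200 mg caffeine
cut-off, alpha = 0.05). A run either simulates its inputs or reads an
existing dataset directory (``cohort.csv``, ``trials.csv``,
``epochs_<id>.csv``), writes every intermediate artifact as CSV under the
output directory, and stamps a manifest with the seed and a configuration
hash. Re-runs refuse to overwrite a completed output directory unless
forced. Exclusions are logged one event per line so every count in the
outputs can be reconstructed from the run log.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from chronocog import actigraphy as act
from chronocog import inference, report
from chronocog import simulate as sim
from chronocog.chronotype import (
    CMQResponse,
    assign_quintiles,
    assignments_frame,
    load_cmq_key,
    score_cmq,
)
from chronocog.cognition import (
    boxcox_if_needed,
    exclude_low_engagement,
    sessions_from_trials_frame,
    summaries_frame,
    summarize_session,
)
from chronocog.errors import ConfigurationError

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run; defaults are the study settings."""

    out_dir: str = "results/run"
    data_dir: str | None = None  # None -> simulate inputs
    seed: int = 0
    simulate: bool = True
    force: bool = False
    log_level: str = "INFO"

    # stage parameters
    window_minutes: int = 60
    nonwear_zero_run_minutes: int = 60
    wear_threshold: float = 0.9
    rt_lower_ms: float = 125.0
    rt_upper_ms: float = 5000.0
    engagement_thresholds: dict = field(default_factory=lambda: {"XNA1": 8, "XNA2": 10})
    caffeine_threshold_mg: float = 200.0
    alpha: float = 0.05
    peak_mean_method: str = "circular"
    fit_tasks: tuple = ("XNA1", "XNA2")
    fit_outcomes: tuple = ("rt", "errors")
    sim_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.wear_threshold <= 1:
            raise ConfigurationError("wear_threshold: must lie in (0, 1]")
        if self.rt_lower_ms >= self.rt_upper_ms:
            raise ConfigurationError("rt_lower_ms: must be below rt_upper_ms")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha: must lie in (0, 1)")

    def simulation_config(self) -> sim.SimulationConfig:
        return sim.SimulationConfig(rng_seed=self.seed, **self.sim_overrides)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _load_dataset(data_dir: Path) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, act.EpochSeries]]:
    cohort = pd.read_csv(data_dir / "cohort.csv")
    trials = pd.read_csv(data_dir / "trials.csv")
    series = {}
    for path in sorted(data_dir.glob("epochs_*.csv")):
        pid = path.stem.removeprefix("epochs_")
        series[pid] = act.read_epoch_csv(path, participant_id=pid)
    return cohort, trials, series


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns a dict of artifact paths and results."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not config.force:
        raise ConfigurationError(
            f"out_dir: {out} already holds a completed run; pass force=True/--force to overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    if config.simulate and config.data_dir is None:
        data_dir = out / "data"
        sim_cfg = config.simulation_config()
        sim.write_dataset(sim_cfg, data_dir)
        log.info("simulated dataset written to %s", data_dir)
    else:
        data_dir = Path(config.data_dir)
        sim_cfg = config.simulation_config()
    cohort, trials, series = _load_dataset(data_dir)

    # --- score ------------------------------------------------------------
    key = load_cmq_key()
    item_cols = [c for c in cohort.columns if c.startswith("cmq_")]
    scores = []
    for row in cohort.itertuples():
        sels = tuple(int(getattr(row, c)) - 1 for c in item_cols)
        scores.append(
            (str(row.participant_id), score_cmq(CMQResponse(str(row.participant_id), sels), key))
        )
    assignments = assign_quintiles(scores)
    assignments_frame(assignments).to_csv(out / "assignments.csv", index=False)

    # --- actigraphy -------------------------------------------------------
    summaries_act = []
    for pid, s in series.items():
        summary = act.summarize_activity(
            s,
            window_minutes=config.window_minutes,
            wear_threshold=config.wear_threshold,
            zero_run_minutes=config.nonwear_zero_run_minutes,
            peak_mean_method=config.peak_mean_method,
        )
        if not summary.included:
            log.info(
                "exclusion participant=%s stage=actigraphy rule=wear_fraction value=%.3f",
                pid,
                summary.wear_fraction,
            )
        summaries_act.append(summary)
    features = act.features_frame(summaries_act)
    features.to_csv(out / "features.csv", index=False, float_format="%.6f")
    included_series = {
        s.participant_id: series[s.participant_id] for s in summaries_act if s.included
    }

    # --- cognition --------------------------------------------------------
    session_records = sessions_from_trials_frame(trials)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        session_summaries = [
            exclude_low_engagement(
                summarize_session(
                    rec,
                    rt_bounds_ms=(config.rt_lower_ms, config.rt_upper_ms),
                    caffeine_threshold_mg=config.caffeine_threshold_mg,
                ),
                thresholds=config.engagement_thresholds,
            )
            for rec in session_records
        ]
    summaries_frame(session_summaries).to_csv(out / "sessions.csv", index=False, float_format="%.4f")

    # --- assemble ---------------------------------------------------------
    demographics = cohort[["participant_id", "age", "sex"]].copy()
    demographics["participant_id"] = demographics["participant_id"].astype(str)
    table = inference.assemble_analysis_table(
        included_series, assignments, session_summaries, demographics
    )
    table.to_csv(out / "analysis_table.csv", index=False, float_format="%.6f")
    exclusions = dict(table.attrs.get("dropped", {}))

    # --- fit --------------------------------------------------------------
    anova = inference.anova_tables(features, assignments)
    anova_rows = []
    for name, res in anova.items():
        anova_rows.append(
            {
                "outcome": name,
                "F": res.F,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "p": res.p,
                "partial_eta_sq": res.partial_eta_sq,
            }
        )
    pd.DataFrame(anova_rows).to_csv(out / "anova.csv", index=False, float_format="%.6f")

    lmm_results = {}
    transforms = {}
    for task in config.fit_tasks:
        for outcome in config.fit_outcomes:
            d = table[(table["task"] == task) & (table["outcome_name"] == outcome)]
            if d.empty:
                continue
            transform = None
            if outcome == "rt":
                transform = boxcox_if_needed(d["outcome_value"].to_numpy(), alpha=config.alpha)
                transforms[f"{task}_{outcome}"] = {
                    "shapiro_p": transform.shapiro_p,
                    "lambda": transform.lmbda if transform.applied else None,
                }
            res = inference.fit_lmm(
                table, outcome_name=outcome, task=task, transform=transform, alpha=config.alpha
            )
            lmm_results[f"{task}_{outcome}"] = res
            tbl = res.terms.reset_index(names="term")
            tbl.to_csv(out / f"lmm_{task}_{outcome}.csv", index=False, float_format="%.6g")

    # --- report -----------------------------------------------------------
    figure_models = {k: v for k, v in lmm_results.items() if k.endswith("_rt")}
    report.report_figures(
        out,
        config,
        config.seed,
        features,
        assignments,
        table,
        lmm_results=figure_models,
        exclusion_counts=exclusions,
    )
    return {
        "out_dir": out,
        "assignments": assignments,
        "features": features,
        "table": table,
        "anova": anova,
        "lmm": lmm_results,
        "transforms": transforms,
        "exclusions": exclusions,
    }
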