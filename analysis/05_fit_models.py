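#!/usr/bin/env python
"""Step 5: assemble the analysis table and fit the ANOVA and mixed models."""

import argparse
from pathlib import Path

import pandas as pd

from chronocog import actigraphy as act
from chronocog import inference
from chronocog.chronotype import ChronotypeAssignment
from chronocog.cognition import SessionSummary, boxcox_if_needed


def _read_assignments(path: Path) -> list[ChronotypeAssignment]:
    df = pd.read_csv(path)
    return [
        ChronotypeAssignment(str(r.participant_id), int(r.cmq_score), str(r.chronotype_group))
        for r in df.itertuples()
    ]


def _read_summaries(path: Path) -> list[SessionSummary]:
    df = pd.read_csv(path)
    return [
        SessionSummary(
            participant_id=str(r.participant_id),
            task=str(r.task),
            session_timestamp=pd.Timestamp(r.session_timestamp),
            time_of_day_h=float(r.time_of_day_h),
            mean_rt_ms=None if pd.isna(r.mean_rt_ms) else float(r.mean_rt_ms),
            n_errors=int(r.n_errors),
            n_valid_rt=int(r.n_valid_rt),
            caffeine_flag=bool(r.caffeine_flag),
            excluded=bool(r.excluded),
            exclusion_reason="" if pd.isna(r.exclusion_reason) else str(r.exclusion_reason),
        )
        for r in df.itertuples()
    ]


def main() -> None:
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--data", type=Path, default=Path("results/data"))
    p.add_argument("--results", type=Path, default=Path("results"))
    args = p.parse_args()

    cohort = pd.read_csv(args.data / "cohort.csv")
    series = {}
    for path in sorted(args.data.glob("epochs_*.csv")):
        pid = path.stem.removeprefix("epochs_")
        s = act.read_epoch_csv(path, participant_id=pid)
        if act.compute_wear_fraction(s) >= act.WEAR_FRACTION_THRESHOLD:
            series[pid] = s
    assignments = _read_assignments(args.results / "assignments.csv")
    summaries = _read_summaries(args.results / "sessions.csv")
    demographics = cohort[["participant_id", "age", "sex"]].copy()
    demographics["participant_id"] = demographics["participant_id"].astype(str)

    table = inference.assemble_analysis_table(series, assignments, summaries, demographics)
    table.to_csv(args.results / "analysis_table.csv", index=False, float_format="%.6f")

    features = pd.read_csv(args.results / "features.csv")
    anova = inference.anova_tables(features, assignments)
    rows = [
        {
            "outcome": name,
            "F": res.F,
            "df_between": res.df_between,
            "df_within": res.df_within,
            "p": res.p,
            "partial_eta_sq": res.partial_eta_sq,
        }
        for name, res in anova.items()
    ]
    pd.DataFrame(rows).to_csv(args.results / "anova.csv", index=False, float_format="%.6f")

    for task in ("XNA1", "XNA2"):
        for outcome in ("rt", "errors"):
            d = table[(table["task"] == task) & (table["outcome_name"] == outcome)]
            if d.empty:
                continue
            transform = boxcox_if_needed(d["outcome_value"].to_numpy()) if outcome == "rt" else None
            res = inference.fit_lmm(table, outcome_name=outcome, task=task, transform=transform)
            out = args.results / f"lmm_{task}_{outcome}.csv"
            res.terms.reset_index(names="term").to_csv(out, index=False, float_format="%.6g")
            print(f"{task}/{outcome}:")
            print(res.terms.to_string())
    print(f"models written under {args.results}")


if __name__ == "__main__":
    main()
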