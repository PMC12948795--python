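#!/usr/bin/env python
"""Step 7: figures (activity by group, model-implied RT trajectories)."""

import argparse
from pathlib import Path

import pandas as pd

from chronocog import inference, report
from chronocog.chronotype import ChronotypeAssignment
from chronocog.cognition import boxcox_if_needed


def main() -> None:
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--results", type=Path, default=Path("results"))
    p.add_argument("--seed", type=int, default=0)
    args = p.parse_args()

    features = pd.read_csv(args.results / "features.csv")
    adf = pd.read_csv(args.results / "assignments.csv")
    assignments = [
        ChronotypeAssignment(str(r.participant_id), int(r.cmq_score), str(r.chronotype_group))
        for r in adf.itertuples()
    ]
    table = pd.read_csv(args.results / "analysis_table.csv")

    lmm_results = {}
    for task in ("XNA1", "XNA2"):
        d = table[(table["task"] == task) & (table["outcome_name"] == "rt")]
        if d.empty:
            continue
        transform = boxcox_if_needed(d["outcome_value"].to_numpy())
        lmm_results[f"{task}_rt"] = inference.fit_lmm(
            table, outcome_name="rt", task=task, transform=transform
        )

    paths = report.report_figures(
        args.results,
        {"source": "analysis scripts 01-07"},
        args.seed,
        features,
        assignments,
        table,
        lmm_results=lmm_results,
    )
    for name, path in sorted(paths.items()):
        print(f"{name}: {path}")


if __name__ == "__main__":
    main()
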