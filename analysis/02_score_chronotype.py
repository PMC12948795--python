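#!/usr/bin/env python
"""Step 2: score CMQ sheets and assign quintile chronotype groups."""

import argparse
from pathlib import Path

import pandas as pd

from chronocog.chronotype import (
    CMQResponse,
    assign_quintiles,
    assignments_frame,
    load_cmq_key,
    score_cmq,
)


def main() -> None:
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--data", type=Path, default=Path("results/data"))
    p.add_argument("--out", type=Path, default=Path("results/assignments.csv"))
    args = p.parse_args()

    key = load_cmq_key()
    cohort = pd.read_csv(args.data / "cohort.csv")
    item_cols = [c for c in cohort.columns if c.startswith("cmq_")]
    scores = []
    for row in cohort.itertuples():
        sels = tuple(int(getattr(row, c)) - 1 for c in item_cols)
        pid = str(row.participant_id)
        scores.append((pid, score_cmq(CMQResponse(pid, sels), key)))
    assignments = assign_quintiles(scores)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    assignments_frame(assignments).to_csv(args.out, index=False)
    print(f"scored {len(scores)} participants -> {args.out}")


if __name__ == "__main__":
    main()
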