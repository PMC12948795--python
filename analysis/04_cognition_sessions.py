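#!/usr/bin/env python
"""Step 4: clean trial logs into per-session cognition summaries."""

import argparse
from pathlib import Path

import pandas as pd

from chronocog.cognition import (
    exclude_low_engagement,
    sessions_from_trials_frame,
    summaries_frame,
    summarize_session,
)


def main() -> None:
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--data", type=Path, default=Path("results/data"))
    p.add_argument("--out", type=Path, default=Path("results/sessions.csv"))
    args = p.parse_args()

    records = sessions_from_trials_frame(pd.read_csv(args.data / "trials.csv"))
    summaries = [exclude_low_engagement(summarize_session(r)) for r in records]
    args.out.parent.mkdir(parents=True, exist_ok=True)
    summaries_frame(summaries).to_csv(args.out, index=False, float_format="%.4f")
    n_excluded = sum(s.excluded for s in summaries)
    print(f"{len(summaries)} sessions ({n_excluded} engagement-excluded) -> {args.out}")


if __name__ == "__main__":
    main()
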