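#!/usr/bin/env python
"""Step 3: extract wear, rolling-AUC and peak-time features per participant."""

import argparse
from pathlib import Path

from chronocog import actigraphy as act


def main() -> None:
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--data", type=Path, default=Path("results/data"))
    p.add_argument("--out", type=Path, default=Path("results/features.csv"))
    args = p.parse_args()

    summaries = []
    for path in sorted(args.data.glob("epochs_*.csv")):
        pid = path.stem.removeprefix("epochs_")
        series = act.read_epoch_csv(path, participant_id=pid)
        summaries.append(act.summarize_activity(series))
    args.out.parent.mkdir(parents=True, exist_ok=True)
    act.features_frame(summaries).to_csv(args.out, index=False, float_format="%.6f")
    n_excluded = sum(not s.included for s in summaries)
    print(f"{len(summaries)} participants ({n_excluded} wear-excluded) -> {args.out}")


if __name__ == "__main__":
    main()
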