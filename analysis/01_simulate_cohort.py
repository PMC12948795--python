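#!/usr/bin/env python
"""Step 1: write the synthetic study dataset (cohort, epoch and trial CSVs)."""

import argparse
from pathlib import Path

from chronocog import simulate as sim


def main() -> None:
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--seed", type=int, default=0)
    p.add_argument("--out", type=Path, default=Path("results/data"))
    args = p.parse_args()

    cfg = sim.SimulationConfig(rng_seed=args.seed)
    study = sim.write_dataset(cfg, args.out)
    print(f"wrote {len(study.profiles)} participants to {args.out}")


if __name__ == "__main__":
    main()
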