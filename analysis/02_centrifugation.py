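#!/usr/bin/env python
"""Dual vs prolonged single centrifugation, and the order-of-draw check.

Runs experiment 1 end-to-end on the simulated 30-tube series: per
protocol and normalization strategy it reports the mean relative level,
the whole-procedure CV, and the protocol-comparison t-test; then the
first-10 vs last-10 order-of-draw t-test. Under the study preset the
generator encodes protocol equivalence, so the expected finding is
"no significant protocol difference, CVs in the 8-20% range".
"""

import argparse
from pathlib import Path

import pandas as pd

from mirvar.pipeline import RunManifest, run_experiment_1


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    paths = run_experiment_1(RunManifest(out_dir=args.out, seed=args.seed))
    table = pd.read_csv(paths["protocol_table"])
    draw = pd.read_csv(paths["order_of_draw"])

    print("\nPer-protocol levels and whole-procedure CVs:")
    print(table.round(3).to_string(index=False))
    sig = table[table["p_value"] < 0.05]
    print(f"\nprotocol comparisons with p < 0.05: {len(sig)} of "
          f"{len(table) // 2}")
    print("\nOrder of draw (first 10 vs last 10 tubes):")
    print(draw.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
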