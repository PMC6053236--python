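#!/usr/bin/env python
"""Cross-material and cross-method agreement on the patient cohort.

Runs experiments 2-3: Spearman correlation of PPP vs standard plasma
(single TaqMan assays) and of single assays vs TLDA, per assay and
normalization strategy. Under the study preset, platelet contamination
in standard plasma degrades the spike-normalized agreement most, and
TLDA pre-amplification noise removes the single-vs-TLDA correlation.
"""

import argparse
from pathlib import Path

import pandas as pd

from mirvar.pipeline import RunManifest, run_experiments_2_3


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    paths = run_experiments_2_3(RunManifest(out_dir=args.out, seed=args.seed))
    materials = pd.read_csv(paths["ppp_vs_standard"])
    tlda = pd.read_csv(paths["single_vs_tlda"])

    print("\nPPP vs standard plasma (Spearman rho):")
    print(materials.round(3).to_string(index=False))
    print("\nSingle TaqMan assays vs TLDA (Spearman rho):")
    print(tlda.round(3).to_string(index=False))
    print(f"\nmax |rho| single-vs-TLDA: {tlda['rho'].abs().max():.2f} "
          "(pre-amplification noise dominates)")


if __name__ == "__main__":
    main()
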