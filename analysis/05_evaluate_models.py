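"""Evaluate all six models and compare the two ensembles.

Ten-fold random cross-validation of the four base learners and both
ensembles (continuous Boyce index, AUC, TSS on the held-out folds, with
one shared fold assignment so comparisons are paired); exact two-sided
Wilcoxon signed-rank tests between the ensembles; binarization of the
ensemble maps at the 10% omission threshold; and suitable-range
summaries (spherical area, southernmost latitude, % of suitable area
inside the expert polygon).
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from rangestack.pipeline import RunConfig, stage_compare, stage_evaluate


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/run")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args(argv)
    cfg = RunConfig(out_dir=args.out, seed=args.seed)
    out = Path(args.out)
    stage_evaluate(cfg, out)
    stage_compare(cfg, out)
    print("cross-validation (mean ± sd):")
    print(pd.read_csv(out / "evaluate" / "cv_summary.csv")[["model", "boyce", "auc", "tss"]].to_string(index=False))
    print("\npaired Wilcoxon, occurrence-only vs expert-informed:")
    print(pd.read_csv(out / "evaluate" / "ensemble_comparison.csv").to_string(index=False))
    print("\nbinary range summaries (10% omission threshold):")
    print(pd.read_csv(out / "evaluate" / "range_summaries.csv").to_string(index=False))
    return 0


if __name__ == "__main__":
    sys.exit(main())
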