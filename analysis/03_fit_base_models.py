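"""Fit the four presence-background base learners and map their predictions.

GLM (AIC-selected quadratic polynomial), GAM (basis-dimension-3 smooths,
GCV penalty), MaxEnt-style penalized regression (cloglog output) and a
down-sampled random forest are fitted on the shared training table; with
--tune, MaxEnt and RF hyperparameters are grid-searched and the winner
chosen by the best-OR10-decile / max-validation-AUC rule.  Each model's
per-cell suitability map is written as an ASCII grid.
"""

import argparse
import json
import sys
from pathlib import Path

from rangestack.pipeline import RunConfig, stage_fit


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/run")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--tune", action="store_true", help="grid-tune MaxEnt and RF (slower)")
    args = ap.parse_args(argv)
    cfg = RunConfig(out_dir=args.out, seed=args.seed, tune=args.tune)
    stage_fit(cfg, Path(args.out))
    hyper = json.loads((Path(args.out) / "fit" / "hyperparams.json").read_text())
    for algo, hp in hyper.items():
        print(f"{algo}: {hp}")
    print(f"suitability maps written under {args.out}/fit")
    return 0


if __name__ == "__main__":
    sys.exit(main())
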