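"""Stack the base predictions into the two logistic meta-learner ensembles.

Builds the out-of-fold meta-training table, computes the distance-to-
expert-range layer (km, 0 inside the polygon), and fits the occurrence-
only (four base predictions) and expert-informed (plus distance)
ensembles.  Prints the meta-learner coefficient table; a negative,
significant distance coefficient means the ensemble has learned to
discount habitat far outside the expert range.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from rangestack.pipeline import RunConfig, stage_stack


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/run")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args(argv)
    cfg = RunConfig(out_dir=args.out, seed=args.seed)
    stage_stack(cfg, Path(args.out))
    coefs = pd.read_csv(Path(args.out) / "stack" / "meta_coefficients.csv")
    print(coefs.to_string(index=False, float_format=lambda v: f"{v: .4f}"))
    return 0


if __name__ == "__main__":
    sys.exit(main())
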