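"""Prepare the modelling inputs: clean/thin occurrences, delineate the
calibration area, draw background points, screen collinear predictors.

Occurrences are thinned to one per grid cell; the calibration area is a
1000-km great-circle buffer around the presences; 10,000 background
(pseudo-absence) points are drawn uniformly within it; predictors with
pairwise |Pearson r| > 0.7 over the calibration cells are reduced to a
non-collinear set.
"""

import argparse
import json
import sys
from pathlib import Path

import pandas as pd

from rangestack.pipeline import RunConfig, stage_prep


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/run")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args(argv)
    cfg = RunConfig(out_dir=args.out, seed=args.seed)
    stage_prep(cfg, Path(args.out))

    out = Path(args.out)
    pres = pd.read_csv(out / "prep" / "presences_thinned.csv")
    bg = pd.read_csv(out / "prep" / "background.csv")
    retained = json.loads((out / "prep" / "retained_predictors.json").read_text())["retained"]
    print(f"presences after cleaning/thinning: {len(pres)}")
    print(f"background points: {len(bg)}")
    print(f"retained predictors after collinearity screen: {retained}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
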