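"""Shared fixtures: a small virtual species and its fitted pipeline.

The small configuration (60x60 grid, 100 presences, 1000 background
points, 200-tree forests) keeps fits fast while preserving the barrier
geometry; the full-scale configuration is used only by the acceptance
experiment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from rangestack.models import build_training_table
from rangestack.pipeline import RunConfig, run_experiment
from rangestack.prep import PrepConfig, build_calibration_area, clean_and_thin, sample_background
from rangestack.simulate import VirtualSpeciesConfig, simulate

warnings.filterwarnings("ignore", category=FutureWarning)


def small_species(**overrides) -> VirtualSpeciesConfig:
    base = dict(lon_max=121.0, lat_max=26.0, resolution=0.1, n_presence=100, seed=11)
    base.update(overrides)
    return VirtualSpeciesConfig(**base)


def small_run_config(**overrides) -> RunConfig:
    base = dict(
        species=small_species(),
        prep=PrepConfig(thin_resolution=0.1, n_background=1000),
        rf_n_trees=200,
    )
    base.update(overrides)
    return RunConfig(**base)


@pytest.fixture(scope="session")
def bundle():
    return simulate(small_species())


@pytest.fixture(scope="session")
def prep_cfg():
    return PrepConfig(thin_resolution=0.1, n_background=1000, seed=11)


@pytest.fixture(scope="session")
def prepared(bundle, prep_cfg):
    pres = clean_and_thin(bundle.presences, bundle.env, prep_cfg)
    area = build_calibration_area(pres, bundle.env, prep_cfg)
    bg = sample_background(area, prep_cfg)
    return pres, bg, area


@pytest.fixture(scope="session")
def train_table(bundle, prepared):
    pres, bg, _ = prepared
    return build_training_table(pres, bg, bundle.env, k=10, seed=11)


@pytest.fixture(scope="session")
def small_experiment():
    """One full stacked-ensemble run on the small barrier landscape."""
    return run_experiment(11, small_run_config())


@pytest.fixture(scope="session")
def run_all_twice(tmp_path_factory):
    """The scaled-down end-to-end workflow executed twice with one seed."""
    import dataclasses

    from rangestack.pipeline import run_all

    dirs = []
    for name in ("run_a", "run_b"):
        out = tmp_path_factory.mktemp("pipeline") / name
        cfg = dataclasses.replace(small_run_config(), out_dir=str(out), seed=11)
        run_all(cfg)
        dirs.append(out)
    return dirs


def logistic_table(n: int = 2000, p: int = 2, slope: float = 2.0, seed: int = 0, k: int = 10):
    """Training table whose label is Bernoulli(logistic(slope * x1));
    remaining predictors are pure noise."""
    import pandas as pd
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = (rng.random(n) < expit(slope * X[:, 0])).astype(int)
    df = pd.DataFrame(X, columns=[f"x{i + 1}" for i in range(p)])
    df["label"] = y
    df["fold"] = rng.permutation(np.tile(np.arange(1, k + 1), n // k + 1)[:n])
    return df
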