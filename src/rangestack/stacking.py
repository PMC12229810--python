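"""Stacked generalization: the two-tier ensembles.

Four base learners produce per-point suitability predictions which,
stacked column-wise, form the training inputs of a logistic-regression
meta-learner.  Two ensemble variants are built: *occurrence-only* (four
base predictions) and *expert-informed* (four base predictions plus the
per-point distance to the expert range polygon).  The default stacking
mode is out-of-fold: each point's base predictions come from models
refitted without that point's fold, which keeps the meta-learner free of
training leakage; in-sample stacking is available for comparison and the
mode is recorded on the fit.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Any

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .grid import Raster
from .models import LABEL_COLS, ModelCandidate, fit_algorithm

__all__ = ["ALGORITHMS", "MetaLearnerFit", "build_meta_table", "fit_meta", "predict_ensemble"]

ALGORITHMS = ("GLM", "GAM", "MAXENT", "RF")
META_COLS = {"GLM": "glm", "GAM": "gam", "MAXENT": "maxent", "RF": "rf"}
DIST_COL = "distance_km"


def build_meta_table(
    base_models: dict[str, ModelCandidate],
    train: pd.DataFrame,
    dist: Raster | None = None,
    mode: str = "out_of_fold",
    point_coords: pd.DataFrame | None = None,
    dist_values: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-point base-model predictions (+ optional distance) and labels.

    ``mode='out_of_fold'`` refits each algorithm once per fold on the
    other folds and predicts the held-out rows; ``mode='in_sample'``
    predicts every row from the supplied full-data fits.  The distance
    column is appended iff a distance layer (with ``point_coords``
    holding lon/lat per row) or a precomputed ``dist_values`` vector is
    given.
    """
    if set(base_models) != set(ALGORITHMS):
        raise ValueError(f"need exactly the four base algorithms {ALGORITHMS}")
    if mode not in ("out_of_fold", "in_sample"):
        raise ValueError(f"unknown stacking mode {mode!r}")
    X = train[[c for c in train.columns if c not in LABEL_COLS]]
    out = pd.DataFrame(index=train.index)
    for algo in ALGORITHMS:
        col = META_COLS[algo]
        if mode == "in_sample":
            out[col] = base_models[algo].predict(X)
        else:
            pred = np.full(len(train), np.nan)
            for f in sorted(train["fold"].unique()):
                hold = train["fold"].to_numpy() == f
                refit = fit_algorithm(algo, train[~hold], base_models[algo].hyperparams)
                pred[hold] = refit.predict(X[hold])
            assert np.isfinite(pred).all(), "out-of-fold bookkeeping left rows unpredicted"
            out[col] = pred
    if dist is not None or dist_values is not None:
        if dist_values is None:
            if point_coords is None:
                raise ValueError("point_coords required to sample the distance layer")
            dist_values = dist.sample(point_coords["lon"].to_numpy(), point_coords["lat"].to_numpy())
        out[DIST_COL] = np.asarray(dist_values, dtype=float)
        if out[DIST_COL].isna().any():
            raise ValueError("distance layer is nodata at some training points")
    out["label"] = train["label"].to_numpy()
    out["fold"] = train["fold"].to_numpy()
    return out


def _ridge_logistic(y: np.ndarray, X: np.ndarray, lam: float = 1e-4, maxiter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """IRLS logistic regression with a small ridge penalty lam*||beta||^2.

    Returns (params, covariance); the covariance is the inverse penalized
    observed information X'WX + 2*lam*I.
    """
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        mu = expit(X @ beta)
        W = mu * (1.0 - mu)
        H = X.T @ (X * W[:, None]) + 2.0 * lam * np.eye(X.shape[1])
        g = X.T @ (y - mu) - 2.0 * lam * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    mu = expit(X @ beta)
    W = mu * (1.0 - mu)
    H = X.T @ (X * W[:, None]) + 2.0 * lam * np.eye(X.shape[1])
    return beta, np.linalg.inv(H)


@dataclasses.dataclass
class MetaLearnerFit:
    """Logistic meta-learner coefficients for one ensemble variant."""

    variant: str  # occurrence_only | expert_informed
    coefficients: pd.Series  # intercept + one per input column
    p_values: pd.Series
    fold_provenance: str  # out_of_fold | in_sample
    condition_number: float

    @property
    def input_columns(self) -> list[str]:
        return [c for c in self.coefficients.index if c != "intercept"]


def fit_meta(table: pd.DataFrame, fold_provenance: str = "out_of_fold") -> MetaLearnerFit:
    """Maximum-likelihood logistic regression of label on the stacked inputs.

    Reports Wald p-values.  A constant input column is rejected (for the
    distance column this means every point lies inside the expert
    polygon — use the occurrence-only variant instead).  Near-collinear
    inputs are flagged through the design condition number; separation
    falls back to a lightly penalized fit with a warning.
    """
    inputs = [c for c in table.columns if c not in LABEL_COLS]
    y = table["label"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both labels must be present to fit the meta-learner")
    for c in inputs:
        if table[c].std() == 0:
            if c == DIST_COL:
                raise ValueError(
                    "distance column is constant (all points inside the expert polygon); "
                    "fit the occurrence-only variant instead"
                )
            raise ValueError(f"constant meta input column {c!r}")
    X = sm.add_constant(table[inputs].to_numpy(), prepend=True)
    Z = table[inputs].to_numpy()
    Zs = (Z - Z.mean(axis=0)) / Z.std(axis=0)
    cond = float(np.linalg.cond(Zs))
    if cond > 1e6:
        warnings.warn(f"meta-learner inputs are near-collinear (condition number {cond:.3g})")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            ok = bool(res.converged) and np.all(np.isfinite(res.bse)) and np.max(np.abs(res.params)) < 1e4
        except Exception:
            ok = False
    if ok:
        params, pvals = np.asarray(res.params), np.asarray(res.pvalues)
    else:
        # separation or a collinear null direction: a light ridge pins the
        # estimate; Wald p-values come from the penalized information, so
        # unidentified directions get huge standard errors (insignificant)
        # while well-identified coefficients are essentially unchanged
        warnings.warn("meta-learner separation/non-convergence; using lightly ridge-penalized fit")
        params, cov = _ridge_logistic(y, X, lam=1e-4)
        se = np.sqrt(np.diag(cov))
        z = params / se
        pvals = 2.0 * stats.norm.sf(np.abs(z))
    names = ["intercept"] + inputs
    variant = "expert_informed" if DIST_COL in inputs else "occurrence_only"
    return MetaLearnerFit(
        variant=variant,
        coefficients=pd.Series(params, index=names),
        p_values=pd.Series(pvals, index=names),
        fold_provenance=fold_provenance,
        condition_number=cond,
    )


def predict_ensemble(
    fit: MetaLearnerFit,
    base_maps: dict[str, Raster],
    dist: Raster | None = None,
) -> Raster:
    """Per-cell ensemble suitability: inverse-logit of the meta linear
    predictor over the co-registered base maps (+ distance layer for the
    expert-informed variant)."""
    if fit.variant == "expert_informed" and dist is None:
        raise ValueError("expert-informed ensemble requires a distance layer")
    if fit.variant == "occurrence_only" and dist is not None:
        raise ValueError("occurrence-only ensemble takes no distance layer")
    if set(base_maps) != set(ALGORITHMS):
        raise ValueError(f"need one map per base algorithm {ALGORITHMS}")
    grid = next(iter(base_maps.values())).grid
    layers = {META_COLS[a]: base_maps[a] for a in ALGORITHMS}
    if dist is not None:
        layers[DIST_COL] = dist
    for r in layers.values():
        if r.grid != grid:
            raise ValueError("ensemble inputs are not co-registered")
    eta = np.full(grid.shape, float(fit.coefficients["intercept"]))
    valid = np.ones(grid.shape, dtype=bool)
    for col in fit.input_columns:
        vals = layers[col].values
        valid &= np.isfinite(vals)
        eta = eta + fit.coefficients[col] * np.nan_to_num(vals)
    out = np.where(valid, expit(eta), np.nan)
    return Raster(grid=grid, values=out, name=f"suitability_{fit.variant}")
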