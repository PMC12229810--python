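"""The four presence-background base learners and their tuning.

All four algorithms consume one shared :class:`TrainingTable` (a pandas
DataFrame with predictor columns, a 0/1 ``label`` and a 1..k ``fold``
assignment), so downstream fold-paired comparisons are valid.

* GLM — binomial regression with linear + quadratic terms, model chosen
  by AIC-guided backward elimination.
* GAM — additive binomial model, one spline smooth (basis dimension 3)
  per predictor, penalty weight picked by GCV on a small grid.
* MaxEnt — L1-penalized binomial regression on a feature expansion
  (linear / quadratic / hinge / product classes) with a regularization
  multiplier, cloglog-transformed to suitability; the standard
  presence-background reformulation of maximum-entropy modelling.
* RF — ensemble of classification trees with per-tree down-sampling of
  the background class to the presence count, handling the extreme
  class imbalance of presence-background data.

Candidate models carry 10-fold validation AUC and 10% omission rate
(OR10); selection keeps the best decile by OR10 and picks the highest
validation AUC within it.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Any, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logsumexp
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier
from statsmodels.gam.api import BSplines, GLMGam

from .grid import EnvStack, Raster
from .metrics import auc, omission_threshold
from .prep import CalibrationArea

__all__ = [
    "ModelCandidate",
    "build_training_table",
    "fit_glm",
    "fit_gam",
    "fit_maxent",
    "fit_rf",
    "fit_algorithm",
    "make_candidate",
    "tune_and_select",
    "tune_maxent",
    "tune_rf",
    "predict_map",
]

LABEL_COLS = ("label", "fold")


def predictor_names(train: pd.DataFrame) -> list[str]:
    return [c for c in train.columns if c not in LABEL_COLS]


def build_training_table(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    env: EnvStack,
    names: Sequence[str] | None = None,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Assemble the shared training table.

    Predictor values are read from the environment stack at each point's
    cell; presences get label 1, background 0; presences and background
    are each partitioned into ``k`` random folds (seeded) so that every
    fold contains both classes.
    """
    names = list(names) if names is not None else list(env.names)
    rng = np.random.default_rng(seed)
    parts = []
    for df, label in ((presences, 1), (background, 0)):
        X = env.table_at_points(df["lon"].to_numpy(), df["lat"].to_numpy())[names]
        X = X.copy()
        X["label"] = label
        fold = np.tile(np.arange(1, k + 1), len(df) // k + 1)[: len(df)]
        X["fold"] = rng.permutation(fold)
        parts.append(X)
    table = pd.concat(parts, ignore_index=True)
    if table[names].isna().any().any():
        raise ValueError("training table has missing predictor values (points off the env mask?)")
    for f in range(1, k + 1):
        sub = table[table["fold"] == f]
        if sub["label"].nunique() < 2:
            raise ValueError(f"fold {f} lacks one of the classes; use fewer folds")
    return table


@dataclasses.dataclass
class ModelCandidate:
    """A fitted base model plus its tuning bookkeeping."""

    algorithm: str  # GLM | GAM | MAXENT | RF
    hyperparams: dict[str, Any]
    fit_state: Any
    validation_auc: float = float("nan")
    validation_or10: float = float("nan")
    complexity: float = 0.0

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.fit_state.predict(X)


# ----------------------------------------------------------------- GLM


def _glm_design(X: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(X))]
    for t in terms:
        if t.endswith("^2"):
            cols.append(X[t[:-2]].to_numpy() ** 2)
        else:
            cols.append(X[t].to_numpy())
    return np.column_stack(cols)


class _GLMFit:
    def __init__(self, predictors: list[str], terms: list[str], params: np.ndarray, aic: float, converged: bool):
        self.predictors = predictors
        self.terms = terms
        self.params = params
        self.aic = aic
        self.converged = converged

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return expit(_glm_design(X, self.terms) @ self.params)


def _fit_binomial(y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Binomial-logit ML fit; on separation/non-convergence fall back to a
    lightly ridge-penalized fit (with a warning).  Returns (params, aic, ok)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=100)
            ok = bool(res.converged) and np.all(np.isfinite(res.params)) and np.max(np.abs(res.params)) < 1e3
        except Exception:
            ok = False
            res = None
    if ok:
        params = np.asarray(res.params)
    else:
        warnings.warn("binomial GLM did not converge cleanly (possible separation); using penalized fallback")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit_regularized(
                method="elastic_net", alpha=1e-4, L1_wt=0.0
            )
        params = np.asarray(res.params)
    mu = np.clip(expit(design @ params), 1e-12, 1 - 1e-12)
    loglik = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    aic = -2.0 * loglik + 2.0 * design.shape[1]
    return params, aic, ok


def fit_glm(train: pd.DataFrame, terms: Sequence[str] | None = None) -> ModelCandidate:
    """Binomial GLM with second-order polynomial terms.

    When ``terms`` is None, starts from all linear + quadratic terms and
    backward-eliminates whichever single removal lowers AIC most,
    stopping when no removal improves; the AIC-minimal model is kept.
    Passing ``terms`` refits that fixed term set (used for fold refits).
    """
    names = predictor_names(train)
    if len(names) < 1 and terms is None:
        raise ValueError("GLM term selection needs at least one predictor")
    y = train["label"].to_numpy(dtype=float)
    if terms is not None:
        terms = list(terms)
        params, aic, _ = _fit_binomial(y, _glm_design(train, terms))
        fit = _GLMFit(names, terms, params, aic, True)
        return ModelCandidate("GLM", {"terms": terms}, fit, complexity=len(terms))
    current = [t for n in names for t in (n, f"{n}^2")]
    params, aic, _ = _fit_binomial(y, _glm_design(train, current))
    while current:
        trials = []
        for t in current:
            reduced = [u for u in current if u != t]
            p_r, aic_r, _ = _fit_binomial(y, _glm_design(train, reduced))
            trials.append((aic_r, reduced, p_r))
        best_aic, best_terms, best_params = min(trials, key=lambda z: z[0])
        if best_aic < aic:
            aic, current, params = best_aic, best_terms, best_params
        else:
            break
    fit = _GLMFit(names, current, params, aic, True)
    return ModelCandidate("GLM", {"terms": list(current)}, fit, complexity=len(current))


# ----------------------------------------------------------------- GAM


class _GAMFit:
    def __init__(self, predictors, smooth_cols, bs, res, const_pred, xmin, xmax):
        self.predictors = predictors
        self.smooth_cols = smooth_cols
        self.bs = bs
        self.res = res
        self.const_pred = const_pred  # fallback constant when no usable smooth
        self.xmin = xmin
        self.xmax = xmax

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self.res is None:
            return np.full(len(X), self.const_pred)
        # constant extrapolation: spline bases are undefined beyond the
        # training range, so clip new data to it
        Xc = np.clip(X[self.smooth_cols].to_numpy(), self.xmin, self.xmax)
        design = np.column_stack([np.ones((len(X), 1)), self.bs.transform(Xc)])
        return np.asarray(expit(design @ self.res.params))


def _gam_gcv(res, n: int) -> float:
    edf = float(np.sum(res.edf)) if hasattr(res, "edf") else res.df_model + 1
    denom = max(n - edf, 1.0)
    return n * res.deviance / denom**2


def fit_gam(train: pd.DataFrame, alpha: float | Sequence[float] | None = None) -> ModelCandidate:
    """Additive binomial model, one basis-dimension-3 spline per predictor.

    The smoothing penalty weight is selected by generalized cross-
    validation over a log-spaced grid unless ``alpha`` is given (a scalar
    applied to all smooths, or one weight per smooth).  Predictors that
    are (near-)constant in the training data carry no information and are
    excluded from the smoother — their contribution is identically zero.
    """
    names = predictor_names(train)
    y = train["label"].to_numpy(dtype=float)
    smooth_cols = [n for n in names if train[n].std() > 1e-12]
    if not smooth_cols:
        p = y.mean()
        return ModelCandidate("GAM", {"alpha": 0.0}, _GAMFit(names, [], None, None, p, None, None), complexity=0)
    Xs = train[smooth_cols].to_numpy()
    bs = BSplines(Xs, df=[3] * len(smooth_cols), degree=[2] * len(smooth_cols), include_intercept=False)
    exog = np.ones((len(train), 1))

    def _fit(a):
        avec = np.full(len(smooth_cols), float(a)) if np.isscalar(a) else np.asarray(a, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = GLMGam(y, exog=exog, smoother=bs, alpha=avec, family=sm.families.Binomial())
            res = model.fit(maxiter=100)
        if not np.all(np.isfinite(res.params)):
            raise RuntimeError(f"GAM fit failed to converge (predictors {smooth_cols})")
        return res

    if alpha is not None:
        res = _fit(alpha)
        chosen = alpha if np.isscalar(alpha) else list(alpha)
    else:
        grid = [0.0, 1.0, 10.0, 100.0]
        fits = [(a, _fit(a)) for a in grid]
        chosen, res = min(fits, key=lambda ar: _gam_gcv(ar[1], len(train)))
    fit = _GAMFit(names, smooth_cols, bs, res, float(y.mean()), Xs.min(axis=0), Xs.max(axis=0))
    return ModelCandidate("GAM", {"alpha": chosen}, fit, complexity=float(np.sum(res.edf)))


# -------------------------------------------------------------- MaxEnt

#: per-class base penalty weights (linear/quadratic light, hinge heavy),
#: echoing conventional MaxEnt regularization defaults
_FC_BASE_PENALTY = {"L": 0.05, "Q": 0.05, "H": 0.5, "P": 0.1}
_N_HINGE_KNOTS = 10


class _MaxentFeatures:
    """Feature expansion over standardized predictors; affine-invariant
    because standardization happens before any feature is built."""

    def __init__(self, train_X: pd.DataFrame, fc: str):
        self.predictors = list(train_X.columns)
        self.fc = fc
        self.mu = train_X.mean().to_numpy()
        sd = train_X.std(ddof=0).to_numpy()
        self.sd = np.where(sd > 0, sd, 1.0)
        Z = (train_X.to_numpy() - self.mu) / self.sd
        self.zmin = Z.min(axis=0)
        self.zmax = Z.max(axis=0)
        qs = np.linspace(0, 1, _N_HINGE_KNOTS + 2)[1:-1]
        self.knots = np.quantile(Z, qs, axis=0)  # (n_knots, p)

    def build(self, X: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        Z = (X[self.predictors].to_numpy() - self.mu) / self.sd
        feats, names, classes = [], [], []
        p = Z.shape[1]
        if "L" in self.fc:
            for j in range(p):
                feats.append(Z[:, j]); names.append(f"L:{self.predictors[j]}"); classes.append("L")
        if "Q" in self.fc:
            for j in range(p):
                feats.append(Z[:, j] ** 2); names.append(f"Q:{self.predictors[j]}"); classes.append("Q")
        if "H" in self.fc:
            for j in range(p):
                span_f = self.zmax[j] - self.knots[:, j]
                span_r = self.knots[:, j] - self.zmin[j]
                for ki in range(self.knots.shape[0]):
                    if span_f[ki] > 0:
                        feats.append(np.clip((Z[:, j] - self.knots[ki, j]) / span_f[ki], 0, None))
                        names.append(f"H+:{self.predictors[j]}@{ki}"); classes.append("H")
                    if span_r[ki] > 0:
                        feats.append(np.clip((self.knots[ki, j] - Z[:, j]) / span_r[ki], 0, None))
                        names.append(f"H-:{self.predictors[j]}@{ki}"); classes.append("H")
        if "P" in self.fc:
            for i in range(p):
                for j in range(i + 1, p):
                    feats.append(Z[:, i] * Z[:, j])
                    names.append(f"P:{self.predictors[i]}*{self.predictors[j]}"); classes.append("P")
        self.classes = classes
        return np.column_stack(feats), names


class _MaxentFit:
    def __init__(self, features: _MaxentFeatures, beta: np.ndarray, feat_sd: np.ndarray, log_z: float, entropy: float):
        self.predictors = features.predictors
        self.features = features
        self.beta = beta
        self.feat_sd = feat_sd
        self.log_z = log_z
        self.entropy = entropy

    def eta(self, X: pd.DataFrame) -> np.ndarray:
        F, _ = self.features.build(X)
        return (F / self.feat_sd) @ self.beta

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        # cloglog output of the exponential model: 1 - exp(-exp(H) * raw)
        log_raw = self.eta(X) - self.log_z
        return np.clip(1.0 - np.exp(-np.exp(self.entropy + log_raw)), 0.0, 1.0)


def fit_maxent(train: pd.DataFrame, fc: str = "LQH", rm: float = 1.0) -> ModelCandidate:
    """MaxEnt as L1-penalized binomial regression with cloglog output.

    Feature classes ``fc`` are a subset of L (linear), Q (quadratic),
    H (hinge, 10 knots per predictor at sample quantiles, both
    orientations) and P (pairwise products).  The per-feature L1 penalty
    is ``rm`` times a class-specific base weight, scaled by the presence
    sample size (penalties weaken as presences accumulate).  Suitability
    is the complementary log-log transform of the exponential
    (Gibbs) model implied by the fitted coefficients, normalized over the
    training background.
    """
    if not fc or any(c not in "LQHP" for c in fc):
        raise ValueError(f"invalid feature classes {fc!r} (subset of 'LQHP' required)")
    if rm <= 0:
        raise ValueError("regularization multiplier must be positive")
    names = predictor_names(train)
    y = train["label"].to_numpy(dtype=int)
    m_presence = int(y.sum())
    features = _MaxentFeatures(train[names], fc)
    F, feat_names = features.build(train)
    feat_sd = F.std(axis=0, ddof=0)
    feat_sd = np.where(feat_sd > 0, feat_sd, 1.0)
    Fs = F / feat_sd
    # per-feature penalty, applied through column scaling so liblinear's
    # uniform L1 becomes sum_j lambda_j |beta_j|
    lam = np.array([rm * _FC_BASE_PENALTY[c] for c in features.classes]) * len(train) / math.sqrt(max(m_presence, 1))
    clf = LogisticRegression(
        l1_ratio=1, C=1.0, solver="liblinear", intercept_scaling=1000.0, tol=1e-10, max_iter=20000,
        random_state=0
    )
    clf.fit(Fs / lam, y)
    beta = clf.coef_.ravel() / lam  # coefficients on the sd-scaled features
    eta_bg = Fs[y == 0] @ beta
    log_z = float(logsumexp(eta_bg))
    log_raw_bg = eta_bg - log_z
    entropy = float(-np.sum(np.exp(log_raw_bg) * log_raw_bg))
    fit = _MaxentFit(features, beta, feat_sd, log_z, entropy)
    return ModelCandidate(
        "MAXENT", {"fc": fc, "rm": rm}, fit, complexity=len(fc) * 10 + 1.0 / rm
    )


# ------------------------------------------------------------------ RF


class _RFFit:
    def __init__(self, predictors: list[str], trees: list[DecisionTreeClassifier]):
        self.predictors = predictors
        self.trees = trees

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xv = X[self.predictors].to_numpy()
        acc = np.zeros(len(X))
        for t in self.trees:
            proba = t.predict_proba(Xv)
            acc += proba[:, list(t.classes_).index(1)] if 1 in t.classes_ else 0.0
        return acc / len(self.trees)


def fit_rf(
    train: pd.DataFrame,
    n_trees: int = 500,
    m_try: int | None = None,
    min_node_size: int = 10,
    seed: int = 0,
) -> ModelCandidate:
    """Down-sampled random forest for presence-background data.

    Each tree is trained on a bootstrap of the presences plus an
    equal-size random subsample of the background, so every tree sees a
    balanced class ratio; suitability is the mean leaf presence fraction
    across trees.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    names = predictor_names(train)
    if m_try is None:
        m_try = max(1, int(math.sqrt(len(names))))
    if m_try > len(names):
        raise ValueError(f"m_try={m_try} exceeds predictor count {len(names)}")
    y = train["label"].to_numpy(dtype=int)
    Xv = train[names].to_numpy()
    pres_idx = np.nonzero(y == 1)[0]
    bg_idx = np.nonzero(y == 0)[0]
    m = len(pres_idx)
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_trees):
        bp = rng.choice(pres_idx, size=m, replace=True)
        bb = rng.choice(bg_idx, size=m, replace=len(bg_idx) < m)
        assert len(bp) == len(bb), "down-sampling contract violated: unbalanced tree sample"
        idx = np.concatenate([bp, bb])
        tree = DecisionTreeClassifier(
            max_features=m_try,
            min_samples_leaf=min_node_size,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(Xv[idx], y[idx])
        trees.append(tree)
    fit = _RFFit(names, trees)
    return ModelCandidate(
        "RF",
        {"n_trees": n_trees, "m_try": m_try, "min_node_size": min_node_size, "seed": seed},
        fit,
        complexity=n_trees * m_try / max(min_node_size, 1),
    )


# ------------------------------------------------------- tuning plumbing


def fit_algorithm(algorithm: str, train: pd.DataFrame, hyperparams: dict[str, Any]) -> ModelCandidate:
    """Refit ``algorithm`` with fixed hyperparameters (used for fold refits)."""
    if algorithm == "GLM":
        return fit_glm(train, terms=hyperparams.get("terms"))
    if algorithm == "GAM":
        return fit_gam(train, alpha=hyperparams.get("alpha"))
    if algorithm == "MAXENT":
        return fit_maxent(train, fc=hyperparams["fc"], rm=hyperparams["rm"])
    if algorithm == "RF":
        return fit_rf(train, **hyperparams)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def crossval_scores(algorithm: str, hyperparams: dict[str, Any], train: pd.DataFrame) -> tuple[float, float]:
    """Mean validation (OR10, AUC) over the table's folds.

    Per fold: refit on the other folds; OR10 threshold is the 10th
    percentile of training-presence predictions, omission the fraction of
    validation presences strictly below it; AUC is presence vs background
    on the held-out fold.
    """
    folds = sorted(train["fold"].unique())
    or10s, aucs = [], []
    for f in folds:
        tr = train[train["fold"] != f]
        va = train[train["fold"] == f]
        cand = fit_algorithm(algorithm, tr, hyperparams)
        thr = omission_threshold(cand.predict(tr[tr["label"] == 1]), rate=0.10)
        va_pres = cand.predict(va[va["label"] == 1])
        va_bg = cand.predict(va[va["label"] == 0])
        or10s.append(float(np.mean(va_pres < thr)))
        aucs.append(auc(va_pres, va_bg))
    return float(np.mean(or10s)), float(np.mean(aucs))


def make_candidate(algorithm: str, train: pd.DataFrame, hyperparams: dict[str, Any] | None = None, with_cv: bool = True) -> ModelCandidate:
    """Full-data fit plus (optionally) fold-validation metrics."""
    cand = fit_algorithm(algorithm, train, hyperparams or {}) if hyperparams is not None else {
        "GLM": fit_glm, "GAM": fit_gam, "MAXENT": fit_maxent, "RF": fit_rf
    }[algorithm](train)
    if with_cv:
        cand.validation_or10, cand.validation_auc = crossval_scores(algorithm, cand.hyperparams, train)
    return cand


def tune_and_select(candidates: Sequence[ModelCandidate]) -> ModelCandidate:
    """Best-decile-by-OR10, then max validation AUC.

    Keeps the ceil(0.1 K) candidates with the lowest validation OR10 —
    candidates tied with the cutoff OR10 are all kept, so an all-tied
    field passes through unfiltered — and returns the highest-
    validation-AUC member of that set (ties toward simpler models, then
    input order).
    """
    if not candidates:
        raise ValueError("empty candidate list")
    k = math.ceil(0.1 * len(candidates))
    ranked = sorted(range(len(candidates)), key=lambda i: (candidates[i].validation_or10, candidates[i].complexity, i))
    cutoff = candidates[ranked[k - 1]].validation_or10
    kept = [i for i in ranked if candidates[i].validation_or10 <= cutoff]
    best = max(kept, key=lambda i: (candidates[i].validation_auc, -candidates[i].complexity, -i))
    return candidates[best]


def tune_maxent(
    train: pd.DataFrame,
    fc_grid: Sequence[str] = ("L", "LQ", "H", "LQH", "LQHP"),
    rm_grid: Sequence[float] = (0.5, 1.0, 2.0, 3.0, 4.0),
) -> tuple[ModelCandidate, pd.DataFrame]:
    """Grid-tune MaxEnt feature classes and regularization multiplier."""
    candidates = []
    for fc in fc_grid:
        for rm in rm_grid:
            hp = {"fc": fc, "rm": rm}
            or10, auc_v = crossval_scores("MAXENT", hp, train)
            cand = fit_maxent(train, fc=fc, rm=rm)
            cand.validation_or10, cand.validation_auc = or10, auc_v
            candidates.append(cand)
    return tune_and_select(candidates), _candidate_table(candidates)


def tune_rf(
    train: pd.DataFrame,
    n_trees_grid: Sequence[int] = (500, 1000),
    m_try_grid: Sequence[int] | None = None,
    min_node_grid: Sequence[int] = (1, 5, 10),
    seed: int = 0,
) -> tuple[ModelCandidate, pd.DataFrame]:
    """Grid-tune the down-sampled RF over its three key parameters."""
    p = len(predictor_names(train))
    if m_try_grid is None:
        m_try_grid = sorted({2, max(1, int(math.sqrt(p))), max(1, p - 1)})
    candidates = []
    for nt in n_trees_grid:
        for mt in m_try_grid:
            if mt > p:
                continue
            for mn in min_node_grid:
                hp = {"n_trees": nt, "m_try": mt, "min_node_size": mn, "seed": seed}
                or10, auc_v = crossval_scores("RF", hp, train)
                cand = fit_rf(train, **hp)
                cand.validation_or10, cand.validation_auc = or10, auc_v
                candidates.append(cand)
    return tune_and_select(candidates), _candidate_table(candidates)


def _candidate_table(candidates: Sequence[ModelCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "algorithm": [c.algorithm for c in candidates],
            "hyperparams": [repr(c.hyperparams) for c in candidates],
            "validation_or10": [c.validation_or10 for c in candidates],
            "validation_auc": [c.validation_auc for c in candidates],
        }
    )


def response_curve(
    model: ModelCandidate,
    train: pd.DataFrame,
    predictor: str,
    quantiles: np.ndarray | None = None,
    n_rows: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Partial-dependence response curve along one predictor.

    At each grid value (training-sample quantiles of the predictor,
    central 80% by default) the prediction is averaged over a subsample
    of training rows with the predictor forced to that value; averaging
    over rows smooths out tree-ensemble noise that a hold-others-at-mean
    profile would show.
    """
    quantiles = np.linspace(0.1, 0.9, 9) if quantiles is None else quantiles
    xs = np.quantile(train[predictor], quantiles)
    rng = np.random.default_rng(seed)
    rows = train.iloc[rng.choice(len(train), size=min(n_rows, len(train)), replace=False)]
    rows = rows[[c for c in train.columns if c not in LABEL_COLS]]
    curve = np.empty(len(xs))
    for i, v in enumerate(xs):
        X = rows.copy()
        X[predictor] = v
        curve[i] = float(np.mean(model.predict(X)))
    return xs, curve


def predict_map(model: ModelCandidate, env: EnvStack, area: CalibrationArea) -> Raster:
    """Per-cell suitability over the calibration area; nodata elsewhere."""
    missing = [n for n in model.fit_state.predictors if n not in env.names]
    if missing:
        raise ValueError(f"model predictors {missing} absent from the environment stack")
    rows, cols = np.nonzero(area.mask)
    X = env.table_at_cells(rows, cols)
    pred = np.clip(model.predict(X), 0.0, 1.0)
    values = np.full(env.grid.shape, np.nan)
    values[rows, cols] = pred
    return Raster(grid=env.grid, values=values, name=f"suitability_{model.algorithm.lower()}")
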