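"""Base-learner contracts: AIC selection, spline/hinge behaviour,
down-sampling, tuning rule, map prediction."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from conftest import logistic_table
from rangestack.models import (
    ModelCandidate,
    build_training_table,
    fit_gam,
    fit_glm,
    fit_maxent,
    fit_rf,
    predict_map,
    response_curve,
    tune_and_select,
)
from rangestack.prep import CalibrationArea


def aic_oracle(y, mu, k):
    """Independent -2 loglik + 2k computation."""
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    ll = np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
    return -2.0 * ll + 2.0 * k


def test_glm_aic_matches_independent_oracle():
    df = logistic_table(n=50, p=2, seed=3)
    cand = fit_glm(df, terms=["x1", "x2", "x2^2"])
    mu = cand.predict(df)
    expected = aic_oracle(df["label"].to_numpy(), mu, 4)  # 3 terms + intercept
    assert cand.fit_state.aic == pytest.approx(expected, abs=1e-6)


def test_glm_null_data_selects_near_empty_model():
    df = logistic_table(n=2000, p=2, slope=0.0, seed=1)
    cand = fit_glm(df)
    null = fit_glm(df, terms=[])
    assert cand.fit_state.aic <= null.fit_state.aic + 2.0


def test_glm_recovers_informative_term_with_sign():
    df = logistic_table(n=2000, p=2, slope=2.0, seed=2)
    cand = fit_glm(df)
    assert "x1" in cand.hyperparams["terms"]
    coef = dict(zip(cand.fit_state.terms, cand.fit_state.params[1:]))
    assert coef["x1"] > 0


def test_glm_intercept_only_predicts_prevalence():
    df = logistic_table(n=500, p=2, slope=0.0, seed=5)
    cand = fit_glm(df, terms=[])
    np.testing.assert_allclose(cand.predict(df), df["label"].mean(), atol=1e-9)


def test_gam_constant_predictor_contributes_nothing():
    df = logistic_table(n=800, p=2, slope=2.0, seed=6)
    df["x2"] = 1.7  # constant column
    cand = fit_gam(df)
    X2 = df.copy()
    X2["x2"] = -40.0
    np.testing.assert_allclose(cand.predict(df), cand.predict(X2), atol=1e-12)


def test_gam_predictions_bounded():
    df = logistic_table(n=800, p=2, seed=7)
    cand = fit_gam(df)
    p = cand.predict(df)
    assert np.all((p >= 0) & (p <= 1))


def presence_background_table(n_pres=100, n_bg=1900, slope=2.0, seed=8):
    """Realistic presence-background class balance (few percent presences)."""
    rng = np.random.default_rng(seed)
    Xb = rng.standard_normal((n_bg, 2))
    # presences oversampled where the truth is suitable
    Xp = rng.standard_normal((n_pres * 10, 2))
    keep = rng.random(len(Xp)) < expit(slope * Xp[:, 0])
    Xp = Xp[keep][:n_pres]
    df = pd.DataFrame(np.vstack([Xp, Xb]), columns=["x1", "x2"])
    df["label"] = [1] * len(Xp) + [0] * n_bg
    df["fold"] = 1
    return df


def test_maxent_heavy_regularization_flattens_prediction():
    df = presence_background_table()
    cand = fit_maxent(df, fc="LQ", rm=100.0)
    p = cand.predict(df)
    assert np.ptp(p) < 1e-9
    assert np.all(np.abs(cand.fit_state.beta) < 1e-12)


def test_maxent_linear_recovers_sign():
    df = logistic_table(n=2000, p=2, slope=2.0, seed=9)
    cand = fit_maxent(df, fc="L", rm=1.0)
    grid = pd.DataFrame({"x1": np.linspace(-2, 2, 9), "x2": 0.0})
    p = cand.predict(grid)
    assert np.all(np.diff(p) > 0)


def test_maxent_affine_invariance():
    df = logistic_table(n=1500, p=2, seed=10)
    cand = fit_maxent(df, fc="LQ", rm=1.0)
    df2 = df.copy()
    df2["x1"] = 3.0 * df["x1"] + 7.0
    cand2 = fit_maxent(df2, fc="LQ", rm=1.0)
    newX = logistic_table(n=200, p=2, seed=11)
    newX2 = newX.copy()
    newX2["x1"] = 3.0 * newX["x1"] + 7.0
    np.testing.assert_allclose(cand.predict(newX), cand2.predict(newX2), atol=1e-6)


def test_maxent_invalid_inputs_rejected():
    df = logistic_table(n=100, p=2)
    with pytest.raises(ValueError):
        fit_maxent(df, fc="", rm=1.0)
    with pytest.raises(ValueError):
        fit_maxent(df, fc="LZ", rm=1.0)
    with pytest.raises(ValueError):
        fit_maxent(df, fc="L", rm=0.0)


def test_rf_degenerate_single_tree_predicts_half():
    df = logistic_table(n=200, p=2, seed=12)
    cand = fit_rf(df, n_trees=1, min_node_size=10_000)
    np.testing.assert_allclose(cand.predict(df), 0.5, atol=1e-12)


def test_rf_separable_problem_high_auc():
    from rangestack.metrics import auc

    rng = np.random.default_rng(13)
    X = rng.standard_normal((1500, 2))
    df = pd.DataFrame(X, columns=["x1", "x2"])
    df["label"] = (X[:, 0] > 0).astype(int)
    df["fold"] = 1
    train, hold = df.iloc[:1000], df.iloc[1000:]
    cand = fit_rf(train, n_trees=500, seed=13)
    p = cand.predict(hold)
    assert auc(p[hold["label"] == 1], p[hold["label"] == 0]) > 0.95


def test_rf_mtry_validation():
    df = logistic_table(n=100, p=2)
    with pytest.raises(ValueError, match="m_try"):
        fit_rf(df, n_trees=10, m_try=5)


def _dummy(or10, auc_v, complexity=0.0):
    return ModelCandidate("RF", {}, None, validation_auc=auc_v, validation_or10=or10, complexity=complexity)


def test_tune_and_select_rule():
    # singleton
    only = _dummy(0.5, 0.5)
    assert tune_and_select([only]) is only
    # K=20 hand-enumerated: ceil(2) lowest-OR10 kept, max AUC among them
    rng = np.random.default_rng(14)
    cands = [_dummy(round(o, 3), round(a, 3)) for o, a in rng.random((20, 2))]
    chosen = tune_and_select(cands)
    by_or10 = sorted(cands, key=lambda c: c.validation_or10)[:2]
    expected = max(by_or10, key=lambda c: c.validation_auc)
    assert chosen is expected
    # all-equal OR10 -> global max AUC
    flat = [_dummy(0.1, a) for a in (0.3, 0.9, 0.6)]
    assert tune_and_select(flat) is flat[1]
    with pytest.raises(ValueError):
        tune_and_select([])


def test_tuning_grids_produce_scored_candidates():
    from rangestack.models import tune_maxent, tune_rf

    df = logistic_table(n=600, p=2, slope=2.0, seed=40, k=3)
    best_mx, table_mx = tune_maxent(df, fc_grid=("L", "LQ"), rm_grid=(1.0, 2.0))
    assert len(table_mx) == 4
    assert table_mx["validation_or10"].between(0, 1).all()
    assert table_mx["validation_auc"].between(0, 1).all()
    assert best_mx.hyperparams["fc"] in ("L", "LQ")
    best_rf, table_rf = tune_rf(df, n_trees_grid=(50,), m_try_grid=(1, 2), min_node_grid=(5,), seed=40)
    assert len(table_rf) == 2
    assert best_rf.hyperparams["n_trees"] == 50


def test_all_learners_monotone_on_monotone_truth():
    """All four response curves rise over the central 80% of the predictor."""
    df = logistic_table(n=3000, p=2, slope=2.0, seed=15)
    fits = {
        "glm": fit_glm(df),
        "gam": fit_gam(df),
        "maxent": fit_maxent(df, fc="LQH", rm=1.0),
        "rf": fit_rf(df, n_trees=500, min_node_size=100, seed=15),
    }
    for name, cand in fits.items():
        _, p = response_curve(cand, df, "x1", n_rows=500)
        assert np.all(np.diff(p) > -1e-6), f"{name} response not monotone: {p}"
        assert p[-1] > p[0] + 0.1, f"{name} response flat"


def test_predict_map_consistency(bundle, prepared, train_table):
    pres, _, area = prepared
    cand = fit_glm(train_table, terms=["env1", "env1^2"])
    smap = predict_map(cand, bundle.env, area)
    vals = smap.values[area.mask]
    assert np.all((vals >= 0) & (vals <= 1))
    # map value at a presence cell equals prediction on that table row
    row, col = bundle.env.grid.cell_of(pres["lon"].iloc[0], pres["lat"].iloc[0])
    expected = cand.predict(train_table.iloc[[0]])[0]
    assert smap.values[row, col] == pytest.approx(expected, abs=1e-9)
    # intercept-only model -> constant map
    flat = fit_glm(train_table, terms=[])
    fvals = predict_map(flat, bundle.env, area).values[area.mask]
    assert np.ptp(fvals) < 1e-12


def test_predict_map_name_mismatch_rejected(bundle, prepared):
    _, _, area = prepared
    df = logistic_table(n=300, p=2)
    cand = fit_glm(df, terms=["x1"])
    with pytest.raises(ValueError, match="absent"):
        predict_map(cand, bundle.env, area)


def test_training_table_folds_partition(train_table):
    assert set(train_table["fold"].unique()) == set(range(1, 11))
    counts = train_table.groupby("fold")["label"].agg(["sum", "count"])
    assert (counts["sum"] > 0).all() and (counts["count"] > counts["sum"]).all()
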