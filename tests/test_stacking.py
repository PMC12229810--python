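"""Stacked-generalization contracts: meta-table building, meta-learner
fit, ensemble prediction, and the expert-range integration properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import rangestack.stacking as stk
from conftest import logistic_table
from rangestack.grid import Raster, RasterGrid
from rangestack.models import fit_gam, fit_glm, fit_maxent, fit_rf
from rangestack.stacking import MetaLearnerFit, build_meta_table, fit_meta, predict_ensemble


@pytest.fixture(scope="module")
def base_models(train_small):
    return {
        "GLM": fit_glm(train_small),
        "GAM": fit_gam(train_small),
        "MAXENT": fit_maxent(train_small, fc="LQ", rm=1.0),
        "RF": fit_rf(train_small, n_trees=100, seed=1),
    }


@pytest.fixture(scope="module")
def train_small():
    return logistic_table(n=600, p=2, slope=2.0, seed=21, k=5)


def test_in_sample_constant_base_model_gives_constant_column(train_small, base_models):
    models = dict(base_models)
    models["GLM"] = fit_glm(train_small, terms=[])  # intercept-only
    table = build_meta_table(models, train_small, mode="in_sample")
    assert table["glm"].std() < 1e-15


def test_no_distance_column_without_layer(train_small, base_models):
    table = build_meta_table(base_models, train_small, mode="in_sample")
    assert [c for c in table.columns if c != "fold"] == ["glm", "gam", "maxent", "rf", "label"]


def test_out_of_fold_refit_bookkeeping(train_small, base_models, monkeypatch):
    """One refit per fold per algorithm; held-out rows predicted only by
    models that never saw them."""
    calls = []
    real = stk.fit_algorithm

    def counting(algorithm, train, hyperparams):
        calls.append((algorithm, len(train)))
        return real(algorithm, train, hyperparams)

    monkeypatch.setattr(stk, "fit_algorithm", counting)
    table = build_meta_table(base_models, train_small, mode="out_of_fold")
    n_folds = train_small["fold"].nunique()
    per_algo = pd.Series([a for a, _ in calls]).value_counts()
    assert (per_algo == n_folds).all() and len(per_algo) == 4
    # every refit saw strictly fewer rows than the table
    assert all(n < len(train_small) for _, n in calls)
    assert table[["glm", "gam", "maxent", "rf"]].notna().all().all()
    in_sample = build_meta_table(base_models, train_small, mode="in_sample")
    assert not np.allclose(table["rf"], in_sample["rf"])


def test_fit_meta_recovers_informative_column():
    rng = np.random.default_rng(30)
    n = 5000
    z = rng.standard_normal(n)
    informative = expit(3.0 * z)
    table = pd.DataFrame(
        {
            "glm": informative,
            "gam": rng.random(n),
            "maxent": rng.random(n),
            "rf": rng.random(n),
            "label": (rng.random(n) < informative).astype(int),
            "fold": 1,
        }
    )
    fit = fit_meta(table)
    assert fit.variant == "occurrence_only"
    assert fit.p_values["glm"] < 0.01
    assert (fit.p_values[["gam", "maxent", "rf"]] > 0.05).all()


def test_fit_meta_flags_collinearity_predictions_stable():
    rng = np.random.default_rng(31)
    n = 3000
    z = expit(2.0 * rng.standard_normal(n))
    table = pd.DataFrame(
        {
            "glm": z,
            "gam": z + 1e-9 * rng.standard_normal(n),  # near-duplicate column
            "maxent": rng.random(n),
            "rf": rng.random(n),
            "label": (rng.random(n) < z).astype(int),
            "fold": 1,
        }
    )
    clean = table.drop(columns=["gam"])
    with pytest.warns(UserWarning, match="collinear"):
        fit = fit_meta(table)
    fit_clean = fit_meta(clean)
    X = np.column_stack([np.ones(n), table[fit.input_columns].to_numpy()])
    Xc = np.column_stack([np.ones(n), clean[fit_clean.input_columns].to_numpy()])
    p1 = expit(X @ fit.coefficients.to_numpy())
    p2 = expit(Xc @ fit_clean.coefficients.to_numpy())
    np.testing.assert_allclose(p1, p2, atol=1e-4)


def test_fit_meta_rejects_degenerate_inputs():
    base = pd.DataFrame({"glm": [0.2, 0.8], "gam": [0.3, 0.6], "maxent": [0.1, 0.9], "rf": [0.4, 0.5]})
    t1 = base.assign(label=[1, 1], fold=1)
    with pytest.raises(ValueError, match="both labels"):
        fit_meta(t1)
    t2 = base.assign(distance_km=[0.0, 0.0], label=[1, 0], fold=1)
    with pytest.raises(ValueError, match="occurrence-only"):
        fit_meta(t2)
    t3 = base.assign(glm=[0.5, 0.5], label=[1, 0], fold=1)
    with pytest.raises(ValueError, match="constant"):
        fit_meta(t3)


def _const_fit(variant, **coefs):
    cols = ["glm", "gam", "maxent", "rf"] + (["distance_km"] if variant == "expert_informed" else [])
    c = pd.Series({"intercept": coefs.get("intercept", 0.0), **{k: coefs.get(k, 0.0) for k in cols}})
    return MetaLearnerFit(variant=variant, coefficients=c, p_values=c * np.nan, fold_provenance="in_sample", condition_number=1.0)


def _maps(grid, values_by_name):
    return {a: Raster(grid, np.full(grid.shape, values_by_name[a])) for a in ("GLM", "GAM", "MAXENT", "RF")}


def test_predict_ensemble_intercept_only_constant():
    grid = RasterGrid(west=0, south=0, resolution=1.0, nrows=3, ncols=3)
    maps = _maps(grid, {"GLM": 0.2, "GAM": 0.4, "MAXENT": 0.6, "RF": 0.8})
    fit = _const_fit("occurrence_only", intercept=-1.3)
    out = predict_ensemble(fit, maps)
    np.testing.assert_allclose(out.values, expit(-1.3), atol=1e-12)


def test_predict_ensemble_distance_monotonicity_and_reduction():
    grid = RasterGrid(west=0, south=0, resolution=1.0, nrows=1, ncols=2)
    maps = {a: Raster(grid, np.array([[0.5, 0.5]])) for a in ("GLM", "GAM", "MAXENT", "RF")}
    dist = Raster(grid, np.array([[0.0, 200.0]]))
    fit = _const_fit("expert_informed", intercept=0.5, rf=2.0, distance_km=-0.01)
    out = predict_ensemble(fit, maps, dist=dist)
    assert out.values[0, 1] < out.values[0, 0]  # farther outside -> lower suitability
    # reduction: zero distance coefficient reproduces the occurrence-only map
    fit0 = _const_fit("expert_informed", intercept=0.5, rf=2.0, distance_km=0.0)
    occ = _const_fit("occurrence_only", intercept=0.5, rf=2.0)
    np.testing.assert_allclose(
        predict_ensemble(fit0, maps, dist=dist).values, predict_ensemble(occ, maps).values, atol=1e-12
    )


def test_predict_ensemble_variant_mismatch():
    grid = RasterGrid(west=0, south=0, resolution=1.0, nrows=1, ncols=2)
    maps = {a: Raster(grid, np.array([[0.5, 0.5]])) for a in ("GLM", "GAM", "MAXENT", "RF")}
    dist = Raster(grid, np.array([[0.0, 1.0]]))
    with pytest.raises(ValueError):
        predict_ensemble(_const_fit("expert_informed"), maps)
    with pytest.raises(ValueError):
        predict_ensemble(_const_fit("occurrence_only"), maps, dist=dist)


def test_distance_coefficient_negative_on_barrier_simulation(small_experiment):
    fit = small_experiment.meta_expert
    assert fit.coefficients["distance_km"] < 0
    assert fit.p_values["distance_km"] < 0.05


def test_variants_agree_more_inside_expert_polygon(small_experiment):
    """Inside the polygon (distance 0) the two ensembles are a monotone
    transform apart, so their rank agreement is higher inside than out."""
    occ = small_experiment.maps["ensemble_occurrence_only"]
    exp = small_experiment.maps["ensemble_expert_informed"]
    valid = np.isfinite(occ.values) & np.isfinite(exp.values)
    rows, cols = np.nonzero(valid)
    inside = small_experiment.maps["distance_km"].values[rows, cols] == 0.0
    rho_in = stats.spearmanr(occ.values[rows, cols][inside], exp.values[rows, cols][inside]).statistic
    rho_out = stats.spearmanr(occ.values[rows, cols][~inside], exp.values[rows, cols][~inside]).statistic
    assert rho_in > rho_out
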