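"""Pipeline orchestration: cross-validation, the barrier experiment, and
the staged run-all workflow with plain-text artifacts and a manifest.

The canonical experiment asks one question: does adding the
distance-to-expert-range predictor to a stacked ensemble suppress
overprediction beyond a dispersal barrier?  On the simulated species the
answer is checkable against truth — the barrier latitude is known, and
habitat south of it is suitable but unoccupied.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from . import __version__
from .expert import distance_to_range
from .grid import EnvStack, Raster, read_geojson, write_geojson
from .metrics import (
    BoyceConfig,
    auc,
    binarize,
    boyce_index,
    compare_models,
    omission_threshold,
    summarize_range,
    tss,
)
from .models import (
    LABEL_COLS,
    build_training_table,
    fit_algorithm,
    fit_gam,
    fit_glm,
    fit_maxent,
    fit_rf,
    predict_map,
    tune_maxent,
    tune_rf,
)
from .prep import CalibrationArea, PrepConfig, build_calibration_area, clean_and_thin, sample_background, screen_predictors
from .simulate import TruthBundle, VirtualSpeciesConfig, simulate, write_bundle
from .stacking import ALGORITHMS, DIST_COL, META_COLS, build_meta_table, fit_meta, predict_ensemble

__all__ = ["RunConfig", "crossvalidate", "run_experiment", "run_all", "ExperimentResult"]

ENSEMBLE_NAMES = ("ensemble_occurrence_only", "ensemble_expert_informed")
MODEL_ORDER = tuple(META_COLS[a] for a in ALGORITHMS) + ENSEMBLE_NAMES


@dataclasses.dataclass
class RunConfig:
    """One run of the full workflow: inputs, knobs, output directory.

    When ``occurrences_csv`` is unset the virtual species defined by
    ``species`` is simulated and used as input; otherwise occurrences,
    an environment-layer directory and an expert-range GeoJSON are read
    from the given paths.
    """

    out_dir: str = "results/run"
    seed: int = 0
    occurrences_csv: str | None = None
    env_dir: str | None = None
    expert_geojson: str | None = None
    species: VirtualSpeciesConfig = dataclasses.field(default_factory=VirtualSpeciesConfig)
    prep: PrepConfig = dataclasses.field(default_factory=PrepConfig)
    boyce: BoyceConfig = dataclasses.field(default_factory=BoyceConfig)
    n_folds: int = 10
    stacking_mode: str = "out_of_fold"
    tune: bool = False
    rf_n_trees: int = 500
    rf_min_node: int = 10
    maxent_fc: str = "LQH"
    maxent_rm: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        species = VirtualSpeciesConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.pop("species", {}).items()})
        prep = PrepConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.pop("prep", {}).items()})
        boyce = BoyceConfig(**raw.pop("boyce", {}))
        return cls(species=species, prep=prep, boyce=boyce, **raw)

    def to_manifest(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["package_version"] = __version__
        d["python"] = platform.python_version()
        d["assumptions"] = {
            "background_points_shared_across_algorithms": True,
            "or10_threshold_source": "training-presence predictions (10th percentile), omission on validation presences",
            "maxent_output": "cloglog",
            "distance_units": "km (great-circle, R=6371)",
            "stacking_mode": self.stacking_mode,
            "binarization": "suitable iff value >= threshold",
        }
        return d


# ------------------------------------------------------- cross-validation


def crossvalidate(
    train: pd.DataFrame,
    hyperparams: dict[str, dict],
    dist_values: np.ndarray | None = None,
    boyce_cfg: BoyceConfig | None = None,
    stacking_mode: str = "out_of_fold",
    with_ensembles: bool = True,
) -> pd.DataFrame:
    """k-fold cross-validation of the four base models and two ensembles.

    The fold assignment already stored on the training table is shared by
    every model, so per-fold metrics are paired.  For each fold, base
    models are refitted on the other folds with their tuned
    hyperparameters; ensembles are stacked within the training folds
    (out-of-fold by default, reusing the fold structure) and scored on
    the held-out fold.  Returns a long DataFrame (fold, model, boyce,
    auc, tss).
    """
    boyce_cfg = boyce_cfg or BoyceConfig()
    folds = sorted(train["fold"].unique())
    if train.groupby("fold")["label"].min().max() > 0 or (train.groupby("fold")["label"].sum() == 0).any():
        raise ValueError("every fold must contain presences and background")
    pred_cols = [c for c in train.columns if c not in LABEL_COLS]
    records = []
    for f in folds:
        tr = train[train["fold"] != f]
        va = train[train["fold"] == f]
        va_pres_mask = va["label"].to_numpy() == 1
        base = {a: fit_algorithm(a, tr, hyperparams[a]) for a in ALGORITHMS}
        va_pred = {META_COLS[a]: base[a].predict(va[pred_cols]) for a in ALGORITHMS}
        if with_ensembles:
            if dist_values is None:
                raise ValueError("distance values are required to evaluate the expert-informed ensemble")
            tr_dist = dist_values[tr.index.to_numpy()]
            va_dist = dist_values[va.index.to_numpy()]
            meta_occ = build_meta_table(base, tr, mode=stacking_mode)
            meta_exp = build_meta_table(base, tr, mode=stacking_mode, dist_values=tr_dist)
            fit_occ = fit_meta(meta_occ, fold_provenance=stacking_mode)
            fit_exp = fit_meta(meta_exp, fold_provenance=stacking_mode)
            base_mat = np.column_stack([va_pred[META_COLS[a]] for a in ALGORITHMS])
            eta_occ = fit_occ.coefficients["intercept"] + base_mat @ fit_occ.coefficients[[META_COLS[a] for a in ALGORITHMS]].to_numpy()
            eta_exp = (
                fit_exp.coefficients["intercept"]
                + base_mat @ fit_exp.coefficients[[META_COLS[a] for a in ALGORITHMS]].to_numpy()
                + fit_exp.coefficients[DIST_COL] * va_dist
            )
            va_pred[ENSEMBLE_NAMES[0]] = expit(eta_occ)
            va_pred[ENSEMBLE_NAMES[1]] = expit(eta_exp)
        for model, pred in va_pred.items():
            pres, bg = pred[va_pres_mask], pred[~va_pres_mask]
            records.append(
                {
                    "fold": f,
                    "model": model,
                    "boyce": boyce_index(pres, bg, boyce_cfg),
                    "auc": auc(pres, bg),
                    "tss": tss(pres, bg),
                }
            )
    return pd.DataFrame.from_records(records)


def format_mean_sd(values) -> str:
    """The conventional 'mean ± sd' metric report, e.g. '0.781 ± 0.177'."""
    v = np.asarray(values, dtype=float)
    return f"{v.mean():.3f} ± {v.std(ddof=1):.3f}"


def summarize_cv(cv: pd.DataFrame) -> pd.DataFrame:
    """Per-model mean ± sd summary of the cross-validation metric table."""
    rows = []
    for model in [m for m in MODEL_ORDER if m in set(cv["model"])]:
        sub = cv[cv["model"] == model]
        row = {"model": model}
        for metric in ("boyce", "auc", "tss"):
            row[f"{metric}_mean"] = sub[metric].mean()
            row[f"{metric}_sd"] = sub[metric].std(ddof=1)
            row[metric] = format_mean_sd(sub[metric])
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------ barrier experiment


@dataclasses.dataclass
class ExperimentResult:
    """Outputs of one barrier-experiment run (one simulated species)."""

    seed: int
    meta_occurrence: Any
    meta_expert: Any
    maps: dict[str, Raster]
    thresholds: dict[str, float]
    summary: pd.DataFrame  # per ensemble: total + south-of-barrier range summaries
    barrier_lat: float

    def headline(self) -> dict[str, float]:
        s = self.summary.set_index("model")
        occ, exp = ENSEMBLE_NAMES
        return {
            "south_area_occurrence_km2": float(s.loc[occ, "south_area_km2"]),
            "south_area_expert_km2": float(s.loc[exp, "south_area_km2"]),
            "southernmost_lat_occurrence": float(s.loc[occ, "southernmost_lat"]),
            "southernmost_lat_expert": float(s.loc[exp, "southernmost_lat"]),
            "pct_within_expert_occurrence": float(s.loc[occ, "pct_within_expert"]),
            "pct_within_expert_expert": float(s.loc[exp, "pct_within_expert"]),
            "distance_coefficient": float(self.meta_expert.coefficients[DIST_COL]),
            "distance_p_value": float(self.meta_expert.p_values[DIST_COL]),
        }


def _fit_base_models(train: pd.DataFrame, cfg: RunConfig) -> tuple[dict, pd.DataFrame | None]:
    if cfg.tune:
        mx, tab_mx = tune_maxent(train)
        rf, tab_rf = tune_rf(train, seed=cfg.seed)
        tables = pd.concat([tab_mx, tab_rf], ignore_index=True)
        base = {"GLM": fit_glm(train), "GAM": fit_gam(train), "MAXENT": mx, "RF": rf}
        return base, tables
    base = {
        "GLM": fit_glm(train),
        "GAM": fit_gam(train),
        "MAXENT": fit_maxent(train, fc=cfg.maxent_fc, rm=cfg.maxent_rm),
        "RF": fit_rf(train, n_trees=cfg.rf_n_trees, min_node_size=cfg.rf_min_node, seed=cfg.seed),
    }
    return base, None


def run_experiment(seed: int, cfg: RunConfig | None = None) -> ExperimentResult:
    """Simulate one virtual species and run the two-ensemble comparison.

    Returns both ensembles' fits, continuous and binarized maps, and
    range summaries (total and south of the dispersal barrier).
    """
    cfg = cfg or RunConfig()
    cfg = dataclasses.replace(cfg, seed=seed, species=dataclasses.replace(cfg.species, seed=seed))
    prep_cfg = dataclasses.replace(cfg.prep, seed=seed)
    bundle = simulate(cfg.species)
    env = bundle.env

    presences = clean_and_thin(bundle.presences, env, prep_cfg)
    area = build_calibration_area(presences, env, prep_cfg)
    background = sample_background(area, prep_cfg)
    retained = screen_predictors(env, area, prep_cfg)
    env_r = env.subset(retained)
    train = build_training_table(presences, background, env_r, k=cfg.n_folds, seed=seed)

    base, _ = _fit_base_models(train, cfg)
    dist = distance_to_range(bundle.expert_polygon, env_r, area)
    coords = pd.concat([presences[["lon", "lat"]], background[["lon", "lat"]]], ignore_index=True)
    meta_occ = build_meta_table(base, train, mode=cfg.stacking_mode)
    meta_exp = build_meta_table(base, train, mode=cfg.stacking_mode, dist=dist, point_coords=coords)
    fit_occ = fit_meta(meta_occ, fold_provenance=cfg.stacking_mode)
    fit_exp = fit_meta(meta_exp, fold_provenance=cfg.stacking_mode)

    base_maps = {a: predict_map(base[a], env_r, area) for a in ALGORITHMS}
    map_occ = predict_ensemble(fit_occ, base_maps)
    map_exp = predict_ensemble(fit_exp, base_maps, dist=dist)
    maps = {META_COLS[a]: base_maps[a] for a in ALGORITHMS}
    maps[ENSEMBLE_NAMES[0]] = map_occ
    maps[ENSEMBLE_NAMES[1]] = map_exp
    maps["distance_km"] = dist

    # 10% omission threshold from training-presence ensemble predictions
    pres_pts = presences[["lon", "lat"]]
    thresholds = {
        ENSEMBLE_NAMES[0]: omission_threshold(map_occ.sample(pres_pts["lon"], pres_pts["lat"])),
        ENSEMBLE_NAMES[1]: omission_threshold(map_exp.sample(pres_pts["lon"], pres_pts["lat"])),
    }
    rows = []
    barrier = cfg.species.barrier_lat
    for name in ENSEMBLE_NAMES:
        bmap = binarize(maps[name], thresholds[name])
        total = summarize_range(bmap, bundle.expert_polygon)
        lat2d = env.grid.center_mesh()[1]
        south_vals = np.where(lat2d < barrier, bmap.raster.values, np.nan)
        south = summarize_range(dataclasses.replace(bmap, raster=Raster(env.grid, south_vals, bmap.raster.name)))
        rows.append(
            {
                "model": name,
                "threshold": thresholds[name],
                "area_km2": total.area_km2,
                "southernmost_lat": total.southernmost_lat,
                "pct_within_expert": total.pct_within_expert,
                "south_area_km2": south.area_km2,
            }
        )
    summary = pd.DataFrame(rows)
    return ExperimentResult(
        seed=seed,
        meta_occurrence=fit_occ,
        meta_expert=fit_exp,
        maps=maps,
        thresholds=thresholds,
        summary=summary,
        barrier_lat=barrier,
    )


# ----------------------------------------------------------- staged run-all


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path} (produced by the '{stage}' stage); run '{stage}' before '{needed_by}'"
        )
    return path


def stage_simulate(cfg: RunConfig, out: Path) -> TruthBundle:
    bundle = simulate(cfg.species)
    write_bundle(bundle, out / "fixtures")
    return bundle


def stage_prep(cfg: RunConfig, out: Path) -> None:
    fx = out / "fixtures"
    if cfg.occurrences_csv:
        occ = pd.read_csv(cfg.occurrences_csv)
        env = EnvStack.read_dir(cfg.env_dir)
    else:
        occ = pd.read_csv(_require(fx / "presences.csv", "simulate", "prep"))
        env = EnvStack.read_dir(_require(fx / "env", "simulate", "prep"))
    if not {"lon", "lat"} <= set(occ.columns):
        raise ValueError("occurrence CSV must have 'lon' and 'lat' columns")
    prep_cfg = dataclasses.replace(cfg.prep, seed=cfg.seed)
    pres = clean_and_thin(occ, env, prep_cfg)
    area = build_calibration_area(pres, env, prep_cfg)
    bg = sample_background(area, prep_cfg)
    retained = screen_predictors(env, area, prep_cfg)
    pd_dir = out / "prep"
    pd_dir.mkdir(parents=True, exist_ok=True)
    pres.to_csv(pd_dir / "presences_thinned.csv", index=False)
    bg.to_csv(pd_dir / "background.csv", index=False)
    Raster(env.grid, area.mask.astype(float), "calibration_mask").write_ascii(pd_dir / "calibration_mask.asc")
    (pd_dir / "retained_predictors.json").write_text(json.dumps({"retained": retained}, indent=2))


def _load_prep(cfg: RunConfig, out: Path, needed_by: str):
    fx = out / "fixtures"
    env = EnvStack.read_dir(cfg.env_dir) if cfg.env_dir else EnvStack.read_dir(_require(fx / "env", "simulate", needed_by))
    pd_dir = out / "prep"
    pres = pd.read_csv(_require(pd_dir / "presences_thinned.csv", "prep", needed_by))
    bg = pd.read_csv(_require(pd_dir / "background.csv", "prep", needed_by))
    mask = Raster.read_ascii(pd_dir / "calibration_mask.asc").values
    area = CalibrationArea(env.grid, np.nan_to_num(mask) > 0.5)
    retained = json.loads((pd_dir / "retained_predictors.json").read_text())["retained"]
    return env.subset(retained), pres, bg, area


def stage_fit(cfg: RunConfig, out: Path) -> None:
    env, pres, bg, area = _load_prep(cfg, out, "fit")
    train = build_training_table(pres, bg, env, k=cfg.n_folds, seed=cfg.seed)
    base, tune_tables = _fit_base_models(train, cfg)
    fit_dir = out / "fit"
    fit_dir.mkdir(parents=True, exist_ok=True)
    train.to_csv(fit_dir / "training_table.csv", index=False)
    (fit_dir / "hyperparams.json").write_text(
        json.dumps({a: base[a].hyperparams for a in ALGORITHMS}, indent=2, default=str)
    )
    if tune_tables is not None:
        tune_tables.to_csv(fit_dir / "candidates.csv", index=False)
    for a in ALGORITHMS:
        predict_map(base[a], env, area).write_ascii(fit_dir / f"suitability_{META_COLS[a]}.asc")


def stage_stack(cfg: RunConfig, out: Path) -> None:
    env, pres, bg, area = _load_prep(cfg, out, "stack")
    fit_dir = out / "fit"
    train = pd.read_csv(_require(fit_dir / "training_table.csv", "fit", "stack"))
    hyper = json.loads(_require(fit_dir / "hyperparams.json", "fit", "stack").read_text())
    hyper = {a: hyper[a] for a in ALGORITHMS}
    base = {a: fit_algorithm(a, train, hyper[a]) for a in ALGORITHMS}
    poly_path = cfg.expert_geojson or out / "fixtures" / "expert_range.geojson"
    poly = read_geojson(_require(Path(poly_path), "simulate", "stack"))
    dist = distance_to_range(poly, env, area)
    coords = pd.concat([pres[["lon", "lat"]], bg[["lon", "lat"]]], ignore_index=True)
    meta_occ = build_meta_table(base, train, mode=cfg.stacking_mode)
    meta_exp = build_meta_table(base, train, mode=cfg.stacking_mode, dist=dist, point_coords=coords)
    fit_occ = fit_meta(meta_occ, cfg.stacking_mode)
    fit_exp = fit_meta(meta_exp, cfg.stacking_mode)
    st = out / "stack"
    st.mkdir(parents=True, exist_ok=True)
    dist.write_ascii(st / "distance_to_expert_range_km.asc")
    meta_exp.to_csv(st / "meta_table.csv", index=False)
    rows = []
    labels = {"glm": "GLM", "gam": "GAM", "maxent": "MaxEnt", "rf": "RF", DIST_COL: "Distance to expert range"}
    for name in ["glm", "gam", "maxent", "rf", DIST_COL]:
        rows.append(
            {
                "predictor": labels[name],
                "occurrence_only_coef": fit_occ.coefficients.get(name, np.nan),
                "occurrence_only_p": fit_occ.p_values.get(name, np.nan),
                "expert_informed_coef": fit_exp.coefficients.get(name, np.nan),
                "expert_informed_p": fit_exp.p_values.get(name, np.nan),
            }
        )
    pd.DataFrame(rows).to_csv(st / "meta_coefficients.csv", index=False)
    base_maps = {a: Raster.read_ascii(fit_dir / f"suitability_{META_COLS[a]}.asc") for a in ALGORITHMS}
    predict_ensemble(fit_occ, base_maps).write_ascii(st / f"suitability_{ENSEMBLE_NAMES[0]}.asc")
    predict_ensemble(fit_exp, base_maps, dist=dist).write_ascii(st / f"suitability_{ENSEMBLE_NAMES[1]}.asc")


def stage_evaluate(cfg: RunConfig, out: Path) -> None:
    env, pres, bg, area = _load_prep(cfg, out, "evaluate")
    fit_dir = out / "fit"
    train = pd.read_csv(_require(fit_dir / "training_table.csv", "fit", "evaluate"))
    hyper = json.loads(_require(fit_dir / "hyperparams.json", "fit", "evaluate").read_text())
    st = out / "stack"
    meta = pd.read_csv(_require(st / "meta_table.csv", "stack", "evaluate"))
    dist_values = meta[DIST_COL].to_numpy()
    cv = crossvalidate(train, hyper, dist_values=dist_values, boyce_cfg=cfg.boyce, stacking_mode=cfg.stacking_mode)
    ev = out / "evaluate"
    ev.mkdir(parents=True, exist_ok=True)
    cv.to_csv(ev / "cv_metrics.csv", index=False)
    summarize_cv(cv).to_csv(ev / "cv_summary.csv", index=False)
    # binarize ensembles at the 10% omission threshold and summarize
    poly_path = cfg.expert_geojson or out / "fixtures" / "expert_range.geojson"
    poly = read_geojson(Path(poly_path))
    rows = []
    n_pres = len(pres)
    for name in ENSEMBLE_NAMES:
        smap = Raster.read_ascii(st / f"suitability_{name}.asc")
        pres_suit = smap.sample(pres["lon"].to_numpy(), pres["lat"].to_numpy())
        thr = omission_threshold(pres_suit[np.isfinite(pres_suit)])
        bmap = binarize(smap, thr)
        bmap.raster.write_ascii(ev / f"binary_{name}.asc", fmt="%.0f")
        s = summarize_range(bmap, poly)
        rows.append(
            {
                "model": name,
                "threshold": thr,
                "n_presences": n_pres,
                "area_km2": s.area_km2,
                "southernmost_lat": s.southernmost_lat,
                "pct_within_expert": s.pct_within_expert,
            }
        )
    pd.DataFrame(rows).to_csv(ev / "range_summaries.csv", index=False)


def stage_compare(cfg: RunConfig, out: Path) -> None:
    ev = out / "evaluate"
    cv = pd.read_csv(_require(ev / "cv_metrics.csv", "evaluate", "compare"))
    rows = []
    for metric in ("boyce", "auc", "tss"):
        res = compare_models(cv, ENSEMBLE_NAMES[0], ENSEMBLE_NAMES[1], metric=metric)
        rows.append(
            {
                "metric": metric,
                "model_a": res.pair[0],
                "model_b": res.pair[1],
                "V": res.statistic_v,
                "p_value": res.p_value,
                "n_nonzero_pairs": res.n_pairs,
            }
        )
    pd.DataFrame(rows).to_csv(ev / "ensemble_comparison.csv", index=False)


STAGES = {
    "simulate": stage_simulate,
    "prep": stage_prep,
    "fit": stage_fit,
    "stack": stage_stack,
    "evaluate": stage_evaluate,
    "compare": stage_compare,
}


def run_all(cfg: RunConfig) -> Path:
    """Run every stage in order and write the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not cfg.occurrences_csv:
        stage_simulate(cfg, out)
    stage_prep(cfg, out)
    stage_fit(cfg, out)
    stage_stack(cfg, out)
    stage_evaluate(cfg, out)
    stage_compare(cfg, out)
    (out / "manifest.json").write_text(json.dumps(cfg.to_manifest(), indent=2, default=str))
    return out
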