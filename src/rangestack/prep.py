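"""Occurrence cleaning, spatial thinning, calibration area, background
sampling and predictor collinearity screening.

The preparation stage mirrors standard presence-background SDM practice:
records without environmental coverage are dropped; records are thinned
to one per grid cell at the working resolution (0.05 degrees by default)
to damp clustered sampling; the calibration area is a great-circle buffer
(1000 km default) around the presences; background (pseudo-absence)
points are drawn uniformly from that area (10,000 by default); and
collinear predictors (|Pearson r| > 0.7 by default) are removed
greedily, respecting a user keep-list that stands in for expert choice.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .grid import EnvStack, RasterGrid, haversine_km

__all__ = ["PrepConfig", "CalibrationArea", "clean_and_thin", "build_calibration_area", "sample_background", "screen_predictors"]


@dataclasses.dataclass
class PrepConfig:
    thin_resolution: float = 0.05
    corr_threshold: float = 0.7
    buffer_km: float = 1000.0
    n_background: int = 10000
    keep_list: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.corr_threshold < 1.0):
            raise ValueError("corr_threshold must be in (0, 1)")
        if self.n_background < 1:
            raise ValueError("n_background must be >= 1")
        if self.thin_resolution <= 0:
            raise ValueError("thin_resolution must be positive")


@dataclasses.dataclass
class CalibrationArea:
    """Boolean in/out mask over the environmental grid."""

    grid: RasterGrid
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape inconsistent with grid")

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())


def clean_and_thin(raw: pd.DataFrame, env: EnvStack, cfg: PrepConfig) -> pd.DataFrame:
    """Drop records without environmental coverage, then thin to one
    record per ``thin_resolution`` cell.

    Thinning keeps the first record (input order) in each thinning cell,
    so it is deterministic and idempotent.
    """
    if len(raw) == 0:
        raise ValueError("no occurrence records supplied")
    df = raw.reset_index(drop=True)
    inside = env.grid.contains(df["lon"].to_numpy(), df["lat"].to_numpy())
    df = df[inside]
    if len(df):
        row, col = env.grid.cell_of(df["lon"].to_numpy(), df["lat"].to_numpy())
        df = df[env.mask[row, col]]
    if len(df) == 0:
        raise ValueError("no records survive cleaning (all on land/nodata or off-grid)")
    # global thinning lattice anchored at (0, 0)
    ti = np.floor(df["lon"].to_numpy() / cfg.thin_resolution).astype(np.int64)
    tj = np.floor(df["lat"].to_numpy() / cfg.thin_resolution).astype(np.int64)
    keep = ~pd.Series(list(zip(ti, tj))).duplicated().to_numpy()
    return df[keep].reset_index(drop=True)


def build_calibration_area(presences: pd.DataFrame, env: EnvStack, cfg: PrepConfig) -> CalibrationArea:
    """Cells whose centre lies within ``buffer_km`` (haversine) of any
    presence, intersected with the environmental mask."""
    if len(presences) == 0:
        raise ValueError("no presences supplied")
    grid = env.grid
    lon2d, lat2d = grid.center_mesh()
    cell_lon = lon2d.ravel()
    cell_lat = lat2d.ravel()
    plon = presences["lon"].to_numpy()
    plat = presences["lat"].to_numpy()
    within = np.zeros(cell_lon.shape, dtype=bool)
    chunk = 200000 // max(1, len(plon) // 64 + 1)
    for start in range(0, len(cell_lon), max(chunk, 1000)):
        sl = slice(start, start + max(chunk, 1000))
        d = haversine_km(cell_lon[sl, None], cell_lat[sl, None], plon[None, :], plat[None, :])
        within[sl] = (d <= cfg.buffer_km).any(axis=1)
    mask = within.reshape(grid.shape) & env.mask
    # presences sit at distance zero from themselves, so their cells are in
    prow, pcol = grid.cell_of(plon, plat)
    assert mask[prow, pcol].all(), "presence cell outside its own calibration buffer"
    return CalibrationArea(grid=grid, mask=mask)


def sample_background(area: CalibrationArea, cfg: PrepConfig) -> pd.DataFrame:
    """Uniform background points over the calibration cells.

    Cells are drawn with replacement (10,000 points typically exceed the
    cell count), and each point is jittered uniformly within its cell.
    """
    if area.n_cells == 0:
        raise ValueError("empty calibration area")
    rng = np.random.default_rng(cfg.seed)
    rows, cols = np.nonzero(area.mask)
    pick = rng.integers(0, len(rows), size=cfg.n_background)
    g = area.grid
    half = g.resolution / 2.0
    lon = g.lon_centers[cols[pick]] + rng.uniform(-half, half, size=cfg.n_background)
    lat = g.lat_centers[rows[pick]] + rng.uniform(-half, half, size=cfg.n_background)
    return pd.DataFrame({"lon": lon, "lat": lat})


def screen_predictors(env: EnvStack, area: CalibrationArea, cfg: PrepConfig) -> list[str]:
    """Greedy collinearity filter over calibration cells.

    While any pair of retained predictors has |Pearson r| above the
    threshold, drop the non-protected member involved in an offending
    pair that has the highest mean absolute correlation with the rest.
    Raises if two protected predictors are themselves collinear.
    """
    if env.n_layers < 2:
        raise ValueError("need at least two predictors to screen")
    rows, cols = np.nonzero(area.mask)
    table = env.table_at_cells(rows, cols)
    names = list(env.names)
    corr = table.corr().abs()
    keep = set(cfg.keep_list)
    retained = list(names)
    while True:
        sub = corr.loc[retained, retained]
        offending = [
            (a, b)
            for i, a in enumerate(retained)
            for b in retained[i + 1 :]
            if sub.loc[a, b] > cfg.corr_threshold
        ]
        if not offending:
            break
        if any(a in keep and b in keep for a, b in offending):
            bad = [(a, b) for a, b in offending if a in keep and b in keep]
            raise ValueError(f"protected predictors are mutually collinear: {bad}")
        candidates = {n for pair in offending for n in pair} - keep
        mean_abs = {n: (sub.loc[n, [m for m in retained if m != n]]).mean() for n in candidates}
        drop = max(mean_abs, key=mean_abs.get)
        retained.remove(drop)
        if len(retained) < 2:
            break
    sub = corr.loc[retained, retained].to_numpy()
    assert (sub[~np.eye(len(retained), dtype=bool)] <= cfg.corr_threshold).all() or len(retained) < 2
    return retained
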