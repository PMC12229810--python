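"""Virtual-species simulation with a dispersal barrier.

The simulator builds an artificial seascape and a species whose true
habitat suitability is a known logistic function of the environment, but
whose realized occupancy is truncated south of a latitudinal dispersal
barrier — the situation of a coastal species whose larvae cannot cross a
freshwater plume.  Because environmentally suitable habitat exists south
of the barrier while the species never occurs there, occurrence-trained
models are expected to overpredict southward, and an expert range polygon
(occupied region plus a commission-error buffer) carries exactly the
range-limit information the models lack.  Every downstream stage of the
package can therefore be exercised and validated offline, against a known
truth.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from scipy.special import expit
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

from .grid import EnvStack, KM_PER_DEG, Raster, RasterGrid, write_geojson

__all__ = ["VirtualSpeciesConfig", "TruthBundle", "generate_env", "make_truth", "sample_presences", "simulate", "write_bundle"]


@dataclasses.dataclass
class VirtualSpeciesConfig:
    """Configuration of the virtual seascape and species.

    Defaults describe a 120x120-cell, 12x12-degree coastal domain with a
    dispersal barrier one third of the way up, four environmental layers,
    and a 300-record biased occurrence sample — a small analogue of a
    regional marine SDM study.
    """

    lon_min: float = 115.0
    lon_max: float = 127.0
    lat_min: float = 20.0
    lat_max: float = 32.0
    resolution: float = 0.1
    n_env: int = 4
    #: intercept and per-layer linear/quadratic coefficients of the true
    #: suitability logit.  Layer 0 has a longitudinal gradient, so high
    #: suitability forms a band that crosses the barrier; the latitudinal
    #: layer gets only a weak coefficient so the environment alone does
    #: not reveal the barrier.
    b0: float = 0.5
    beta: tuple[float, ...] = (1.2, 0.3, 0.4, 0.0)
    gamma: tuple[float, ...] = (-1.0, -0.2, 0.0, -0.3)
    barrier_lat: float = 24.0
    n_presence: int = 300
    sampling_bias_strength: float = 1.0
    coastal_kernel: str = "west"  # "west" (sampling effort decays eastward) or "uniform"
    expert_buffer_km: float = 50.0
    #: omission-error radius (km): the expert polygon is a morphological
    #: opening of the occupied-cell union at this radius, so scattered
    #: marginal occurrences fall outside the mapped range, as real expert
    #: maps miss range fringes.  0 disables omission error.
    expert_omission_km: float = 10.0
    noise_sigma_cells: float = 5.0
    noise_weight: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_presence < 1:
            raise ValueError("n_presence must be >= 1")
        if self.expert_buffer_km < 0:
            raise ValueError("expert_buffer_km must be >= 0")
        if self.sampling_bias_strength < 0:
            raise ValueError("sampling_bias_strength must be >= 0")
        if len(self.beta) != self.n_env or len(self.gamma) != self.n_env:
            raise ValueError("beta and gamma must have one entry per environmental layer")

    @property
    def grid(self) -> RasterGrid:
        nrows = int(round((self.lat_max - self.lat_min) / self.resolution))
        ncols = int(round((self.lon_max - self.lon_min) / self.resolution))
        return RasterGrid(west=self.lon_min, south=self.lat_min, resolution=self.resolution, nrows=nrows, ncols=ncols)


@dataclasses.dataclass
class TruthBundle:
    """Everything the simulator knows: the answer key for the pipeline."""

    config: VirtualSpeciesConfig
    env: EnvStack
    true_suitability: Raster
    occupancy: np.ndarray  # int {0,1} on the grid; 0 wherever masked
    expert_polygon: BaseGeometry
    presences: pd.DataFrame  # columns lon, lat


def generate_env(config: VirtualSpeciesConfig) -> EnvStack:
    """Simulate environmental layers: smooth gradient + autocorrelated noise.

    Each layer is a deterministic planar gradient (direction rotating with
    layer index, so layer 0 is longitudinal and layer 1 latitudinal) plus
    spatially autocorrelated noise made by Gaussian-smoothing white noise
    (sigma = ``noise_sigma_cells`` cells).  Layers are standardized to
    mean 0, sd 1 over unmasked cells.
    """
    grid = config.grid
    if grid.nrows < 4 or grid.ncols < 4:
        raise ValueError("degenerate grid: need at least 4x4 cells")
    rng = np.random.default_rng(config.seed)
    lon2d, lat2d = grid.center_mesh()
    # normalized coordinates in [-1, 1]
    u = 2.0 * (lon2d - grid.west) / (grid.east - grid.west) - 1.0
    v = 2.0 * (lat2d - grid.south) / (grid.north - grid.south) - 1.0
    mask = np.ones(grid.shape, dtype=bool)
    layers = []
    for j in range(config.n_env):
        theta = (j % 4) * np.pi / 4.0  # 0: lon, pi/4: diagonal, pi/2: lat, ...
        gradient = np.cos(theta) * u + np.sin(theta) * v
        noise = gaussian_filter(rng.standard_normal(grid.shape), sigma=config.noise_sigma_cells)
        noise_sd = noise.std()
        if noise_sd > 0:
            noise = noise / noise_sd
        layer = gradient + config.noise_weight * noise
        layer = (layer - layer[mask].mean()) / layer[mask].std()
        layers.append(layer)
    return EnvStack(grid=grid, names=[f"env{j + 1}" for j in range(config.n_env)], data=np.stack(layers), mask=mask)


def make_truth(env: EnvStack, config: VirtualSpeciesConfig) -> TruthBundle:
    """Build the true suitability surface, barrier-truncated occupancy and
    the expert range polygon.

    Suitability is logistic(b0 + sum beta_j x_j + sum gamma_j x_j^2).
    Occupancy is Bernoulli(suitability) north of the barrier latitude and
    identically zero south of it.  The expert polygon is the union of
    occupied cells dilated by ``expert_buffer_km`` (commission error).
    """
    grid = env.grid
    logit = np.full(grid.shape, config.b0)
    for j in range(config.n_env):
        logit += config.beta[j] * env.data[j] + config.gamma[j] * env.data[j] ** 2
    suit = expit(logit)
    suit_r = Raster(grid=grid, values=np.where(env.mask, suit, np.nan), name="true_suitability")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    _, lat2d = grid.center_mesh()
    north_of_barrier = lat2d >= config.barrier_lat
    occ = (rng.random(grid.shape) < suit) & north_of_barrier & env.mask
    occupancy = occ.astype(int)
    if occupancy.sum() == 0:
        raise RuntimeError("simulation failure: no occupied cells (true suitability too low)")
    south_suitable = (~north_of_barrier) & env.mask & (suit >= 0.5)
    if not south_suitable.any():
        raise RuntimeError(
            "simulation failure: no suitable-but-unoccupied habitat south of the barrier; "
            "the barrier experiment would be vacuous"
        )

    res = grid.resolution
    lon2d, _ = grid.center_mesh()
    rows, cols = np.nonzero(occupancy)
    cells = [
        box(lon2d[r, c] - res / 2, lat2d[r, c] - res / 2, lon2d[r, c] + res / 2, lat2d[r, c] + res / 2)
        for r, c in zip(rows, cols)
    ]
    occupied_union = shapely.union_all(cells)
    # Expert maps are coarse: they overdraw the range margin (commission,
    # emulated by the outward buffer) while missing scattered marginal
    # occurrences (omission, emulated by a morphological opening that
    # erases occupied specks isolated from the range core).  Buffers are
    # in degrees of latitude-equivalent arc; adequate at these scales.
    poly = occupied_union
    if config.expert_omission_km > 0:
        om = config.expert_omission_km / KM_PER_DEG
        core = poly.buffer(-om).buffer(om)
        if not core.is_empty:
            poly = core
    if config.expert_buffer_km > 0:
        poly = poly.buffer(config.expert_buffer_km / KM_PER_DEG)

    bundle = TruthBundle(
        config=config,
        env=env,
        true_suitability=suit_r,
        occupancy=occupancy,
        expert_polygon=poly,
        presences=pd.DataFrame(columns=["lon", "lat"]),
    )
    bundle.presences = sample_presences(bundle, config)
    return bundle


def _coastal_weight(kind: str, lon: np.ndarray, grid: RasterGrid) -> np.ndarray:
    """Fixed spatial sampling-effort kernel (emulating nearshore bias)."""
    if kind == "uniform":
        return np.ones_like(lon)
    if kind == "west":
        # effort decays eastward from the "coast" at the western edge
        span = grid.east - grid.west
        return np.exp(-2.0 * (lon - grid.west) / span)
    raise ValueError(f"unknown coastal kernel {kind!r}")


def sample_presences(truth: TruthBundle, config: VirtualSpeciesConfig) -> pd.DataFrame:
    """Draw biased presence records from occupied cells.

    Cells are drawn without replacement with weight proportional to
    suitability**bias_strength times the fixed coastal kernel; coordinates
    are jittered uniformly within the cell (clamped so no record falls
    south of the barrier).
    """
    grid = truth.env.grid
    rows, cols = np.nonzero(truth.occupancy)
    if len(rows) < config.n_presence:
        raise ValueError(f"only {len(rows)} occupied cells; cannot draw {config.n_presence} presences")
    lon2d, lat2d = grid.center_mesh()
    lon_c, lat_c = lon2d[rows, cols], lat2d[rows, cols]
    suit = truth.true_suitability.values[rows, cols]
    w = suit**config.sampling_bias_strength * _coastal_weight(config.coastal_kernel, lon_c, grid)
    w = w / w.sum()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    pick = rng.choice(len(rows), size=config.n_presence, replace=False, p=w)
    half = grid.resolution / 2.0
    lon = lon_c[pick] + rng.uniform(-half, half, size=config.n_presence)
    lat = lat_c[pick] + rng.uniform(-half, half, size=config.n_presence)
    lat = np.maximum(lat, config.barrier_lat)
    return pd.DataFrame({"lon": lon, "lat": lat})


def simulate(config: VirtualSpeciesConfig | None = None, **overrides) -> TruthBundle:
    """One-call simulation: environment, truth, expert polygon, presences."""
    if config is None:
        config = VirtualSpeciesConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    env = generate_env(config)
    return make_truth(env, config)


def write_bundle(bundle: TruthBundle, outdir: str | Path) -> None:
    """Write the simulated fixture set under ``outdir``.

    Environmental layers as ASCII grids, presences as CSV (lon,lat),
    the expert polygon as GeoJSON, the truth layers for reference.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.env.write_dir(outdir / "env")
    bundle.presences.to_csv(outdir / "presences.csv", index=False)
    write_geojson(bundle.expert_polygon, outdir / "expert_range.geojson", properties={"source_label": "synthetic expert range"})
    bundle.true_suitability.write_ascii(outdir / "true_suitability.asc")
    Raster(grid=bundle.env.grid, values=bundle.occupancy.astype(float), name="occupancy").write_ascii(outdir / "occupancy.asc")
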