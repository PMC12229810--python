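"""Regular lon/lat raster containers and plain-text geospatial I/O.

All rasters in this package live on a shared regular geographic grid
(EPSG:4326, degrees).  Layers are stored as ESRI ASCII grids (``.asc``) —
a plain-text format every GIS reads — with a small JSON sidecar carrying
layer names for multi-layer stacks.  Polygons are GeoJSON via shapely.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

EARTH_RADIUS_KM = 6371.0
#: kilometres per degree of great-circle arc on the R=6371 sphere
KM_PER_DEG = np.pi * EARTH_RADIUS_KM / 180.0

__all__ = [
    "EARTH_RADIUS_KM",
    "KM_PER_DEG",
    "RasterGrid",
    "Raster",
    "EnvStack",
    "haversine_km",
    "read_geojson",
    "write_geojson",
]


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees.

    Broadcasts like numpy; uses the haversine formula on a sphere of
    radius 6371 km.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclasses.dataclass(frozen=True)
class RasterGrid:
    """A regular lon/lat grid: row 0 is the northernmost row."""

    west: float
    south: float
    resolution: float
    nrows: int
    ncols: int

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def north(self) -> float:
        return self.south + self.nrows * self.resolution

    @property
    def east(self) -> float:
        return self.west + self.ncols * self.resolution

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.ncols) + 0.5) * self.resolution

    @property
    def lat_centers(self) -> np.ndarray:
        """Cell-centre latitudes, north to south (matching row order)."""
        return self.north - (np.arange(self.nrows) + 0.5) * self.resolution

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        lon2d, lat2d = np.meshgrid(self.lon_centers, self.lat_centers)
        return lon2d, lat2d

    def cell_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point (no bounds check)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.west) / self.resolution).astype(int)
        row = np.floor((self.north - lat) / self.resolution).astype(int)
        # points exactly on the north/east edge belong to the outermost cell
        col = np.where((lon == self.east), self.ncols - 1, col)
        row = np.where((lat == self.north), 0, row)
        return row, col

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (lon >= self.west) & (lon <= self.east) & (lat >= self.south) & (lat <= self.north)

    def cell_area_km2(self) -> np.ndarray:
        """Spherical cell areas, one value per row (constant along a row).

        Area of a lon/lat rectangle on the sphere:
        R^2 * dlambda * (sin(phi_top) - sin(phi_bottom)).
        """
        res = np.radians(self.resolution)
        lat_top = np.radians(self.north - np.arange(self.nrows) * self.resolution)
        lat_bot = lat_top - np.radians(self.resolution)
        return EARTH_RADIUS_KM**2 * res * (np.sin(lat_top) - np.sin(lat_bot))


@dataclasses.dataclass
class Raster:
    """A single raster layer; NaN marks nodata."""

    grid: RasterGrid
    values: np.ndarray
    name: str = "layer"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(f"values shape {self.values.shape} != grid shape {self.grid.shape}")

    @property
    def mask(self) -> np.ndarray:
        """Boolean array of valid (non-nodata) cells."""
        return np.isfinite(self.values)

    def sample(self, lon, lat) -> np.ndarray:
        """Raster value at each point (NaN outside the grid)."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        out = np.full(lon.shape, np.nan)
        inside = self.grid.contains(lon, lat)
        row, col = self.grid.cell_of(lon[inside], lat[inside])
        out[inside] = self.values[row, col]
        return out

    def write_ascii(self, path: str | Path, nodata: float = -9999.0, fmt: str = "%.8g") -> None:
        g = self.grid
        vals = np.where(np.isfinite(self.values), self.values, nodata)
        header = (
            f"ncols {g.ncols}\nnrows {g.nrows}\n"
            f"xllcorner {g.west:.10g}\nyllcorner {g.south:.10g}\n"
            f"cellsize {g.resolution:.10g}\nNODATA_value {nodata:g}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt=fmt)

    @classmethod
    def read_ascii(cls, path: str | Path, name: str | None = None) -> "Raster":
        path = Path(path)
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals)
        grid = RasterGrid(
            west=header["xllcorner"],
            south=header["yllcorner"],
            resolution=header["cellsize"],
            nrows=int(header["nrows"]),
            ncols=int(header["ncols"]),
        )
        nodata = header.get("nodata_value")
        if nodata is not None:
            vals = np.where(vals == nodata, np.nan, vals)
        return cls(grid=grid, values=vals, name=name or path.stem)


@dataclasses.dataclass
class EnvStack:
    """A stack of co-registered environmental layers on one grid."""

    grid: RasterGrid
    names: list[str]
    data: np.ndarray  # (n_layers, nrows, ncols)
    mask: np.ndarray  # valid cells, shared by all layers

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != (len(self.names), *self.grid.shape):
            raise ValueError("data shape inconsistent with names/grid")
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape inconsistent with grid")

    @property
    def n_layers(self) -> int:
        return len(self.names)

    def layer(self, name: str) -> Raster:
        idx = self.names.index(name)
        vals = np.where(self.mask, self.data[idx], np.nan)
        return Raster(grid=self.grid, values=vals, name=name)

    def subset(self, names: list[str]) -> "EnvStack":
        idx = [self.names.index(n) for n in names]
        return EnvStack(grid=self.grid, names=list(names), data=self.data[idx], mask=self.mask)

    def table_at_cells(self, rows: np.ndarray, cols: np.ndarray) -> pd.DataFrame:
        """Predictor values at the given cells as a DataFrame."""
        return pd.DataFrame({n: self.data[i, rows, cols] for i, n in enumerate(self.names)})

    def table_at_points(self, lon, lat) -> pd.DataFrame:
        rows, cols = self.grid.cell_of(lon, lat)
        return self.table_at_cells(rows, cols)

    def write_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in self.names:
            self.layer(name).write_ascii(outdir / f"{name}.asc")
        (outdir / "layers.json").write_text(json.dumps({"names": self.names}, indent=2))

    @classmethod
    def read_dir(cls, indir: str | Path) -> "EnvStack":
        indir = Path(indir)
        names = json.loads((indir / "layers.json").read_text())["names"]
        layers = [Raster.read_ascii(indir / f"{n}.asc", name=n) for n in names]
        grid = layers[0].grid
        data = np.stack([r.values for r in layers])
        mask = np.all(np.isfinite(data), axis=0)
        return cls(grid=grid, names=names, data=np.nan_to_num(data), mask=mask)


def read_geojson(path: str | Path) -> BaseGeometry:
    """Read the first (or only) geometry from a GeoJSON file."""
    obj = json.loads(Path(path).read_text())
    if obj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in obj["features"]]
        return shapely.union_all(geoms) if len(geoms) > 1 else geoms[0]
    if obj.get("type") == "Feature":
        return shape(obj["geometry"])
    return shape(obj)


def write_geojson(geom: BaseGeometry, path: str | Path, properties: dict | None = None) -> None:
    feature = {"type": "Feature", "properties": properties or {}, "geometry": mapping(geom)}
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": [feature]}))
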