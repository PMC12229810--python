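"""Discrimination metrics, thresholding and map summaries for
presence-background models.

The continuous Boyce index is the headline metric: the Spearman rank
correlation between the predicted-to-expected presence ratio and habitat
suitability across moving suitability windows (1 = perfect ranking, 0 =
random, negative = inverse).  AUC and TSS are presence-vs-background
versions of the usual discrimination statistics.  Model comparison uses
the exact two-sided Wilcoxon signed-rank test on fold-paired metric
values.  Continuous maps are binarized at the 10% omission-rate
threshold (the 10th percentile of training-presence predictions) and
summarized by suitable area, southernmost latitude, and overlap with the
expert range polygon.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import shapely
from scipy import stats
from shapely.geometry.base import BaseGeometry

from .grid import Raster

__all__ = [
    "BoyceConfig",
    "boyce_index",
    "auc",
    "tss",
    "wilcoxon_signed_rank",
    "compare_models",
    "omission_threshold",
    "BinaryMap",
    "binarize",
    "RangeSummary",
    "summarize_range",
]


@dataclasses.dataclass
class BoyceConfig:
    n_windows: int = 101
    window_fraction: float = 0.1

    def __post_init__(self):
        if self.n_windows < 3:
            raise ValueError("n_windows must be >= 3")
        if not (0.0 < self.window_fraction < 1.0):
            raise ValueError("window_fraction must be in (0, 1)")


def boyce_index(pres_suit, background_suit, cfg: BoyceConfig | None = None) -> float:
    """Continuous Boyce index of a suitability prediction.

    Windows of width ``window_fraction`` x (max - min) with midpoints
    evenly spaced over the pooled suitability range; per window, F_i =
    (fraction of presences inside) / (fraction of background inside),
    windows without background dropped; the index is the Spearman rank
    correlation of F_i against the window midpoint.  Following the
    standard continuous-Boyce implementation, runs of consecutive equal
    F values (overlapping windows seeing the same points) are collapsed
    to their first window before the correlation; an exactly flat F
    profile is the random-prediction case and returns 0.
    """
    cfg = cfg or BoyceConfig()
    pres = np.asarray(pres_suit, dtype=float)
    bg = np.asarray(background_suit, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise ValueError("presence and background suitability vectors must be non-empty")
    lo = min(pres.min(), bg.min())
    hi = max(pres.max(), bg.max())
    if bg.std() == 0 or hi == lo:
        raise ValueError("constant suitability: Boyce index undefined")
    width = cfg.window_fraction * (hi - lo)
    mids = np.linspace(lo + width / 2.0, hi - width / 2.0, cfg.n_windows)
    f_vals, f_mids = [], []
    for m in mids:
        a, b = m - width / 2.0, m + width / 2.0
        e = np.mean((bg >= a) & (bg <= b))
        if e == 0:
            continue
        p = np.mean((pres >= a) & (pres <= b))
        f_vals.append(p / e)
        f_mids.append(m)
    if len(f_vals) == 0:
        raise ValueError("all windows empty of background: Boyce index undefined")
    f_vals = np.asarray(f_vals)
    f_mids = np.asarray(f_mids)
    if np.all(f_vals == f_vals[0]):
        return 0.0
    keep = np.concatenate([[True], f_vals[1:] != f_vals[:-1]])
    f_vals, f_mids = f_vals[keep], f_mids[keep]
    rho = stats.spearmanr(f_mids, f_vals).statistic
    return float(rho)


def auc(pres_suit, background_suit) -> float:
    """Rank-based (Mann-Whitney) AUC, ties counted one half."""
    pres = np.asarray(pres_suit, dtype=float)
    bg = np.asarray(background_suit, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise ValueError("presence and background suitability vectors must be non-empty")
    ranks = stats.rankdata(np.concatenate([pres, bg]))
    r1 = ranks[: pres.size].sum()
    return float((r1 - pres.size * (pres.size + 1) / 2.0) / (pres.size * bg.size))


def tss(pres_suit, background_suit) -> float:
    """Max-over-thresholds true skill statistic (sensitivity+specificity-1).

    Candidate thresholds are the midpoints between consecutive sorted
    unique suitability values (plus one below the minimum so the trivial
    all-suitable classification, TSS = 0, is always available).
    """
    pres = np.asarray(pres_suit, dtype=float)
    bg = np.asarray(background_suit, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise ValueError("presence and background suitability vectors must be non-empty")
    uniq = np.unique(np.concatenate([pres, bg]))
    thresholds = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0])
    best = -1.0
    for t in thresholds:
        sens = np.mean(pres >= t)
        spec = np.mean(bg < t)
        best = max(best, sens + spec - 1.0)
    return float(best)


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test, exact for n <= 25.

    Zero differences are dropped; ties among |differences| get average
    ranks.  Returns (V, p) where V is the sum of ranks of positive
    differences.  The exact null distribution (uniform over sign
    assignments, conditional on the observed ranks) is computed by
    dynamic programming; beyond n = 25 a tie-corrected normal
    approximation is used.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero: test undefined")
    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    if n <= 25:
        # average ranks are multiples of 1/2: double them to integers
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: counts.size - r]
            counts = counts + shifted
        counts /= counts.sum()
        v2 = int(round(2 * v))
        p_le = counts[: v2 + 1].sum()
        p_ge = counts[v2:].sum()
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        tie_term = np.sum(ranks**2)  # handles ties exactly: var = sum r_i^2 / 4
        sd = math.sqrt(tie_term / 4.0)
        z = (v - mean) / sd
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return v, float(p)


@dataclasses.dataclass
class ComparisonResult:
    pair: tuple[str, str]
    statistic_v: float
    p_value: float
    n_pairs: int
    metric: str


def compare_models(cv, a: str, b: str, metric: str = "boyce") -> ComparisonResult:
    """Exact paired Wilcoxon test between two models' per-fold metrics.

    ``cv`` is a long-format DataFrame with columns ``fold``, ``model``
    and one column per metric (the output of the cross-validation
    driver); folds must be shared between the two models.
    """
    xa = cv[cv["model"] == a].sort_values("fold")[metric].to_numpy()
    xb = cv[cv["model"] == b].sort_values("fold")[metric].to_numpy()
    if len(xa) != len(xb) or len(xa) == 0:
        raise ValueError(f"models {a!r} and {b!r} do not share folds")
    d = xb - xa
    v, p = wilcoxon_signed_rank(xb, xa)
    return ComparisonResult(pair=(a, b), statistic_v=v, p_value=p, n_pairs=int(np.sum(d != 0)), metric=metric)


def omission_threshold(train_pres_suit, rate: float = 0.10) -> float:
    """Omission-rate threshold from training-presence suitabilities.

    Sorted-value convention: the ceil(rate * n)-th smallest value, so at
    least (1 - rate) of training presences sit at or above the threshold.
    """
    if not (0.0 < rate < 1.0):
        raise ValueError("rate must be in (0, 1)")
    vals = np.sort(np.asarray(train_pres_suit, dtype=float))
    if vals.size == 0:
        raise ValueError("empty training-presence vector")
    k = math.ceil(rate * vals.size)
    return float(vals[k - 1])


@dataclasses.dataclass
class BinaryMap:
    """Thresholded suitability: 1 suitable, 0 unsuitable, NaN nodata."""

    raster: Raster
    threshold: float

    @property
    def suitable(self) -> np.ndarray:
        return np.nan_to_num(self.raster.values, nan=0.0) >= 1.0


def binarize(suitability: Raster, threshold: float) -> BinaryMap:
    """Suitable iff suitability >= threshold; nodata preserved."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    vals = np.where(np.isfinite(suitability.values), (suitability.values >= threshold).astype(float), np.nan)
    return BinaryMap(raster=Raster(grid=suitability.grid, values=vals, name=f"{suitability.name}_binary"), threshold=threshold)


@dataclasses.dataclass
class RangeSummary:
    area_km2: float
    southernmost_lat: float  # NaN when no suitable cells
    pct_within_expert: float


def summarize_range(bin_map: BinaryMap, poly: BaseGeometry | None = None) -> RangeSummary:
    """Suitable-range summary: spherical area, southern limit, expert overlap.

    Cell areas use R^2 * dlambda * (sin(top) - sin(bottom)) with
    R = 6371 km; a cell counts as inside the expert polygon when its
    centre is covered by (inside or on the boundary of) the polygon.
    """
    grid = bin_map.raster.grid
    suitable = bin_map.suitable
    row_area = grid.cell_area_km2()
    area = float((suitable.sum(axis=1) * row_area).sum())
    if not suitable.any():
        return RangeSummary(area_km2=0.0, southernmost_lat=float("nan"), pct_within_expert=float("nan"))
    rows, cols = np.nonzero(suitable)
    south = float(grid.lat_centers[rows.max()])
    if poly is None:
        pct = float("nan")
    else:
        pts = shapely.points(grid.lon_centers[cols], grid.lat_centers[rows])
        inside = shapely.covers(poly, pts)
        area_inside = float((row_area[rows] * inside).sum())
        pct = 100.0 * area_inside / area
    return RangeSummary(area_km2=area, southernmost_lat=south, pct_within_expert=pct)
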