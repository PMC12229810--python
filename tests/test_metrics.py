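"""Metric correctness against independent brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

import oracles
from rangestack.grid import Raster, RasterGrid
from rangestack.metrics import (
    BoyceConfig,
    auc,
    binarize,
    boyce_index,
    omission_threshold,
    summarize_range,
    tss,
    wilcoxon_signed_rank,
)


def random_instance(rng, n_max=50):
    n1 = int(rng.integers(3, n_max + 1))
    n0 = int(rng.integers(3, n_max + 1))
    if rng.random() < 0.3:  # discretized values force ties
        pres = rng.integers(0, 6, n1) / 5.0
        bg = rng.integers(0, 6, n0) / 5.0
    else:
        pres = rng.random(n1)
        bg = rng.random(n0)
    return pres, bg


def test_metrics_match_bruteforce_oracles():
    """boyce/auc/tss equal loop-based oracles to 1e-9 on 200 random instances."""
    rng = np.random.default_rng(42)
    cfg = BoyceConfig(n_windows=11, window_fraction=0.25)
    checked_boyce = 0
    for _ in range(200):
        pres, bg = random_instance(rng)
        assert auc(pres, bg) == pytest.approx(oracles.auc_oracle(pres, bg), abs=1e-9)
        assert tss(pres, bg) == pytest.approx(oracles.tss_oracle(pres, bg), abs=1e-9)
        expected = oracles.boyce_oracle(pres, bg, cfg.n_windows, cfg.window_fraction)
        if np.isfinite(expected):
            assert boyce_index(pres, bg, cfg) == pytest.approx(expected, abs=1e-9)
            checked_boyce += 1
    assert checked_boyce > 100


def test_wilcoxon_matches_enumeration_and_scipy():
    """Exact signed-rank p equals full 2^n enumeration (and scipy on tie-free data)."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        n = int(rng.integers(4, 13))
        x = rng.random(n)
        if rng.random() < 0.3:
            y = x + rng.integers(-2, 3, n) / 4.0  # ties and zeros
            if np.all(y == x):
                y[0] += 0.25
        else:
            y = x + rng.standard_normal(n)
        d = x - y
        if np.all(d == 0):
            continue
        v, p = wilcoxon_signed_rank(x, y)
        v_o, p_o = oracles.wilcoxon_oracle(x, y)
        assert v == pytest.approx(v_o, abs=1e-9)
        assert p == pytest.approx(p_o, abs=1e-9)
        dd = d[d != 0]
        if len(np.unique(np.abs(dd))) == len(dd):  # scipy exact needs no ties
            sp = stats.wilcoxon(x[d != 0], y[d != 0], method="exact", alternative="two-sided")
            assert p == pytest.approx(sp.pvalue, abs=1e-9)


def test_wilcoxon_known_values_and_symmetry():
    a = np.arange(10.0)
    b = a + 1.0  # all positive differences of b over a
    v, p = wilcoxon_signed_rank(b, a)
    assert v == 55.0
    assert p == pytest.approx(2.0 / 1024.0, abs=1e-12)
    v2, p2 = wilcoxon_signed_rank(a, b)
    assert v2 == 0.0 and p2 == pytest.approx(p, abs=1e-12)
    with pytest.raises(ValueError):
        wilcoxon_signed_rank(a, a)


def test_boyce_separated_and_null_behaviour():
    rng = np.random.default_rng(3)
    bg = rng.random(1000)
    pres = 0.9 + 0.1 * rng.random(1000)  # presences in the top decile
    assert boyce_index(pres, bg) > 0.9
    same = rng.random(1000)
    assert abs(boyce_index(same, same)) < 0.2
    # rank antisymmetry: negating suitability negates the index exactly
    b1 = boyce_index(pres, bg)
    b2 = boyce_index(-pres, -bg)
    assert b2 == pytest.approx(-b1, abs=1e-12)


def test_rank_metrics_invariant_to_monotone_transform():
    rng = np.random.default_rng(5)
    pres = rng.random(300)
    bg = rng.random(500)
    assert auc(pres**3, bg**3) == pytest.approx(auc(pres, bg), abs=1e-12)
    assert boyce_index(pres**3, bg**3) == pytest.approx(boyce_index(pres, bg), abs=0.15)


def test_boyce_undefined_cases_signalled():
    with pytest.raises(ValueError):
        boyce_index(np.full(10, 0.5), np.full(10, 0.5))
    with pytest.raises(ValueError):
        boyce_index(np.array([]), np.array([0.1]))


def test_auc_small_examples():
    assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0
    assert auc([0.5, 0.5], [0.5, 0.5]) == 0.5
    assert auc([0.7, 0.3], [0.5]) == 0.5


def test_tss_examples():
    assert tss([0.9, 0.8], [0.1, 0.2]) == pytest.approx(1.0)
    # sensitivity 0.8, specificity 0.7 at the optimum
    pres = [1.0] * 8 + [0.0] * 2
    bg = [0.0] * 7 + [1.0] * 3
    assert tss(pres, bg) == pytest.approx(0.5)
    rng = np.random.default_rng(9)
    assert tss(rng.random(2000), rng.random(2000)) < 0.15


def test_omission_threshold_convention():
    vals = np.arange(0.1, 1.01, 0.1)
    thr = omission_threshold(vals, rate=0.10)
    assert thr == pytest.approx(0.1)
    assert np.mean(vals < thr) == 0.0
    rng = np.random.default_rng(1)
    u = rng.random(1000)
    thr = omission_threshold(u, rate=0.10)
    frac = np.mean(u < thr)
    assert 0.09 <= frac <= 0.10
    assert omission_threshold(np.full(5, 0.3)) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        omission_threshold(u, rate=1.5)


def _grid_raster(values, west=0.0, south=0.0, res=1.0):
    values = np.asarray(values, dtype=float)
    grid = RasterGrid(west=west, south=south, resolution=res, nrows=values.shape[0], ncols=values.shape[1])
    return Raster(grid=grid, values=values)


def test_binarize_contracts():
    r = _grid_raster([[0.2, 0.8], [np.nan, 0.5]])
    b = binarize(r, 0.0)
    assert np.nansum(b.raster.values) == 3  # all valid cells suitable
    assert np.isnan(b.raster.values[1, 0])  # nodata preserved
    assert binarize(r, 0.9).suitable.sum() == 0
    b2 = binarize(r, 0.5)
    again = binarize(r, b2.threshold)
    np.testing.assert_array_equal(b2.raster.values, again.raster.values)


def test_summarize_range_area_oracle():
    # one suitable 1x1-degree cell centred on the equator
    r = _grid_raster([[1.0]], south=-0.5)
    s = summarize_range(binarize(r, 0.5))
    expected = oracles.strip_area_oracle(-0.5, 0.5, 1.0)
    assert s.area_km2 == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(12364, abs=1.0)


def test_summarize_range_latitude_and_overlap():
    from shapely.geometry import box

    vals = np.zeros((30, 2))
    grid = RasterGrid(west=0.0, south=0.0, resolution=1.0, nrows=30, ncols=2)
    r = Raster(grid=grid, values=vals)
    r.values[grid.cell_of(0.5, 10.5)] = 1.0
    r.values[grid.cell_of(0.5, 20.5)] = 1.0
    s = summarize_range(binarize(r, 0.5), poly=box(-1, -1, 3, 31))
    assert s.southernmost_lat == pytest.approx(10.5)
    assert s.pct_within_expert == pytest.approx(100.0)
    s2 = summarize_range(binarize(r, 0.5), poly=box(-1, 15, 3, 31))
    assert s2.pct_within_expert < 100.0


def test_area_additive_under_retiling():
    """Halving the cell size changes total suitable area by < 1% on a smooth map."""
    grid = RasterGrid(west=0.0, south=10.0, resolution=0.5, nrows=40, ncols=40)
    lon2d, lat2d = grid.center_mesh()
    smooth = np.sin(lon2d / 5.0) + np.cos(lat2d / 5.0)
    coarse = summarize_range(binarize(Raster(grid, smooth), 0.3)).area_km2
    fine_grid = RasterGrid(west=0.0, south=10.0, resolution=0.25, nrows=80, ncols=80)
    flon, flat = fine_grid.center_mesh()
    fine_vals = np.sin(flon / 5.0) + np.cos(flat / 5.0)
    fine = summarize_range(binarize(Raster(fine_grid, fine_vals), 0.3)).area_km2
    assert fine == pytest.approx(coarse, rel=0.01)
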