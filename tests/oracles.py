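"""Independent brute-force oracles used to validate the metric code.

Everything here is written as directly as possible — explicit loops,
pairwise enumeration, exhaustive threshold sweeps, full enumeration of
sign assignments — and deliberately shares no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def average_ranks(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) computed from first principles."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    ranks = np.empty(n)
    for i, v in enumerate(values):
        less = np.sum(values < v)
        equal = np.sum(values == v)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def spearman(x, y) -> float:
    rx = average_ranks(np.asarray(x))
    ry = average_ranks(np.asarray(y))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def boyce_oracle(pres, bg, n_windows: int, window_fraction: float) -> float:
    """Windowed predicted/expected ratio + Spearman, all by explicit loops."""
    pres = np.asarray(pres, dtype=float)
    bg = np.asarray(bg, dtype=float)
    lo = min(pres.min(), bg.min())
    hi = max(pres.max(), bg.max())
    width = window_fraction * (hi - lo)
    mids = np.linspace(lo + width / 2.0, hi - width / 2.0, n_windows)
    f_vals, f_mids = [], []
    for m in mids:
        a, b = m - width / 2.0, m + width / 2.0
        e = sum(1 for v in bg if a <= v <= b) / len(bg)
        if e == 0:
            continue
        p = sum(1 for v in pres if a <= v <= b) / len(pres)
        f_vals.append(p / e)
        f_mids.append(m)
    if len(f_vals) == 0:
        return float("nan")
    if len(set(f_vals)) == 1:
        return 0.0
    # collapse runs of consecutive equal F values to their first window
    kept_v, kept_m = [f_vals[0]], [f_mids[0]]
    for v, m in zip(f_vals[1:], f_mids[1:]):
        if v != kept_v[-1]:
            kept_v.append(v)
            kept_m.append(m)
    if len(kept_v) < 2:
        return 0.0
    return spearman(kept_m, kept_v)


def auc_oracle(pres, bg) -> float:
    """Pairwise win count, ties half."""
    wins = 0.0
    for p in pres:
        for b in bg:
            if p > b:
                wins += 1.0
            elif p == b:
                wins += 0.5
    return wins / (len(pres) * len(bg))


def tss_oracle(pres, bg) -> float:
    """Exhaustive sweep over midpoint thresholds (plus one below min)."""
    pres = np.asarray(pres, dtype=float)
    bg = np.asarray(bg, dtype=float)
    uniq = np.unique(np.concatenate([pres, bg]))
    thresholds = [uniq[0] - 1.0] + [(uniq[i] + uniq[i + 1]) / 2.0 for i in range(len(uniq) - 1)]
    best = -1.0
    for t in thresholds:
        sens = np.mean(pres >= t)
        spec = np.mean(bg < t)
        best = max(best, sens + spec - 1.0)
    return float(best)


def wilcoxon_oracle(x, y) -> tuple[float, float]:
    """Exact two-sided signed-rank p by full enumeration of sign flips.

    Only feasible for n <= ~14; zeros dropped, average ranks for ties.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = average_ranks(np.abs(d))
    v = float(ranks[d > 0].sum())
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(sum(r for s, r in zip(signs, ranks) if s))
    stats = np.asarray(stats)
    n_total = len(stats)
    p_le = np.sum(stats <= v + 1e-12) / n_total
    p_ge = np.sum(stats >= v - 1e-12) / n_total
    return v, min(1.0, 2.0 * min(p_le, p_ge))


def strip_area_oracle(lat_bottom_deg: float, lat_top_deg: float, dlon_deg: float, radius_km: float = 6371.0) -> float:
    """Area of a lon/lat rectangle from the spherical-strip formula."""
    lam = np.radians(dlon_deg)
    return radius_km**2 * lam * (np.sin(np.radians(lat_top_deg)) - np.sin(np.radians(lat_bottom_deg)))
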