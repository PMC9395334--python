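"""Naive reference implementations of the summary statistics.

Explicit double loops over points and r values, written independently of the
package's optimized estimators, used to verify them to floating precision.
"""

import numpy as np


def _edge_weight(pat, u, v, correction):
    X, Y = pat.side_lengths
    if correction == "translation":
        dx = abs(pat.x[u] - pat.x[v])
        dy = abs(pat.y[u] - pat.y[v])
        return (X * Y) / ((X - dx) * (Y - dy))
    return 1.0


def _dist(pat, u, v, correction):
    dx = abs(pat.x[u] - pat.x[v])
    dy = abs(pat.y[u] - pat.y[v])
    if correction == "toroidal":
        X, Y = pat.side_lengths
        dx = min(dx, X - dx)
        dy = min(dy, Y - dy)
    return np.hypot(dx, dy)


def naive_k(pat, r_grid, correction="none"):
    n = pat.n
    out = np.zeros(len(r_grid))
    for ridx, r in enumerate(r_grid):
        s = 0.0
        for u in range(n):
            for v in range(n):
                if u == v:
                    continue
                if _dist(pat, u, v, correction) <= r:
                    s += _edge_weight(pat, u, v, correction)
        out[ridx] = pat.area * s / (n * (n - 1))
    return out


def naive_cross_k(pat, ti, tj, r_grid, correction="none"):
    idx_i = np.flatnonzero(pat.marks == ti)
    idx_j = np.flatnonzero(pat.marks == tj)
    out = np.zeros(len(r_grid))
    for ridx, r in enumerate(r_grid):
        s = 0.0
        for u in idx_i:
            for v in idx_j:
                if u == v:
                    continue
                if _dist(pat, u, v, correction) <= r:
                    s += _edge_weight(pat, u, v, correction)
        out[ridx] = pat.area * s / (len(idx_i) * len(idx_j))
    return out


def epanechnikov(t, h):
    return 0.75 / h * (1 - (t / h) ** 2) if abs(t) <= h else 0.0


def naive_g(pat, r_grid, h, correction="none"):
    n = pat.n
    out = np.zeros(len(r_grid))
    for ridx, r in enumerate(r_grid):
        s = 0.0
        for u in range(n):
            for v in range(n):
                if u == v:
                    continue
                d = _dist(pat, u, v, correction)
                s += epanechnikov(d - r, h) * _edge_weight(pat, u, v, correction)
        out[ridx] = pat.area * s / (2 * np.pi * r * n * (n - 1))
    return out


def naive_p_lm(pat, l, m, r_grid, h):
    n = pat.n
    out = np.full(len(r_grid), np.nan)
    for ridx, r in enumerate(r_grid):
        num = den = 0.0
        for u in range(n):
            for v in range(n):
                if u == v:
                    continue
                kv = epanechnikov(_dist(pat, u, v, "none") - r, h)
                den += kv
                if pat.marks[u] == l and pat.marks[v] == m:
                    num += kv
        if den > 0:
            out[ridx] = num / den
    return out


def naive_k_mm(pat, r_grid, h):
    n = pat.n
    vals = pat.values
    prods = [vals[u] * vals[v] for u in range(n) for v in range(n) if u != v]
    c = np.mean(prods)
    out = np.full(len(r_grid), np.nan)
    for ridx, r in enumerate(r_grid):
        num = den = 0.0
        for u in range(n):
            for v in range(n):
                if u == v:
                    continue
                kv = epanechnikov(_dist(pat, u, v, "none") - r, h)
                den += kv
                num += kv * vals[u] * vals[v]
        if den > 0:
            out[ridx] = (num / den) / c
    return out
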