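"""Summary statistics for (marked) spatial point patterns.

Estimators for Ripley's K, the bivariate cross-K, the pair correlation
function g, the J-function, the Clark–Evans nearest-neighbour test, mark
connection functions p_lm(r) (single pair and full L×L array), and the mark
correlation function k_mm(r), with explicit edge corrections and Monte
Carlo envelopes.

Estimators and conventions
--------------------------
All windows are rectangles [x0, x1) × [y0, y1); |W| denotes the window
area.  With n points and pair weights e(u, v):

    K̂(r)    = |W| / (n(n-1)) · Σ_{u≠v} 1(d_uv ≤ r) e(u, v)
    K̂_ij(r) = |W| / (n_i n_j) · Σ_{u∈i, v∈j, u≠v} 1(d_uv ≤ r) e(u, v)
    ĝ(r)    = |W| / (2πr n(n-1)) · Σ_{u≠v} k_h(d_uv - r) e(u, v)
    p̂_lm(r) = Σ_{u≠v} 1(m_u=l, m_v=m) k_h(d_uv - r) / Σ_{u≠v} k_h(d_uv - r)
    k̂_mm(r) = [Σ_{u≠v} m_u m_v k_h(d_uv - r) / Σ_{u≠v} k_h(d_uv - r)] / c̄,
               c̄ = mean of m_u m_v over all distinct ordered pairs

k_h is the Epanechnikov kernel of half-width h (default 0.15/√λ̂, Stoyan's
rule).  Edge corrections: ``none`` (e ≡ 1), ``translation``
(e = |W| / |W ∩ W_shifted|, exact for rectangles) and ``toroidal``
(distances on the torus, e ≡ 1).  Under complete spatial randomness the
reference values are K = πr², g = 1, J = 1, R = 1, p_lm = p_l·p_m and
k_mm = 1.

Kernel sums are evaluated exactly (no binning) in O((n² + m) log n²) via
prefix sums of the kernel's polynomial moments over the sorted pairwise
distances, and match the naive O(n²·m) double loop to floating precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from scipy.stats import norm

from .imaging import ValidationError
from .pattern import MarkedPointPattern, intensity, split_by_mark
from .nullmodels import randomize_marks, simulate_csr_n

__all__ = [
    "SummaryFunctionEstimate",
    "ClarkEvansResult",
    "EnvelopeResult",
    "default_r_grid",
    "stoyan_bandwidth",
    "k_function",
    "cross_k_function",
    "pair_correlation",
    "j_function",
    "clark_evans_test",
    "mark_connection",
    "mark_connection_matrix",
    "mark_correlation",
    "envelope",
]

# Clark–Evans standard error constant: sqrt((4 - pi) / (4 pi))
CE_SE_CONST = 0.26136


@dataclass
class SummaryFunctionEstimate:
    """An estimated summary function on an r grid with its CSR reference."""

    statistic: str
    r: np.ndarray
    estimate: np.ndarray
    theoretical: np.ndarray
    correction: str = "none"
    bandwidth: float | None = None
    mark_pair: tuple[int, int] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"r": self.r, "estimate": self.estimate,
             "theoretical": self.theoretical}
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, ax=None, **kw):
        """Estimate vs the reference-model curve on the r grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lab = self.statistic
        if self.mark_pair is not None:
            lab += f"[{self.mark_pair[0]},{self.mark_pair[1]}]"
        ax.plot(self.r, self.estimate, label=f"{lab} estimate", **kw)
        ax.plot(self.r, self.theoretical, "k--", label="reference")
        ax.set_xlabel("r")
        ax.set_ylabel(lab)
        ax.legend()
        return ax


@dataclass
class ClarkEvansResult:
    """Clark–Evans nearest-neighbour test of complete spatial randomness.

    R < 1 indicates clustering, R > 1 regularity; under CSR the standardised
    mean nearest-neighbour distance is asymptotically normal.
    """

    n: int
    intensity: float
    mean_nn_distance: float
    expected_nn_distance: float
    R: float
    z: float
    p_value: float
    metric: str = "euclidean"

    def summary(self) -> str:
        return (
            f"Clark–Evans CSR test ({self.metric} metric)\n"
            f"  n = {self.n}, intensity = {self.intensity:.6g}\n"
            f"  mean NN distance = {self.mean_nn_distance:.6g} "
            f"(CSR expectation {self.expected_nn_distance:.6g})\n"
            f"  R = {self.R:.4f}, z = {self.z:.3f}, p = {self.p_value:.4g}"
        )


@dataclass
class EnvelopeResult:
    """Pointwise Monte Carlo envelope for a summary statistic."""

    statistic: str
    r: np.ndarray
    observed: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    null_model: str
    n_sim: int
    rank: int
    seed: int | None = None

    def fraction_inside(self) -> float:
        ok = np.isfinite(self.observed) & np.isfinite(self.lo) & np.isfinite(self.hi)
        inside = (self.observed[ok] >= self.lo[ok]) & (self.observed[ok] <= self.hi[ok])
        return float(inside.mean()) if ok.any() else float("nan")

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(self.r, self.lo, self.hi, alpha=0.3,
                        label=f"{self.null_model} envelope")
        ax.plot(self.r, self.observed, label=f"{self.statistic} observed")
        ax.set_xlabel("r")
        ax.set_ylabel(self.statistic)
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# pair machinery


def default_r_grid(pattern: MarkedPointPattern, n: int = 512,
                   include_zero: bool = True) -> np.ndarray:
    """Equispaced r values from 0 to a quarter of the shorter window side."""
    rmax = min(pattern.side_lengths) / 4.0
    r = np.linspace(0.0, rmax, n)
    return r if include_zero else r[1:]

def stoyan_bandwidth(pattern: MarkedPointPattern) -> float:
    """Stoyan's rule of thumb h = 0.15 / sqrt(λ̂)."""
    lam = intensity(pattern)
    if lam <= 0:
        raise ValidationError("bandwidth rule needs a non-empty pattern")
    return 0.15 / np.sqrt(lam)


def _pair_arrays(pattern: MarkedPointPattern, correction: str):
    """Condensed pairwise distances and edge-correction weights.

    Returns (d, e) for the n(n-1)/2 unordered pairs (u < v).  Summary sums
    over ordered pairs double these, which all estimators here exploit via
    kernel/indicator symmetry in d.
    """
    pts = pattern.coords()
    X, Y = pattern.side_lengths
    if correction == "toroidal":
        dx = np.abs(pts[:, None, 0] - pts[None, :, 0])
        dy = np.abs(pts[:, None, 1] - pts[None, :, 1])
        dx = np.minimum(dx, X - dx)
        dy = np.minimum(dy, Y - dy)
        iu = np.triu_indices(len(pts), k=1)
        d = np.hypot(dx[iu], dy[iu])
        e = np.ones_like(d)
    elif correction in ("none", "translation"):
        d = pdist(pts)
        if correction == "none":
            e = np.ones_like(d)
        else:
            ddx = pdist(pts[:, :1])  # |x_u - x_v|
            ddy = pdist(pts[:, 1:])  # |y_u - y_v|
            e = (X * Y) / ((X - ddx) * (Y - ddy))
    else:
        raise ValidationError(f"unknown edge correction {correction!r}")
    return d, e


def _cross_pair_arrays(pat_i: MarkedPointPattern, pat_j: MarkedPointPattern,
                       correction: str, window_sides):
    """Distances and weights for all ordered (u in i, v in j) pairs of two
    sub-patterns sharing a window; coincident points (u = v when i = j) must
    be excluded by the caller."""
    X, Y = window_sides
    dx = np.abs(pat_i.x[:, None] - pat_j.x[None, :])
    dy = np.abs(pat_i.y[:, None] - pat_j.y[None, :])
    if correction == "toroidal":
        dx = np.minimum(dx, X - dx)
        dy = np.minimum(dy, Y - dy)
        e = np.ones_like(dx)
    elif correction == "none":
        e = np.ones_like(dx)
    elif correction == "translation":
        e = (X * Y) / ((X - dx) * (Y - dy))
    else:
        raise ValidationError(f"unknown edge correction {correction!r}")
    return np.hypot(dx, dy), e


def _epanechnikov_sums(d: np.ndarray, weights: list[np.ndarray],
                       r: np.ndarray, h: float) -> list[np.ndarray]:
    """Exact Σ_pairs w · k_h(d - r) for each weight vector, every r.

    k_h(t) = 0.75/h (1 - t²/h²) on |t| ≤ h is quadratic in d, so the sum
    over the pairs inside [r-h, r+h] follows from prefix sums of w, w·d and
    w·d² on the distance-sorted pairs.
    """
    if h <= 0:
        raise ValidationError("bandwidth must be positive")
    order = np.argsort(d, kind="stable")
    ds = d[order]
    r = np.asarray(r, dtype=float)
    lo = np.searchsorted(ds, r - h, side="left")
    hi = np.searchsorted(ds, r + h, side="right")
    out = []
    for w in weights:
        ws = w[order]
        c0 = np.concatenate([[0.0], np.cumsum(ws)])
        c1 = np.concatenate([[0.0], np.cumsum(ws * ds)])
        c2 = np.concatenate([[0.0], np.cumsum(ws * ds * ds)])
        S0 = c0[hi] - c0[lo]
        S1 = c1[hi] - c1[lo]
        S2 = c2[hi] - c2[lo]
        val = (0.75 / h) * (
            (1.0 - r * r / h**2) * S0 + (2.0 * r / h**2) * S1 - S2 / h**2
        )
        out.append(np.maximum(val, 0.0))
    return out


def _check_rmax(pattern: MarkedPointPattern, r: np.ndarray) -> None:
    bound = min(pattern.side_lengths) / 2.0
    if r.max() > bound + 1e-12:
        raise ValidationError(
            f"r_max = {r.max():g} exceeds half the shorter window side "
            f"({bound:g})"
        )


# ---------------------------------------------------------------------------
# second-order statistics


def k_function(pattern: MarkedPointPattern, r=None,
               correction: str = "translation") -> SummaryFunctionEstimate:
    """Ripley's K: λK(r) is the expected number of further points within
    distance r of a typical point."""
    if pattern.n < 2:
        raise ValidationError("K-function needs at least 2 points")
    if r is None:
        r = default_r_grid(pattern)
    r = np.asarray(r, dtype=float)
    _check_rmax(pattern, r)
    d, e = _pair_arrays(pattern, correction)
    order = np.argsort(d, kind="stable")
    ds, es = d[order], e[order]
    csum = np.concatenate([[0.0], np.cumsum(es)])
    counts = 2.0 * csum[np.searchsorted(ds, r, side="right")]  # ordered pairs
    n = pattern.n
    est = pattern.area * counts / (n * (n - 1))
    return SummaryFunctionEstimate("K", r, est, np.pi * r**2, correction)


def cross_k_function(pattern: MarkedPointPattern, type_i: int, type_j: int,
                     r=None, correction: str = "translation"
                     ) -> SummaryFunctionEstimate:
    """Bivariate K: λ_i K_ij(r) is the expected number of type-j points
    within r of a typical type-i point.  For i = j this reduces to the
    ordinary K of the type-i sub-pattern."""
    subs = split_by_mark(pattern)
    for t in (type_i, type_j):
        if t not in subs:
            raise ValidationError(f"pattern has no points of type {t}")
    if r is None:
        r = default_r_grid(pattern)
    r = np.asarray(r, dtype=float)
    _check_rmax(pattern, r)
    if type_i == type_j:
        est = k_function(subs[type_i], r, correction)
        return SummaryFunctionEstimate(
            "K_ij", r, est.estimate, est.theoretical, correction,
            mark_pair=(type_i, type_j),
        )
    pi, pj = subs[type_i], subs[type_j]
    d, e = _cross_pair_arrays(pi, pj, correction, pattern.side_lengths)
    d, e = d.ravel(), e.ravel()
    order = np.argsort(d, kind="stable")
    csum = np.concatenate([[0.0], np.cumsum(e[order])])
    counts = csum[np.searchsorted(d[order], r, side="right")]
    est = pattern.area * counts / (pi.n * pj.n)
    return SummaryFunctionEstimate(
        "K_ij", r, est, np.pi * r**2, correction, mark_pair=(type_i, type_j)
    )


def pair_correlation(pattern: MarkedPointPattern, r=None,
                     bandwidth: float | None = None,
                     correction: str = "translation"
                     ) -> SummaryFunctionEstimate:
    """Kernel estimate of the pair correlation function g(r); g > 1 means
    clustering and g < 1 inhibition at scale r."""
    if pattern.n < 2:
        raise ValidationError("pair correlation needs at least 2 points")
    if r is None:
        r = default_r_grid(pattern, include_zero=False)
    r = np.asarray(r, dtype=float)
    if (r <= 0).any():
        warnings.warn("dropping r = 0 values (1/r singularity)", stacklevel=2)
        r = r[r > 0]
    _check_rmax(pattern, r)
    h = stoyan_bandwidth(pattern) if bandwidth is None else float(bandwidth)
    d, e = _pair_arrays(pattern, correction)
    (ksum,) = _epanechnikov_sums(d, [e], r, h)
    n = pattern.n
    est = pattern.area * 2.0 * ksum / (2.0 * np.pi * r * n * (n - 1))
    return SummaryFunctionEstimate(
        "g", r, est, np.ones_like(r), correction, bandwidth=h
    )


# ---------------------------------------------------------------------------
# nearest-neighbour / empty-space statistics


def _nn_distances(pattern: MarkedPointPattern, metric: str) -> np.ndarray:
    pts = pattern.coords()
    if metric == "toroidal":
        X, Y = pattern.side_lengths
        dx = np.abs(pts[:, None, 0] - pts[None, :, 0])
        dy = np.abs(pts[:, None, 1] - pts[None, :, 1])
        dx = np.minimum(dx, X - dx)
        dy = np.minimum(dy, Y - dy)
        dm = np.hypot(dx, dy)
    elif metric == "euclidean":
        dm = cdist(pts, pts)
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    np.fill_diagonal(dm, np.inf)
    return dm.min(axis=1)


def _boundary_distances(x, y, window) -> np.ndarray:
    x0, x1, y0, y1 = window
    return np.minimum.reduce([x - x0, x1 - x, y - y0, y1 - y])


def j_function(pattern: MarkedPointPattern, r=None,
               dummy_grid: int = 100) -> SummaryFunctionEstimate:
    """J(r) = (1 - G(r)) / (1 - F(r)): nearest-neighbour distribution G over
    empty-space function F.  J ≡ 1 under CSR; J > 1 signals inhibition and
    J < 1 clustering.

    G uses the Hanisch border-corrected estimator (monotone by
    construction); F uses the reduced-sample estimator on a regular
    dummy-point grid.  Values where F̂(r) = 1 are reported as NaN.
    """
    if pattern.n < 1:
        raise ValidationError("J-function needs at least 1 point")
    if r is None:
        r = default_r_grid(pattern)
    r = np.asarray(r, dtype=float)

    # G: Hanisch estimator from NN distances d_i and boundary distances b_i
    nn = _nn_distances(pattern, "euclidean")
    b = _boundary_distances(pattern.x, pattern.y, pattern.window)
    X, Y = pattern.side_lengths
    obs = nn <= b  # NN observed within the eroded window
    if obs.any():
        wts = 1.0 / ((X - 2 * nn[obs]) * (Y - 2 * nn[obs]))
        order = np.argsort(nn[obs], kind="stable")
        dsort, wsort = nn[obs][order], wts[order]
        cw = np.concatenate([[0.0], np.cumsum(wsort)])
        G = cw[np.searchsorted(dsort, r, side="right")] / cw[-1]
    else:
        G = np.zeros_like(r)

    # F: reduced-sample estimator on a dummy grid
    gx = (np.arange(dummy_grid) + 0.5) * X / dummy_grid + pattern.window[0]
    gy = (np.arange(dummy_grid) + 0.5) * Y / dummy_grid + pattern.window[2]
    GX, GY = np.meshgrid(gx, gy)
    dummies = np.column_stack([GX.ravel(), GY.ravel()])
    dmin = cdist(dummies, pattern.coords()).min(axis=1)
    bd = _boundary_distances(dummies[:, 0], dummies[:, 1], pattern.window)
    ge = bd[:, None] >= r  # dummy observable at range r
    denom = ge.sum(axis=0).astype(float)
    num = ((dmin[:, None] <= r) & ge).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(denom > 0, num / denom, np.nan)
        J = np.where(F < 1, (1.0 - G) / (1.0 - F), np.nan)
    return SummaryFunctionEstimate("J", r, J, np.ones_like(r), "border")


def clark_evans_test(pattern: MarkedPointPattern,
                     metric: str = "euclidean") -> ClarkEvansResult:
    """Clark–Evans test: the standardised mean nearest-neighbour distance is
    asymptotically normal under CSR, with expectation 1/(2√λ)."""
    if pattern.n < 2:
        raise ValidationError("Clark–Evans test needs at least 2 points")
    lam = intensity(pattern)
    d_obs = float(_nn_distances(pattern, metric).mean())
    d_exp = 1.0 / (2.0 * np.sqrt(lam))
    R = d_obs / d_exp
    se = CE_SE_CONST / np.sqrt(pattern.n * lam)
    z = (d_obs - d_exp) / se
    p = 2.0 * norm.sf(abs(z))
    return ClarkEvansResult(pattern.n, lam, d_obs, d_exp, R, float(z),
                            float(p), metric)


# ---------------------------------------------------------------------------
# mark statistics


def _marked_pair_data(pattern: MarkedPointPattern):
    if pattern.n < 2:
        raise ValidationError("mark statistics need at least 2 points")
    d = pdist(pattern.coords())
    iu, iv = np.triu_indices(pattern.n, k=1)
    return d, iu, iv


def mark_connection(pattern: MarkedPointPattern, l: int, m: int,
                    r=None, bandwidth: float | None = None
                    ) -> SummaryFunctionEstimate:
    """Mark connection function p_lm(r): the conditional probability that an
    ordered pair of points a distance r apart carries marks (l, m).  Equals
    p_l·p_m under independent marking."""
    if pattern.marks is None:
        raise ValidationError("mark connection needs categorical marks")
    levels = set(int(v) for v in pattern.mark_levels())
    for t in (l, m):
        if int(t) not in levels:
            raise ValidationError(f"unknown mark value {t}")
    if r is None:
        r = default_r_grid(pattern, include_zero=False)
    r = np.asarray(r, dtype=float)
    h = stoyan_bandwidth(pattern) if bandwidth is None else float(bandwidth)
    d, iu, iv = _marked_pair_data(pattern)
    mk = pattern.marks
    # ordered-pair indicator folded onto unordered pairs
    w_num = ((mk[iu] == l) & (mk[iv] == m)).astype(float) + (
        (mk[iv] == l) & (mk[iu] == m)
    ).astype(float)
    w_den = np.full_like(d, 2.0)
    num, den = _epanechnikov_sums(d, [w_num, w_den], r, h)
    with np.errstate(invalid="ignore", divide="ignore"):
        est = np.where(den > 0, num / den, np.nan)
    from .pattern import mark_probabilities

    p = mark_probabilities(pattern)
    theo = np.full_like(r, p.get(int(l), 0.0) * p.get(int(m), 0.0))
    return SummaryFunctionEstimate(
        "p_lm", r, est, theo, "none", bandwidth=h, mark_pair=(int(l), int(m))
    )


def mark_connection_matrix(pattern: MarkedPointPattern, r=None,
                           bandwidth: float | None = None) -> dict:
    """All ordered mark pairs (l, m) → p̂_lm; the entries sum to 1 at every
    r where the pair-density denominator is positive."""
    out = {}
    levels = [int(v) for v in pattern.mark_levels()]
    for l in levels:
        for m in levels:
            out[(l, m)] = mark_connection(pattern, l, m, r, bandwidth)
    return out


def mark_correlation(pattern: MarkedPointPattern, r=None,
                     bandwidth: float | None = None
                     ) -> SummaryFunctionEstimate:
    """Mark correlation function k_mm(r): the mean product of the numeric
    marks over point pairs at distance r, normalised by the mean product
    over all distinct pairs.  1 under mark independence; > 1 mutual
    stimulation, < 1 mutual inhibition."""
    if pattern.values is None:
        raise ValidationError("mark correlation needs a numeric mark channel")
    if r is None:
        r = default_r_grid(pattern, include_zero=False)
    r = np.asarray(r, dtype=float)
    h = stoyan_bandwidth(pattern) if bandwidth is None else float(bandwidth)
    d, iu, iv = _marked_pair_data(pattern)
    v = pattern.values
    prod = v[iu] * v[iv]
    norm_c = prod.mean()  # mean of m_u m_v over all distinct pairs
    if abs(norm_c) < 1e-300:
        raise ValidationError(
            "mean pair mark product is zero; k_mm normalisation undefined"
        )
    num, den = _epanechnikov_sums(d, [prod, np.ones_like(d)], r, h)
    with np.errstate(invalid="ignore", divide="ignore"):
        est = np.where(den > 0, (num / den) / norm_c, np.nan)
    return SummaryFunctionEstimate("k_mm", r, est, np.ones_like(r), "none",
                                   bandwidth=h)


# ---------------------------------------------------------------------------
# Monte Carlo envelopes

_STAT_BUILDERS = {
    "K": lambda pat, kw: k_function(pat, kw.get("r"),
                                    kw.get("correction", "translation")),
    "g": lambda pat, kw: pair_correlation(pat, kw.get("r"),
                                          kw.get("bandwidth"),
                                          kw.get("correction", "translation")),
    "J": lambda pat, kw: j_function(pat, kw.get("r"),
                                    kw.get("dummy_grid", 100)),
    "K_ij": lambda pat, kw: cross_k_function(pat, kw["type_i"], kw["type_j"],
                                             kw.get("r"),
                                             kw.get("correction",
                                                    "translation")),
    "p_lm": lambda pat, kw: mark_connection(pat, kw["l"], kw["m"],
                                            kw.get("r"), kw.get("bandwidth")),
    "k_mm": lambda pat, kw: mark_correlation(pat, kw.get("r"),
                                             kw.get("bandwidth")),
}

_NEEDS_MARKS = {"K_ij", "p_lm", "k_mm"}


def envelope(pattern: MarkedPointPattern, statistic, null_model: str = "CSR",
             n_sim: int = 199, rank: int = 5, seed=None,
             **stat_kwargs) -> EnvelopeResult:
    """Pointwise Monte Carlo envelope: the rank-th smallest/largest values of
    the statistic over n_sim simulations of the null model.

    ``CSR`` simulates uniform patterns conditioned on the observed n (marks
    discarded); ``random_labeling`` permutes marks holding locations fixed.
    ``statistic`` is a name from {K, g, J, K_ij, p_lm, k_mm} or a callable
    pattern → SummaryFunctionEstimate.
    """
    if n_sim < 2 * rank:
        raise ValidationError("need n_sim >= 2·rank for the requested rank")
    if callable(statistic):
        build = lambda pat: statistic(pat)
        name = getattr(statistic, "__name__", "custom")
    else:
        if statistic not in _STAT_BUILDERS:
            raise ValidationError(f"unknown statistic {statistic!r}")
        if null_model == "CSR" and statistic in _NEEDS_MARKS:
            raise ValidationError(
                f"{statistic} needs marks, which the CSR null does not carry; "
                "use null_model='random_labeling'"
            )
        build = lambda pat: _STAT_BUILDERS[statistic](pat, stat_kwargs)
        name = statistic
    obs = build(pattern)
    if "r" not in stat_kwargs and not callable(statistic):
        stat_kwargs = dict(stat_kwargs, r=obs.r)
        build = lambda pat: _STAT_BUILDERS[statistic](pat, stat_kwargs)
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sim, len(obs.r)))
    for s in range(n_sim):
        if null_model == "CSR":
            sim_pat = simulate_csr_n(pattern.n, pattern.window, rng)
        elif null_model == "random_labeling":
            sim_pat = randomize_marks(pattern, "permute", seed=rng)
        else:
            raise ValidationError(f"unknown null model {null_model!r}")
        sims[s] = build(sim_pat).estimate
    sims_sorted = np.sort(sims, axis=0)
    lo = sims_sorted[rank - 1]
    hi = sims_sorted[n_sim - rank]
    return EnvelopeResult(name, obs.r, obs.estimate, lo, hi, null_model,
                          n_sim, rank, seed if isinstance(seed, int) else None)
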