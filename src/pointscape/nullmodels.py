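"""Seeded simulators for reference point processes.

Homogeneous Poisson (complete spatial randomness, CSR), the Matérn cluster
process (attraction), simple sequential inhibition (repulsion), and mark
randomisation (the null for mark statistics).  All simulators accept a seed
or a numpy Generator and are fully deterministic given one.

Matérn parents are simulated on the window dilated by the cluster radius so
the offspring process is stationary inside the analysis window; the expected
retained offspring count is κ·μ·|W|.
"""

from __future__ import annotations

import warnings

import numpy as np

from .imaging import ValidationError
from .pattern import MarkedPointPattern

__all__ = [
    "simulate_poisson",
    "simulate_csr_n",
    "simulate_matern_cluster",
    "simulate_ssi",
    "randomize_marks",
]

Window = tuple[float, float, float, float]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _uniform_points(n: int, window: Window, rng) -> tuple[np.ndarray, np.ndarray]:
    x0, x1, y0, y1 = window
    return rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)


def simulate_poisson(lam: float, window: Window = (0, 1, 0, 1),
                     seed=None) -> MarkedPointPattern:
    """Homogeneous Poisson process: N ~ Poisson(λ·|W|), locations uniform."""
    if lam < 0:
        raise ValidationError("intensity must be >= 0")
    rng = _rng(seed)
    x0, x1, y0, y1 = window
    area = (x1 - x0) * (y1 - y0)
    n = int(rng.poisson(lam * area))
    x, y = _uniform_points(n, window, rng)
    return MarkedPointPattern(x, y, window)


def simulate_csr_n(n: int, window: Window = (0, 1, 0, 1),
                   seed=None) -> MarkedPointPattern:
    """CSR conditioned on the point count: exactly n uniform points."""
    if n < 0:
        raise ValidationError("n must be >= 0")
    rng = _rng(seed)
    x, y = _uniform_points(int(n), window, rng)
    return MarkedPointPattern(x, y, window)


def simulate_matern_cluster(kappa: float, mu: float, rho: float,
                            window: Window = (0, 1, 0, 1),
                            seed=None) -> MarkedPointPattern:
    """Matérn cluster process: Poisson(κ) parents on the ρ-dilated window,
    each with Poisson(μ) offspring uniform in its radius-ρ disc; offspring
    falling outside the window are clipped."""
    if kappa < 0 or mu < 0 or rho < 0:
        raise ValidationError("κ, μ, ρ must all be >= 0")
    rng = _rng(seed)
    x0, x1, y0, y1 = window
    dil = (x0 - rho, x1 + rho, y0 - rho, y1 + rho)
    dil_area = (dil[1] - dil[0]) * (dil[3] - dil[2])
    n_par = int(rng.poisson(kappa * dil_area))
    px = rng.uniform(dil[0], dil[1], n_par)
    py = rng.uniform(dil[2], dil[3], n_par)
    n_off = rng.poisson(mu, n_par)
    total = int(n_off.sum())
    # uniform in a disc of radius rho around each parent
    theta = rng.uniform(0, 2 * np.pi, total)
    rad = rho * np.sqrt(rng.uniform(0, 1, total))
    cx = np.repeat(px, n_off) + rad * np.cos(theta)
    cy = np.repeat(py, n_off) + rad * np.sin(theta)
    keep = (cx >= x0) & (cx < x1) & (cy >= y0) & (cy < y1)
    return MarkedPointPattern(cx[keep], cy[keep], window)


def simulate_ssi(n: int, delta: float, window: Window = (0, 1, 0, 1),
                 seed=None, max_attempts: int = 10000) -> MarkedPointPattern:
    """Simple sequential inhibition: uniform proposals accepted iff at least
    δ away from every accepted point; stops at n points or max_attempts.

    Infeasible packings return the partial pattern with a warning.
    """
    if n < 0 or delta < 0:
        raise ValidationError("n and δ must be >= 0")
    rng = _rng(seed)
    xs: list[float] = []
    ys: list[float] = []
    attempts = 0
    while len(xs) < n and attempts < max_attempts:
        attempts += 1
        px, py = _uniform_points(1, window, rng)
        px, py = float(px[0]), float(py[0])
        if xs and delta > 0:
            d2 = (np.asarray(xs) - px) ** 2 + (np.asarray(ys) - py) ** 2
            if d2.min() < delta**2:
                continue
        xs.append(px)
        ys.append(py)
    if len(xs) < n:
        warnings.warn(
            f"SSI achieved only {len(xs)}/{n} points in {max_attempts} attempts",
            stacklevel=2,
        )
    return MarkedPointPattern(np.asarray(xs), np.asarray(ys), window)


def randomize_marks(pattern: MarkedPointPattern, mode: str = "permute",
                    p: dict | np.ndarray | None = None,
                    seed=None) -> MarkedPointPattern:
    """Random-labelling null: coordinates fixed, marks randomised.

    ``permute`` shuffles the existing marks (mark multiset preserved
    exactly); ``iid`` draws marks independently from probabilities ``p``.
    """
    rng = _rng(seed)
    if mode == "permute":
        if pattern.marks is None:
            raise ValidationError("permute mode needs an already-marked pattern")
        perm = rng.permutation(pattern.n)
        return pattern.with_marks(
            pattern.marks[perm],
            None if pattern.values is None else pattern.values[perm],
        )
    if mode == "iid":
        if p is None:
            raise ValidationError("iid mode needs mark probabilities p")
        if isinstance(p, dict):
            levels = np.asarray(sorted(p), dtype=int)
            probs = np.asarray([p[k] for k in sorted(p)], dtype=float)
        else:
            probs = np.asarray(p, dtype=float)
            levels = np.arange(len(probs))
        if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValidationError("mark probabilities must be >= 0 and sum to 1")
        marks = rng.choice(levels, size=pattern.n, p=probs)
        return pattern.with_marks(marks, pattern.values)
    raise ValidationError(f"unknown mark-randomisation mode {mode!r}")
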