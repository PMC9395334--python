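"""Marked point patterns in a rectangular window.

A classified patch grid becomes a marked point pattern by replacing each
patch with a point at its centre carrying the class label as a qualitative
mark; the full pattern is the superposition of the per-class sub-patterns.
An optional numeric mark channel supports quantitatively marked statistics
(the mark correlation function).

Patterns built from a grid are perfectly lattice-arranged, so summary
statistics on them show strong regularity at the patch scale w (a step in K
at r = w, Clark–Evans R near 2).  That is inherent to the construction, not
a bug; interpret summary functions at r > w.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import ValidationError, patch_center

__all__ = [
    "MarkedPointPattern",
    "pattern_from_labels",
    "split_by_mark",
    "intensity",
    "per_type_intensity",
    "mark_probabilities",
    "read_pattern_csv",
    "write_pattern_csv",
]


@dataclass(frozen=True)
class MarkedPointPattern:
    """Points in the half-open window [0, X) × [0, Y) with optional marks.

    ``marks`` are categorical integer labels (or None for an unmarked
    pattern); ``values`` is an optional numeric mark per point.
    """

    x: np.ndarray
    y: np.ndarray
    window: tuple[float, float, float, float] = (0.0, 1.0, 0.0, 1.0)  # x0,x1,y0,y1
    marks: np.ndarray | None = None
    values: np.ndarray | None = None

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float).ravel()
        y = np.asarray(self.y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValidationError("x and y must have equal length")
        x0, x1, y0, y1 = (float(v) for v in self.window)
        if x1 <= x0 or y1 <= y0:
            raise ValidationError("window must have positive extent")
        if len(x) and (
            (x < x0).any() or (x >= x1).any() or (y < y0).any() or (y >= y1).any()
        ):
            raise ValidationError("points must lie inside the window")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "window", (x0, x1, y0, y1))
        if self.marks is not None:
            m = np.asarray(self.marks).ravel().astype(int)
            if m.shape != x.shape:
                raise ValidationError("marks must match point count")
            object.__setattr__(self, "marks", m)
        if self.values is not None:
            v = np.asarray(self.values, dtype=float).ravel()
            if v.shape != x.shape:
                raise ValidationError("values must match point count")
            object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def area(self) -> float:
        x0, x1, y0, y1 = self.window
        return (x1 - x0) * (y1 - y0)

    @property
    def side_lengths(self) -> tuple[float, float]:
        x0, x1, y0, y1 = self.window
        return (x1 - x0, y1 - y0)

    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def mark_levels(self) -> np.ndarray:
        if self.marks is None:
            return np.array([], dtype=int)
        return np.unique(self.marks)

    def with_marks(self, marks=None, values=None) -> "MarkedPointPattern":
        return MarkedPointPattern(self.x, self.y, self.window, marks, values)


def pattern_from_labels(
    label_grid: np.ndarray,
    w: int,
    include_classes=None,
) -> MarkedPointPattern:
    """One point per included grid cell at the patch centre, mark = label.

    The window is (0, n_cols·w) × (0, n_rows·w).  ``include_classes`` limits
    the pattern to a subset of labels; an empty selection yields a valid
    empty pattern with a warning.
    """
    label_grid = np.asarray(label_grid, dtype=int)
    if label_grid.ndim != 2:
        raise ValidationError("label grid must be 2-D")
    nr, nc = label_grid.shape
    ii, jj = np.mgrid[0:nr, 0:nc]
    lab = label_grid.ravel()
    x = jj.ravel() * w + w / 2.0
    y = ii.ravel() * w + w / 2.0
    if include_classes is not None:
        keep = np.isin(lab, list(include_classes))
        x, y, lab = x[keep], y[keep], lab[keep]
        if len(x) == 0:
            warnings.warn("class selection produced an empty pattern",
                          stacklevel=2)
    return MarkedPointPattern(
        x, y, (0.0, nc * float(w), 0.0, nr * float(w)), marks=lab
    )


def split_by_mark(pattern: MarkedPointPattern) -> dict[int, MarkedPointPattern]:
    """Decompose a marked pattern into per-mark sub-patterns (same window)."""
    if pattern.marks is None or pattern.n == 0:
        return {}
    out = {}
    for m in pattern.mark_levels():
        sel = pattern.marks == m
        out[int(m)] = MarkedPointPattern(
            pattern.x[sel],
            pattern.y[sel],
            pattern.window,
            marks=pattern.marks[sel],
            values=None if pattern.values is None else pattern.values[sel],
        )
    return out


def intensity(pattern: MarkedPointPattern) -> float:
    """Points per unit area, λ = n / |W|."""
    if pattern.area <= 0:
        raise ValidationError("window area must be positive")
    return pattern.n / pattern.area


def per_type_intensity(pattern: MarkedPointPattern) -> dict[int, float]:
    """Per-type intensity λ_i = n_i / |W| for each mark level."""
    if pattern.area <= 0:
        raise ValidationError("window area must be positive")
    return {m: sub.n / pattern.area for m, sub in split_by_mark(pattern).items()}


def mark_probabilities(pattern: MarkedPointPattern) -> dict[int, float]:
    """Empirical mark distribution p_l = n_l / n."""
    if pattern.n == 0:
        raise ValidationError("mark probabilities undefined for empty pattern")
    if pattern.marks is None:
        raise ValidationError("pattern has no marks")
    levels, counts = np.unique(pattern.marks, return_counts=True)
    return {int(l): c / pattern.n for l, c in zip(levels, counts)}


def labels_from_pattern(pattern: MarkedPointPattern, w: int) -> np.ndarray:
    """Invert pattern_from_labels: regroup points by (floor(x/w), floor(y/w)).

    Cells with no point get label -1.
    """
    x0, x1, y0, y1 = pattern.window
    nc = int(round((x1 - x0) / w))
    nr = int(round((y1 - y0) / w))
    grid = np.full((nr, nc), -1, dtype=int)
    jj = np.floor((pattern.x - x0) / w).astype(int)
    ii = np.floor((pattern.y - y0) / w).astype(int)
    grid[ii, jj] = pattern.marks
    return grid


def write_pattern_csv(pattern: MarkedPointPattern, path: str) -> None:
    """CSV with header x,y[,mark][,value] and a `# window x0 x1 y0 y1` comment."""
    cols = {"x": pattern.x, "y": pattern.y}
    if pattern.marks is not None:
        cols["mark"] = pattern.marks
    if pattern.values is not None:
        cols["value"] = pattern.values
    df = pd.DataFrame(cols)
    x0, x1, y0, y1 = pattern.window
    with open(path, "w") as fh:
        fh.write(f"# window {x0!r} {x1!r} {y0!r} {y1!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_pattern_csv(path: str) -> MarkedPointPattern:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# window"):
            raise ValidationError("pattern CSV must start with a window comment")
        parts = first.split()[2:]
        window = tuple(float(p) for p in parts)
        df = pd.read_csv(fh, float_precision="round_trip")
    return MarkedPointPattern(
        df["x"].to_numpy(),
        df["y"].to_numpy(),
        window,
        marks=df["mark"].to_numpy() if "mark" in df else None,
        values=df["value"].to_numpy() if "value" in df else None,
    )
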