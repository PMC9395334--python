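"""Temporal label propagation and leak-free dataset splitting.

Co-registered scenes of the same area acquired at different times show the
same landscape under different sensing conditions.  A patch labeled on the
reference scene therefore labels the co-registered patch of every replicate
for free: ``propagate_labels`` turns n labeled cells and k replicates into
n·(k+1) labeled patches.  ``pseudo_label_expand`` extends the set further by
letting a trained classifier label the patches of additional scenes.

Because the (k+1) temporal copies of one grid cell are near-identical,
train/test splits are assigned per grid cell, never per patch — otherwise
copies of the same cell land on both sides of the split and test accuracy is
trivially inflated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import StateError, TrainedClassifier
from .imaging import (
    LabeledPatchSet,
    UNLABELED,
    ValidationError,
    extract_patch_grid,
    labeled_set_from_grid,
)
from .synthetic import SceneSeries

__all__ = [
    "SplitSpec",
    "propagate_labels",
    "pseudo_label_expand",
    "split_dataset",
]


@dataclass
class SplitSpec:
    """Train/test/validation fractions, assigned at the grid-cell level."""

    fractions: tuple = (0.7, 0.2, 0.1)
    unit: str = "grid-cell"
    seed: int = 0

    def __post_init__(self):
        f = tuple(float(v) for v in self.fractions)
        if len(f) != 3 or any(not (0 < v < 1) for v in f):
            raise ValidationError("three fractions in (0, 1) required")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValidationError("fractions must sum to 1")
        if self.unit not in ("grid-cell", "patch"):
            raise ValidationError("unit must be 'grid-cell' or 'patch'")
        self.fractions = f


def _largest_remainder_sizes(n: int, fractions) -> list[int]:
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(v)) for v in raw]
    short = n - sum(sizes)
    rema = sorted(
        range(len(fractions)), key=lambda i: (-(raw[i] - sizes[i]), i)
    )
    for i in rema[:short]:
        sizes[i] += 1
    return sizes


def _cell_assignment(cells: list[tuple], split: SplitSpec) -> dict:
    rng = np.random.default_rng(split.seed)
    cells = sorted(cells)
    order = rng.permutation(len(cells))
    sizes = _largest_remainder_sizes(len(cells), split.fractions)
    names = ["train", "test", "validation"]
    for nm, sz in zip(names, sizes):
        if sz == 0:
            warnings.warn(f"split '{nm}' is empty at n={len(cells)}",
                          stacklevel=3)
    assign = {}
    pos = 0
    for nm, sz in zip(names, sizes):
        for k in order[pos : pos + sz]:
            assign[cells[k]] = nm
        pos += sz
    return assign


def propagate_labels(series: SceneSeries, reference_labels: LabeledPatchSet,
                     split: SplitSpec | None = None) -> LabeledPatchSet:
    """Assign each labeled reference cell's class to the co-registered patch
    of every scene in the series.

    The output holds one patch per (scene, labeled cell): n_labeled·(k+1)
    patches, with provenance "propagated" for replicate copies.  When a
    ``split`` is given, each grid cell receives one split assignment shared
    by all its temporal copies.  Idempotent: re-running on its own output
    adds nothing and changes no label.
    """
    w = series.patch_size
    nr, nc = series.class_map.shape
    ref_id = series.reference.scene_id
    meta = reference_labels.meta
    ref_rows = meta[meta["scene_id"] == ref_id]
    if len(ref_rows) == 0:
        # accept label sets not carrying the reference scene_id, as long as
        # the per-cell labeling is unambiguous
        ref_rows = meta.drop_duplicates(subset=["i", "j"])
        chk = meta.groupby(["i", "j"])["label"].nunique()
        if (chk > 1).any():
            raise ValidationError("inconsistent labels across scenes for a cell")
    ref_rows = ref_rows[ref_rows["label"] != UNLABELED]
    if ((ref_rows["i"] >= nr) | (ref_rows["j"] >= nc)).any():
        raise ValidationError(
            "reference labels index outside the series' patch grid"
        )
    cell_label = {
        (int(r.i), int(r.j)): int(r.label) for r in ref_rows.itertuples()
    }
    cells = sorted(cell_label)
    assign = _cell_assignment(cells, split) if split is not None else None

    patches_out = []
    rows = []
    for scene in series.scenes:
        grid = extract_patch_grid(scene, w)
        for (i, j) in cells:
            patches_out.append(grid.patches[i, j])
            rows.append(
                {
                    "scene_id": scene.scene_id,
                    "i": i,
                    "j": j,
                    "x": j * w + w / 2.0,
                    "y": i * w + w / 2.0,
                    "label": cell_label[(i, j)],
                    "provenance": "manual" if scene.scene_id == ref_id
                    else "propagated",
                }
            )
            if assign is not None:
                rows[-1]["split"] = assign[(i, j)]
    return LabeledPatchSet(
        np.stack(patches_out), pd.DataFrame(rows), reference_labels.n_classes
    )


def pseudo_label_expand(classifier: TrainedClassifier, scenes, w: int,
                        min_confidence: float | None = None) -> LabeledPatchSet:
    """Label every patch of the given scenes with the classifier's argmax
    class; patches whose top probability falls below ``min_confidence`` are
    dropped.  Output provenance is "pseudo"."""
    if not getattr(classifier, "trained", False):
        raise StateError("classifier is not trained")
    patches_out, rows = [], []
    for scene in scenes:
        grid = extract_patch_grid(scene, w)
        flat = grid.patches.reshape(-1, w, w, grid.patches.shape[-1])
        labels, probs = classifier.classify(flat)
        top = probs.max(axis=1)
        keep = np.ones(len(flat), dtype=bool)
        if min_confidence is not None:
            keep = top >= min_confidence
        ii, jj = np.mgrid[0 : grid.n_rows, 0 : grid.n_cols]
        ii, jj = ii.ravel(), jj.ravel()
        for k in np.flatnonzero(keep):
            patches_out.append(flat[k])
            rows.append(
                {
                    "scene_id": scene.scene_id,
                    "i": int(ii[k]),
                    "j": int(jj[k]),
                    "x": jj[k] * w + w / 2.0,
                    "y": ii[k] * w + w / 2.0,
                    "label": int(labels[k]),
                    "provenance": "pseudo",
                    "confidence": float(top[k]),
                }
            )
    n_classes = classifier.spec.n_classes
    if not rows:
        meta = pd.DataFrame(
            columns=["scene_id", "i", "j", "x", "y", "label", "provenance",
                     "confidence"]
        )
        empty = np.empty((0, w, w, scenes[0].channels)) if scenes else \
            np.empty((0, w, w, 1))
        return LabeledPatchSet(empty, meta, n_classes)
    return LabeledPatchSet(np.stack(patches_out), pd.DataFrame(rows), n_classes)


def split_dataset(patches: LabeledPatchSet, split: SplitSpec):
    """Partition into (train, test, validation) so that all temporal copies
    of one grid cell share a split; seeded and reproducible."""
    if len(patches) == 0:
        raise ValidationError("cannot split an empty patch set")
    if split.unit == "grid-cell":
        cells = sorted(
            set(zip(patches.meta["i"].astype(int), patches.meta["j"].astype(int)))
        )
        assign = _cell_assignment(cells, split)
        lab = np.array(
            [assign[(int(i), int(j))]
             for i, j in zip(patches.meta["i"], patches.meta["j"])]
        )
    else:  # per-patch; leaks temporal copies across splits, use with care
        assign = _cell_assignment(list(range(len(patches))), split)
        lab = np.array([assign[k] for k in range(len(patches))])
    out = []
    for nm in ("train", "test", "validation"):
        sub = patches.subset(lab == nm)
        sub.meta = sub.meta.assign(split=nm)
        out.append(sub)
    return tuple(out)
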