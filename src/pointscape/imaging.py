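"""Raster scenes and fixed-size patch grids.

A scene is an H×W×C array of finite intensities in a pixel-unit Cartesian
frame: origin at the raster's top-left corner, x along columns, y along rows
(y increases downward), windows half-open [0, X) × [0, Y).  Scenes are tiled
into non-overlapping w×w patches; trailing rows/columns that do not fill a
full patch are dropped, so every patch has identical shape and the grid is
regular.  The centre of grid cell (i, j) is the point

    x = j*w + w/2,    y = i*w + w/2,

the centroid of the patch's pixel-index footprint under the half-open
convention.  These centres are what downstream modules turn into marked
point patterns.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RasterScene",
    "PatchGrid",
    "LabeledPatchSet",
    "load_scene",
    "save_scene_npz",
    "extract_patch_grid",
    "patch_center",
]

UNLABELED = -1


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class RasterScene:
    """One H×W×C raster with pixel-unit geometry and a time identifier."""

    pixels: np.ndarray
    scene_id: str = "scene"
    time_index: int = 0

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3:
            raise ValidationError(
                f"scene pixels must be H×W or H×W×C, got ndim={px.ndim}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1 or px.shape[2] < 1:
            raise ValidationError(f"scene dims must be positive, got {px.shape}")
        bad = ~np.isfinite(px)
        if bad.any():
            idx = tuple(int(k) for k in np.argwhere(bad)[0])
            raise ValidationError(f"non-finite pixel value at index {idx}")
        if self.time_index < 0:
            raise ValidationError("time_index must be >= 0")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return self.pixels.shape[2]

    def replace(self, **kw) -> "RasterScene":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class PatchGrid:
    """Regular tiling of a scene into disjoint w×w patches.

    ``patches`` has shape (n_rows, n_cols, w, w, C); cell (i, j) covers pixel
    rows [i*w, (i+1)*w) and columns [j*w, (j+1)*w) of the source scene.
    """

    scene_id: str
    patch_size: int
    patches: np.ndarray  # (n_rows, n_cols, w, w, C)

    @property
    def n_rows(self) -> int:
        return self.patches.shape[0]

    @property
    def n_cols(self) -> int:
        return self.patches.shape[1]

    @property
    def n_patches(self) -> int:
        return self.n_rows * self.n_cols

    def centers(self) -> np.ndarray:
        """(n_rows*n_cols, 2) array of (x, y) patch centres, row-major."""
        ii, jj = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
        xy = np.stack(
            [
                jj.ravel() * self.patch_size + self.patch_size / 2.0,
                ii.ravel() * self.patch_size + self.patch_size / 2.0,
            ],
            axis=1,
        )
        return xy

    def window(self) -> tuple[float, float]:
        """(X, Y) extent of the cropped scene covered by full patches."""
        return (
            float(self.n_cols * self.patch_size),
            float(self.n_rows * self.patch_size),
        )


@dataclass
class LabeledPatchSet:
    """Patches with class labels and provenance bookkeeping.

    ``patches``: (N, w, w, C) float array.
    ``meta``: DataFrame with columns scene_id, i, j, x, y, label, provenance
    (one of {"manual", "propagated", "pseudo"}) and optionally split.
    Label -1 means unlabeled.
    """

    patches: np.ndarray
    meta: pd.DataFrame
    n_classes: int

    def __post_init__(self):
        self.patches = np.asarray(self.patches, dtype=float)
        if len(self.patches) != len(self.meta):
            raise ValidationError("patches and meta length mismatch")
        lab = self.meta["label"].to_numpy()
        if ((lab >= self.n_classes) | ((lab < 0) & (lab != UNLABELED))).any():
            raise ValidationError("label out of range")
        key = self.meta[["scene_id", "i", "j"]]
        if key.duplicated().any():
            raise ValidationError("(scene_id, i, j) keys must be unique")

    def __len__(self) -> int:
        return len(self.meta)

    @property
    def labels(self) -> np.ndarray:
        return self.meta["label"].to_numpy().astype(int)

    def subset(self, mask) -> "LabeledPatchSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return LabeledPatchSet(
            self.patches[idx],
            self.meta.iloc[idx].reset_index(drop=True),
            self.n_classes,
        )

    def save(self, npz_path: str, csv_path: str | None = None) -> None:
        np.savez_compressed(npz_path, patches=self.patches,
                            n_classes=self.n_classes)
        if csv_path is None:
            csv_path = os.path.splitext(npz_path)[0] + ".csv"
        self.meta.to_csv(csv_path, index=False)

    @classmethod
    def load(cls, npz_path: str, csv_path: str | None = None) -> "LabeledPatchSet":
        if csv_path is None:
            csv_path = os.path.splitext(npz_path)[0] + ".csv"
        with np.load(npz_path) as z:
            patches = z["patches"]
            n_classes = int(z["n_classes"])
        meta = pd.read_csv(csv_path)
        return cls(patches, meta, n_classes)


def load_scene(path: str, format: str | None = None, *, scene_id: str | None = None,
               time_index: int = 0) -> RasterScene:
    """Read a raster scene from GeoTIFF/TIFF, PNG, or NPZ.

    Grayscale rasters are promoted to C=1; intensities are cast to float.
    For multi-band TIFFs the first bands are taken as channels.
    """
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    if format is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        format = {"tif": "geotiff", "tiff": "geotiff", "png": "png",
                  "npz": "npz", "npy": "npz"}.get(ext, ext)
    if format == "geotiff":
        import tifffile

        arr = tifffile.imread(path)
    elif format == "png":
        from PIL import Image

        arr = np.asarray(Image.open(path))
    elif format == "npz":
        if path.endswith(".npy"):
            arr = np.load(path)
        else:
            with np.load(path) as z:
                key = "pixels" if "pixels" in z else z.files[0]
                arr = z[key]
    else:
        raise ValidationError(f"unknown format {format!r}")
    arr = np.asarray(arr)
    if arr.ndim not in (2, 3):
        raise ValidationError(
            f"raster must be H×W or H×W×C, got shape {arr.shape}"
        )
    if scene_id is None:
        scene_id = os.path.splitext(os.path.basename(path))[0]
    return RasterScene(arr.astype(float), scene_id=scene_id, time_index=time_index)


def save_scene_npz(scene: RasterScene, path: str) -> None:
    """Write a scene to NPZ; reloading reproduces pixels bit-exactly."""
    np.savez_compressed(path, pixels=scene.pixels,
                        time_index=scene.time_index)


def extract_patch_grid(scene: RasterScene, w: int) -> PatchGrid:
    """Tile a scene into floor(H/w)·floor(W/w) disjoint w×w patches."""
    if w < 1:
        raise ValidationError("patch size must be a positive integer")
    H, W = scene.height, scene.width
    if w > min(H, W):
        raise ValidationError(
            f"patch size {w} exceeds min scene dimension {min(H, W)}"
        )
    n_rows, n_cols = H // w, W // w
    crop = scene.pixels[: n_rows * w, : n_cols * w, :]
    C = scene.channels
    patches = (
        crop.reshape(n_rows, w, n_cols, w, C).transpose(0, 2, 1, 3, 4).copy()
    )
    return PatchGrid(scene_id=scene.scene_id, patch_size=w, patches=patches)


def patch_center(cell: tuple[int, int], w: int) -> tuple[float, float]:
    """Centre point (x, y) of grid cell (i, j) for patch size w."""
    i, j = cell
    if i < 0 or j < 0:
        raise ValidationError(f"grid indices must be non-negative, got {cell}")
    if w < 1:
        raise ValidationError("patch size must be a positive integer")
    return (j * w + w / 2.0, i * w + w / 2.0)


def labeled_set_from_grid(
    grid: PatchGrid,
    labels: np.ndarray | None = None,
    n_classes: int | None = None,
    provenance: str = "manual",
) -> LabeledPatchSet:
    """Flatten a PatchGrid into a LabeledPatchSet (row-major cell order).

    ``labels`` is an (n_rows, n_cols) integer grid or None (all unlabeled).
    """
    nr, nc, w = grid.n_rows, grid.n_cols, grid.patch_size
    if labels is None:
        lab = np.full(nr * nc, UNLABELED, dtype=int)
        if n_classes is None:
            raise ValidationError("n_classes required when labels is None")
    else:
        labels = np.asarray(labels, dtype=int)
        if labels.shape != (nr, nc):
            raise ValidationError(
                f"label grid shape {labels.shape} != grid dims {(nr, nc)}"
            )
        lab = labels.ravel()
        if n_classes is None:
            n_classes = int(lab.max()) + 1
    ii, jj = np.mgrid[0:nr, 0:nc]
    meta = pd.DataFrame(
        {
            "scene_id": grid.scene_id,
            "i": ii.ravel(),
            "j": jj.ravel(),
            "x": jj.ravel() * w + w / 2.0,
            "y": ii.ravel() * w + w / 2.0,
            "label": lab,
            "provenance": provenance,
        }
    )
    patches = grid.patches.reshape(nr * nc, w, w, grid.patches.shape[-1])
    return LabeledPatchSet(patches, meta, n_classes)
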