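"""Synthetic multi-temporal scene series with a known class map.

Emulates a multi-class landscape imaged repeatedly under varying
illumination and noise: a shared class map on the patch grid, one rendered
reference scene, and k perturbed replicates.  Replicates never change the
class map — a patch keeps the same true label in every scene of a series —
which is exactly the property the temporal label-propagation augmentation
exploits.

The perturbation family is deliberately minimal: an affine intensity change
(multiplicative gain + additive offset), white noise, and an optional
Gaussian blur.  That is enough to make replicates non-identical yet
label-preserving; it does not model physical radiative transfer, clouds, or
phenology.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging import RasterScene, ValidationError

__all__ = [
    "SyntheticSceneConfig",
    "SceneSeries",
    "generate_class_map",
    "render_scene",
    "perturb_scene",
    "generate_series",
    "default_class_colors",
]


def default_class_colors(L: int, C: int = 3) -> np.ndarray:
    """Well-separated mean color vectors for L classes (values in [0, 255])."""
    rng = np.random.default_rng(12345)  # fixed palette, not a simulation seed
    base = np.array(
        [
            [34, 139, 34],    # forest
            [30, 100, 200],   # water
            [222, 184, 135],  # field
            [128, 128, 128],  # residence
            [240, 230, 140],  # sand
            [180, 40, 40],    # bare/urban red
        ],
        dtype=float,
    )
    if L <= len(base):
        cols = base[:L]
    else:
        extra = rng.uniform(0, 255, size=(L - len(base), 3))
        cols = np.vstack([base, extra])
    if C == 3:
        return cols
    if C == 1:
        return cols.mean(axis=1, keepdims=True)
    out = np.zeros((L, C))
    out[:, : min(3, C)] = cols[:, : min(3, C)]
    if C > 3:
        out[:, 3:] = rng.uniform(0, 255, size=(L, C - 3))
    return out


@dataclass
class SyntheticSceneConfig:
    """Stated world for a synthetic series.

    Defaults emulate a 6-class landscape tiled into 10×10 patches, imaged
    k=3 further times with moderate sensing perturbations.
    """

    n_rows: int = 50
    n_cols: int = 50
    patch_size: int = 10
    n_classes: int = 6
    n_channels: int = 3
    class_map_method: str = "voronoi"  # or "smoothed-threshold"
    class_colors: np.ndarray | None = None  # (L, C)
    within_patch_sd: float = 10.0
    n_replicates: int = 3
    brightness_offset_sd: float = 8.0
    gain_sd: float = 0.05
    replicate_noise_sd: float = 8.0
    blur_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValidationError("need at least 2 classes")
        for name in ("within_patch_sd", "brightness_offset_sd", "gain_sd",
                     "replicate_noise_sd", "blur_sigma"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.class_colors is None:
            self.class_colors = default_class_colors(
                self.n_classes, self.n_channels
            )
        self.class_colors = np.asarray(self.class_colors, dtype=float)
        if self.class_colors.shape != (self.n_classes, self.n_channels):
            raise ValidationError(
                "class_colors must have shape (n_classes, n_channels)"
            )

    def to_json(self) -> str:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in self.__dict__.items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "SyntheticSceneConfig":
        d = json.loads(s)
        if d.get("class_colors") is not None:
            d["class_colors"] = np.asarray(d["class_colors"], dtype=float)
        return cls(**d)


@dataclass
class SceneSeries:
    """A reference scene plus co-registered replicates sharing one class map."""

    reference: RasterScene
    replicates: list[RasterScene]
    class_map: np.ndarray  # (n_rows, n_cols) true labels
    patch_size: int

    def __post_init__(self):
        shp = self.reference.pixels.shape
        for s in self.replicates:
            if s.pixels.shape != shp:
                raise ValidationError("all scenes in a series must share dims")
        nr = shp[0] // self.patch_size
        nc = shp[1] // self.patch_size
        if self.class_map.shape != (nr, nc):
            raise ValidationError(
                f"class_map dims {self.class_map.shape} do not match the "
                f"patch grid dims {(nr, nc)}"
            )

    @property
    def scenes(self) -> list[RasterScene]:
        return [self.reference] + list(self.replicates)

    @property
    def n_scenes(self) -> int:
        return 1 + len(self.replicates)


def generate_class_map(
    n_rows: int,
    n_cols: int,
    L: int,
    method: str = "voronoi",
    params: dict | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Generate an (n_rows, n_cols) integer class map with values in {0..L-1}.

    ``voronoi`` drops L*k random seed sites on the grid and assigns each cell
    the class of its nearest site (compact patchy regions).
    ``smoothed-threshold`` thresholds a Gaussian-smoothed white-noise field at
    L-1 equally spaced quantiles (diffuse gradients).  When the grid can hold
    all L classes but a draw misses one, the draw is retried a bounded number
    of times.
    """
    if L < 2:
        raise ValidationError("L must be >= 2")
    if n_rows < 1 or n_cols < 1:
        raise ValidationError("grid dims must be positive")
    params = dict(params or {})
    n_cells = n_rows * n_cols
    if n_cells < L:
        warnings.warn(
            f"grid of {n_cells} cells cannot contain all {L} classes",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    max_retry = 20
    for _ in range(max_retry):
        if method == "voronoi":
            k = int(params.get("sites_per_class", 3))
            n_sites = L * k
            sites = np.column_stack(
                [rng.uniform(0, n_rows, n_sites), rng.uniform(0, n_cols, n_sites)]
            )
            site_class = np.repeat(np.arange(L), k)
            ii, jj = np.mgrid[0:n_rows, 0:n_cols]
            cells = np.column_stack([ii.ravel() + 0.5, jj.ravel() + 0.5])
            d2 = ((cells[:, None, :] - sites[None, :, :]) ** 2).sum(axis=2)
            cmap = site_class[np.argmin(d2, axis=1)].reshape(n_rows, n_cols)
        elif method == "smoothed-threshold":
            sigma = float(params.get("sigma", max(2.0, min(n_rows, n_cols) / 10)))
            field_ = rng.standard_normal((n_rows, n_cols))
            field_ = ndimage.gaussian_filter(field_, sigma, mode="wrap")
            qs = np.quantile(field_, np.linspace(0, 1, L + 1)[1:-1])
            cmap = np.searchsorted(qs, field_.ravel()).reshape(n_rows, n_cols)
        else:
            raise ValidationError(f"unknown class-map method {method!r}")
        if n_cells < L or len(np.unique(cmap)) == L:
            return cmap.astype(int)
    warnings.warn(
        f"could not realise all {L} classes in {max_retry} draws; "
        "returning last draw",
        stacklevel=2,
    )
    return cmap.astype(int)


def render_scene(
    class_map: np.ndarray,
    class_colors: np.ndarray,
    w: int,
    within_patch_sd: float = 10.0,
    seed: int = 0,
    scene_id: str = "synthetic",
    time_index: int = 0,
) -> RasterScene:
    """Render a class map into a scene: each w×w block is its class's mean
    color plus i.i.d. Gaussian noise."""
    class_map = np.asarray(class_map, dtype=int)
    class_colors = np.asarray(class_colors, dtype=float)
    L, C = class_colors.shape
    if class_map.min() < 0 or class_map.max() >= L:
        raise ValidationError("class map labels outside the color table")
    nr, nc = class_map.shape
    rng = np.random.default_rng(seed)
    means = class_colors[class_map]  # (nr, nc, C)
    px = np.repeat(np.repeat(means, w, axis=0), w, axis=1)
    if within_patch_sd > 0:
        px = px + rng.normal(0.0, within_patch_sd, size=px.shape)
    return RasterScene(px, scene_id=scene_id, time_index=time_index)


def perturb_scene(
    scene: RasterScene,
    gain: float = 1.0,
    offset: float = 0.0,
    noise_sd: float = 0.0,
    blur_sigma: float = 0.0,
    seed: int = 0,
    scene_id: str | None = None,
) -> RasterScene:
    """Apply gain·pixels + offset + noise, then an optional Gaussian blur.

    Dimensions are preserved and the time index is incremented, emulating a
    later acquisition of the same co-registered area.
    """
    if noise_sd < 0 or blur_sigma < 0:
        raise ValidationError("noise_sd and blur_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    px = gain * scene.pixels + offset
    if noise_sd > 0:
        px = px + rng.normal(0.0, noise_sd, size=px.shape)
    if blur_sigma > 0:
        px = ndimage.gaussian_filter(px, sigma=(blur_sigma, blur_sigma, 0))
    return RasterScene(
        px,
        scene_id=scene_id or f"{scene.scene_id}_t{scene.time_index + 1}",
        time_index=scene.time_index + 1,
    )


def generate_series(config: SyntheticSceneConfig) -> SceneSeries:
    """Generate a reference scene plus k perturbed replicates.

    All randomness flows from ``config.seed`` through one SeedSequence, split
    into independent streams per scene, so the whole series is reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    map_seed, render_seed, *rep_seeds = ss.spawn(2 + 2 * config.n_replicates)
    cmap = generate_class_map(
        config.n_rows,
        config.n_cols,
        config.n_classes,
        method=config.class_map_method,
        seed=map_seed,
    )
    ref = render_scene(
        cmap,
        config.class_colors,
        config.patch_size,
        within_patch_sd=config.within_patch_sd,
        seed=render_seed,
        scene_id="ref",
        time_index=0,
    )
    reps = []
    for t in range(config.n_replicates):
        prm = np.random.default_rng(rep_seeds[2 * t])
        gain = 1.0 + (prm.normal(0, config.gain_sd) if config.gain_sd > 0 else 0.0)
        offset = (
            prm.normal(0, config.brightness_offset_sd)
            if config.brightness_offset_sd > 0
            else 0.0
        )
        rep = perturb_scene(
            ref,
            gain=gain,
            offset=offset,
            noise_sd=config.replicate_noise_sd,
            blur_sigma=config.blur_sigma,
            seed=rep_seeds[2 * t + 1],
            scene_id=f"rep{t + 1}",
        )
        rep = rep.replace(time_index=t + 1)
        reps.append(rep)
    return SceneSeries(ref, reps, cmap, config.patch_size)
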