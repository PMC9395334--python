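"""A small LeNet-style CNN for w×w patch classification, in pure NumPy.

Architecture (adapted to small inputs; the canonical LeNet expects 32×32):
two 3×3 convolution stages (16 and 32 filters, ReLU, "same" padding), each
followed by 2×2 max-pool downsampling, a 64-unit hidden dense stage with
ReLU, and a softmax output over L classes.  Training uses mini-batch Adam
with cross-entropy loss; the default protocol is Adam, batch size 256,
30 epochs, learning rate 1e-3.

Patch intensities are standardized per channel using training-set
statistics, stored with the model.  Everything is deterministic under a
fixed seed.  The implementation is deliberately dependency-free (im2col
convolution, explicit backprop) so the whole pipeline runs on one CPU with
only the scientific Python stack; at 10×10 inputs this trains thousands of
patches per second.

Alternative architectures (e.g. compound-scaled networks) can be plugged in
through the same ``TrainedClassifier`` duck interface: anything with
``predict_proba``/``classify`` works downstream.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .imaging import LabeledPatchSet, ValidationError

__all__ = [
    "ClassifierSpec",
    "TrainedClassifier",
    "EvalReport",
    "build_classifier",
    "train",
    "classify_patches",
    "evaluate",
]


class StateError(RuntimeError):
    """Raised when an operation requires a trained model."""


@dataclass
class ClassifierSpec:
    """Input geometry, architecture widths, and the training protocol."""

    patch_size: int = 10
    n_channels: int = 3
    n_classes: int = 6
    conv_filters: tuple = (16, 32)
    dense_units: int = 64
    optimizer: str = "adam"
    batch_size: int = 256
    epochs: int = 30
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValidationError("need at least 2 classes")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("batch_size and epochs must be >= 1")
        if len(self.conv_filters) != 2:
            raise ValidationError("exactly two convolution stages expected")
        # each stage halves the spatial size (floor); both must stay >= 1
        if (self.patch_size // 2) // 2 < 1:
            raise ValidationError(
                f"patch size {self.patch_size} too small for two 2× "
                f"downsampling stages; minimal size is 4"
            )
        if self.optimizer.lower() != "adam":
            raise ValidationError("only the adam optimizer is implemented")

    @property
    def flat_features(self) -> int:
        s = (self.patch_size // 2) // 2
        return s * s * self.conv_filters[1]


@dataclass
class EvalReport:
    """Top-1/top-k accuracy with a confusion matrix."""

    top1: float
    top5: float
    confusion: np.ndarray
    n: int
    per_class_recall: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {
                "top1": self.top1,
                "top5": self.top5,
                "n": self.n,
                "confusion": self.confusion.tolist(),
                "per_class_recall": self.per_class_recall.tolist(),
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# layer primitives


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(N, H, W, C) → (N, H, W, k·k·C) sliding 3×3 windows, same padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # v: (N, H, W, C, k, k) → (N, H, W, k, k, C)
    return np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3)).reshape(
        x.shape[0], x.shape[1], x.shape[2], k * k * x.shape[3]
    )


def _col2im(dcols: np.ndarray, shape, k: int = 3) -> np.ndarray:
    """Adjoint of _im2col: scatter window gradients back onto the image."""
    N, H, W, C = shape
    p = k // 2
    dxp = np.zeros((N, H + 2 * p, W + 2 * p, C))
    d6 = dcols.reshape(N, H, W, k, k, C)
    for a in range(k):
        for b in range(k):
            dxp[:, a : a + H, b : b + W, :] += d6[:, :, :, a, b, :]
    return dxp[:, p : p + H, p : p + W, :]


def _maxpool(x: np.ndarray):
    """2×2 stride-2 max pooling (odd trailing row/col cropped)."""
    N, H, W, C = x.shape
    Ho, Wo = H // 2, W // 2
    xc = x[:, : Ho * 2, : Wo * 2, :]
    r = xc.reshape(N, Ho, 2, Wo, 2, C).transpose(0, 1, 3, 5, 2, 4)
    r = r.reshape(N, Ho, Wo, C, 4)
    idx = r.argmax(axis=4)
    out = np.take_along_axis(r, idx[..., None], axis=4)[..., 0]
    return out, (idx, x.shape)


def _maxpool_backward(dout: np.ndarray, cache) -> np.ndarray:
    idx, shape = cache
    N, H, W, C = shape
    Ho, Wo = H // 2, W // 2
    dr = np.zeros((N, Ho, Wo, C, 4))
    np.put_along_axis(dr, idx[..., None], dout[..., None], axis=4)
    dr = dr.reshape(N, Ho, Wo, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    dx = np.zeros(shape)
    dx[:, : Ho * 2, : Wo * 2, :] = dr.reshape(N, Ho * 2, Wo * 2, C)
    return dx


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# the model


class TrainedClassifier:
    """LeNet-style patch classifier; starts untrained, trained by ``train``."""

    PARAM_KEYS = ("W1", "b1", "W2", "b2", "W3", "b3", "W4", "b4")

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        self.params: dict[str, np.ndarray] = {}
        self.mu = np.zeros(spec.n_channels)
        self.sigma = np.ones(spec.n_channels)
        self.history = pd.DataFrame(
            columns=["epoch", "loss", "train_acc", "val_acc", "n_steps"]
        )
        self.trained = False
        self._init_params()

    # -- initialization ----------------------------------------------------
    def _init_params(self) -> None:
        s = self.spec
        rng = np.random.default_rng(s.seed)
        f1, f2 = s.conv_filters
        k = 3

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params = {
            "W1": he((k * k * s.n_channels, f1), k * k * s.n_channels),
            "b1": np.zeros(f1),
            "W2": he((k * k * f1, f2), k * k * f1),
            "b2": np.zeros(f2),
            "W3": he((s.flat_features, s.dense_units), s.flat_features),
            "b3": np.zeros(s.dense_units),
            "W4": he((s.dense_units, s.n_classes), s.dense_units),
            "b4": np.zeros(s.n_classes),
        }

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- forward / backward ------------------------------------------------
    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mu) / self.sigma

    def _forward(self, X: np.ndarray, want_cache: bool = False):
        p = self.params
        N = X.shape[0]
        cols1 = _im2col(X)
        z1 = cols1 @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        p1, cache_p1 = _maxpool(a1)
        cols2 = _im2col(p1)
        z2 = cols2 @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0.0)
        p2, cache_p2 = _maxpool(a2)
        flat = p2.reshape(N, -1)
        z3 = flat @ p["W3"] + p["b3"]
        a3 = np.maximum(z3, 0.0)
        z4 = a3 @ p["W4"] + p["b4"]
        probs = _softmax(z4)
        if not want_cache:
            return probs
        return probs, (X, cols1, z1, cache_p1, p1, cols2, z2, cache_p2, p2,
                       flat, z3, a3)

    def _backward(self, probs, y_onehot, cache):
        (X, cols1, z1, cache_p1, p1, cols2, z2, cache_p2, p2, flat, z3,
         a3) = cache
        p = self.params
        N = X.shape[0]
        g = {}
        dz4 = (probs - y_onehot) / N
        g["W4"] = a3.T @ dz4
        g["b4"] = dz4.sum(axis=0)
        da3 = dz4 @ p["W4"].T
        dz3 = da3 * (z3 > 0)
        g["W3"] = flat.T @ dz3
        g["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["W3"].T
        dp2 = dflat.reshape(p2.shape)
        da2 = _maxpool_backward(dp2, cache_p2)
        dz2 = da2 * (z2 > 0)
        g["W2"] = cols2.reshape(-1, cols2.shape[-1]).T @ dz2.reshape(
            -1, dz2.shape[-1]
        )
        g["b2"] = dz2.sum(axis=(0, 1, 2))
        dcols2 = dz2 @ p["W2"].T
        dp1 = _col2im(dcols2, p1.shape)
        da1 = _maxpool_backward(dp1, cache_p1)
        dz1 = da1 * (z1 > 0)
        g["W1"] = cols1.reshape(-1, cols1.shape[-1]).T @ dz1.reshape(
            -1, dz1.shape[-1]
        )
        g["b1"] = dz1.sum(axis=(0, 1, 2))
        return g

    # -- inference ---------------------------------------------------------
    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """Probability vectors (rows sum to 1) for (N, w, w, C) patches."""
        if not self.trained:
            raise StateError("classifier is not trained")
        X = self._check_input(patches)
        return self._forward(self._standardize(X))

    def classify(self, patches: np.ndarray):
        """Argmax labels (ties toward the lowest class index) + probabilities."""
        probs = self.predict_proba(patches)
        return probs.argmax(axis=1), probs

    def _check_input(self, patches: np.ndarray) -> np.ndarray:
        X = np.asarray(patches, dtype=float)
        if X.ndim == 3:
            X = X[None]
        s = self.spec
        if X.shape[1:] != (s.patch_size, s.patch_size, s.n_channels):
            raise ValidationError(
                f"patch shape {X.shape[1:]} does not match spec "
                f"({s.patch_size}, {s.patch_size}, {s.n_channels})"
            )
        return X

    # -- persistence -------------------------------------------------------
    def save(self, path: str) -> None:
        buf = io.StringIO()
        self.history.to_csv(buf, index=False)
        np.savez_compressed(
            path,
            spec_json=json.dumps(asdict(self.spec)),
            mu=self.mu,
            sigma=self.sigma,
            trained=np.array(self.trained),
            history_csv=buf.getvalue(),
            **self.params,
        )

    @classmethod
    def load(cls, path: str) -> "TrainedClassifier":
        with np.load(path, allow_pickle=False) as z:
            d = json.loads(str(z["spec_json"]))
            d["conv_filters"] = tuple(d["conv_filters"])
            model = cls(ClassifierSpec(**d))
            model.mu = z["mu"]
            model.sigma = z["sigma"]
            model.trained = bool(z["trained"])
            model.history = pd.read_csv(io.StringIO(str(z["history_csv"])))
            for k in cls.PARAM_KEYS:
                model.params[k] = z[k]
        return model


def build_classifier(spec: ClassifierSpec) -> TrainedClassifier:
    """Instantiate an untrained model with seeded He initialization."""
    return TrainedClassifier(spec)


def _as_xy(dataset, spec: ClassifierSpec):
    if isinstance(dataset, LabeledPatchSet):
        X, y = dataset.patches, dataset.labels
    else:
        X, y = dataset
        X, y = np.asarray(X, dtype=float), np.asarray(y, dtype=int)
    if len(X) == 0:
        raise ValidationError("dataset is empty")
    if (y < 0).any() or (y >= spec.n_classes).any():
        raise ValidationError("labels outside the class range")
    return X, y


def train(model: TrainedClassifier, train_set, validation_set=None,
          epochs: int | None = None, batch_size: int | None = None,
          learning_rate: float | None = None,
          verbose: bool = False) -> TrainedClassifier:
    """Mini-batch Adam training; records one history row per epoch.

    Accepts a LabeledPatchSet or an (X, y) tuple.  Standardization
    statistics are computed from the training set on entry.
    """
    s = model.spec
    epochs = s.epochs if epochs is None else epochs
    batch_size = s.batch_size if batch_size is None else batch_size
    lr = s.learning_rate if learning_rate is None else learning_rate
    X, y = _as_xy(train_set, s)
    model._check_input(X)
    model.mu = X.mean(axis=(0, 1, 2))
    model.sigma = np.maximum(X.std(axis=(0, 1, 2)), 1e-8)
    Xs = model._standardize(X)
    val = None
    if validation_set is not None:
        Xv, yv = _as_xy(validation_set, s)
        val = (model._standardize(model._check_input(Xv)), yv)

    onehot = np.eye(s.n_classes)[y]
    rng = np.random.default_rng(np.random.SeedSequence([s.seed, 7]))
    m_t = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_t = {k: np.zeros_like(v) for k, v in model.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0
    rows = []
    for epoch in range(1, epochs + 1):
        perm = rng.permutation(len(Xs))
        losses, hits, seen, n_steps = 0.0, 0, 0, 0
        for start in range(0, len(Xs), batch_size):
            idx = perm[start : start + batch_size]
            xb, yb = Xs[idx], onehot[idx]
            probs, cache = model._forward(xb, want_cache=True)
            loss = -np.mean(
                np.log(np.maximum(probs[np.arange(len(idx)), y[perm[start:start + batch_size]]], 1e-300))
            )
            grads = model._backward(probs, yb, cache)
            t += 1
            for k in model.params:
                m_t[k] = b1 * m_t[k] + (1 - b1) * grads[k]
                v_t[k] = b2 * v_t[k] + (1 - b2) * grads[k] ** 2
                mhat = m_t[k] / (1 - b1**t)
                vhat = v_t[k] / (1 - b2**t)
                model.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
            losses += loss * len(idx)
            hits += int((probs.argmax(axis=1) == y[idx]).sum())
            seen += len(idx)
            n_steps += 1
        val_acc = np.nan
        if val is not None:
            vp = model._forward(val[0])
            val_acc = float((vp.argmax(axis=1) == val[1]).mean())
        rows.append(
            {
                "epoch": epoch,
                "loss": losses / seen,
                "train_acc": hits / seen,
                "val_acc": val_acc,
                "n_steps": n_steps,
            }
        )
        if verbose:
            print(f"epoch {epoch:3d}  loss {rows[-1]['loss']:.4f}  "
                  f"acc {rows[-1]['train_acc']:.4f}  val {val_acc}")
    model.history = pd.DataFrame(rows)
    model.trained = True
    return model


def classify_patches(model: TrainedClassifier, patches: np.ndarray):
    """Labels (argmax, ties to the lowest index) and probability vectors."""
    return model.classify(patches)


def _topk_hit(probs: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    # stable sort ⇒ ties resolved toward the lowest class index
    order = np.argsort(-probs, axis=1, kind="stable")[:, :k]
    return (order == y[:, None]).any(axis=1)


def evaluate(model: TrainedClassifier, test_set, k_top: int = 5) -> EvalReport:
    """Top-1/top-k accuracy and the L×L confusion matrix on a test set."""
    s = model.spec
    X, y = _as_xy(test_set, s)
    probs = model.predict_proba(X)
    pred = probs.argmax(axis=1)
    L = s.n_classes
    conf = np.zeros((L, L), dtype=int)
    np.add.at(conf, (y, pred), 1)
    row = conf.sum(axis=1)
    with np.errstate(invalid="ignore"):
        recall = np.where(row > 0, np.diag(conf) / row, np.nan)
    top1 = float((pred == y).mean())
    topk = float(_topk_hit(probs, y, min(k_top, L)).mean())
    return EvalReport(top1, topk, conf, len(y), recall)
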