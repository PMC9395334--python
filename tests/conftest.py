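import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

import pointscape as ps
from pointscape import classifier as C
from pointscape.synthetic import default_class_colors


def make_benchmark(n, seed, L=6, w=10, channels=3, sd=10.0):
    """Separable synthetic benchmark: distinct class mean colors, i.i.d.
    Gaussian texture noise small enough that the Bayes accuracy is ≈ 1."""
    rng = np.random.default_rng(seed)
    colors = default_class_colors(L, channels)
    y = rng.integers(0, L, n)
    X = colors[y][:, None, None, :] + rng.normal(0, sd, (n, w, w, channels))
    return X, y


@pytest.fixture(scope="session")
def small_trained_model():
    """A quickly trained but accurate model for serialization/pseudo-label
    tests (600 separable patches, 10 epochs)."""
    Xtr, ytr = make_benchmark(600, seed=11)
    spec = ps.ClassifierSpec(epochs=10, seed=3)
    model = ps.build_classifier(spec)
    C.train(model, (Xtr, ytr))
    return model


@pytest.fixture(scope="session")
def small_series():
    cfg = ps.SyntheticSceneConfig(n_rows=8, n_cols=9, n_replicates=3, seed=5)
    return cfg, ps.generate_series(cfg)


@pytest.fixture()
def csr_marked():
    pat = ps.simulate_csr_n(300, seed=21)
    return ps.randomize_marks(pat, "iid", p=[0.25, 0.25, 0.3, 0.2], seed=22)
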