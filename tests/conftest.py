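import numpy as np
import pytest

from rwrfuse import (
    CouplingParams,
    FeatureMatrix,
    RWRConfig,
    SimilarityNetwork,
    assemble_multiplex,
    similarity_from_features,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """5 features x 6 samples with two missing cells."""
    vals = np.arange(30, dtype=float).reshape(5, 6)
    vals[1, 2] = np.nan
    vals[4, 0] = np.nan
    return FeatureMatrix(
        values=vals,
        feature_ids=[f"g{i}" for i in range(5)],
        sample_ids=[f"s{j}" for j in range(6)],
        layer_name="toy",
    )


def random_similarity(n: int, rng: np.random.Generator) -> SimilarityNetwork:
    """A random valid similarity network: symmetric, entries in (0,1], diag 1."""
    a = rng.uniform(0.05, 1.0, size=(n, n))
    s = (a + a.T) / 2.0
    np.fill_diagonal(s, 1.0)
    return SimilarityNetwork(values=s, sample_ids=[f"s{i}" for i in range(n)])


def random_multiplex(n: int, L: int, rng: np.random.Generator, variant: str = "RWRF",
                     m: int = 3, beta: float = 0.9):
    layers = []
    for j in range(L):
        layer = random_similarity(n, rng)
        layer.layer_name = f"layer{j}"
        layers.append(layer)
    return assemble_multiplex(layers, CouplingParams(variant=variant, m=m, beta=beta))


@pytest.fixture
def two_layer_multiplex(rng):
    return random_multiplex(8, 2, rng)


def gaussian_blob_views(n_per: int, centers, noise: float, dim: int, seed: int):
    """Well-separated Gaussian blobs as a FeatureMatrix plus labels."""
    rng = np.random.default_rng(seed)
    centers = np.asarray(centers, dtype=float)
    k = len(centers)
    pts = np.concatenate([
        centers[c] + rng.normal(0, noise, size=(n_per, dim)) for c in range(k)
    ])
    labels = np.repeat(np.arange(k), n_per)
    fm = FeatureMatrix(
        values=pts.T,
        feature_ids=[f"f{j}" for j in range(dim)],
        sample_ids=[f"s{i}" for i in range(k * n_per)],
        layer_name="blobs",
    )
    return fm, labels
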