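"""Scaled-exponential-kernel sample similarity networks.

For one omics layer the similarity between samples x and y is

    S(x, y) = exp( -dist^2(x, y) / (mu * E(x, y)) )

with a locally adaptive bandwidth

    E(x, y) = [ mean(dist(x, N_x)) + mean(dist(y, N_y)) + dist(x, y) ] / 3

where ``N_x`` is the set of the ``N`` nearest neighbors of x (self excluded)
and dist is the Euclidean distance over the layer's features. The kernel is
the standard scaled exponential affinity of similarity-network fusion;
defaults N=20, mu=0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data_io import FeatureMatrix

logger = logging.getLogger("rwrfuse")


@dataclass
class KernelParams:
    """Hyper-parameters of the scaled exponential kernel.

    ``mu`` scales the local bandwidth; ``n_neighbors`` is the neighborhood
    size N used for the adaptive scale (clamped to n-1 for small cohorts).
    """

    mu: float = 0.5
    n_neighbors: int = 20

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.n_neighbors < 1:
            raise ValueError(f"n_neighbors must be >= 1, got {self.n_neighbors}")


@dataclass
class DistanceMatrix:
    """Symmetric Euclidean sample-by-sample distances with a zero diagonal."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class SimilarityNetwork:
    """A sample affinity matrix for one layer: symmetric, entries in (0, 1], diag 1."""

    values: np.ndarray
    sample_ids: list[str]
    layer_name: str = "layer"
    local_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match sample ids")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def pairwise_distances(m: FeatureMatrix) -> DistanceMatrix:
    """Euclidean distance between every pair of samples of one layer."""
    if np.isnan(m.values).any():
        raise ValueError("feature matrix has missing values; impute first")
    d = squareform(pdist(m.values.T, metric="euclidean"))
    return DistanceMatrix(values=d, sample_ids=list(m.sample_ids))


def _clamped_neighbors(n: int, n_neighbors: int) -> int:
    if n_neighbors >= n:
        logger.warning("n_neighbors=%d >= n=%d samples; clamping to %d", n_neighbors, n, n - 1)
        return n - 1
    return n_neighbors


def local_scale(d: DistanceMatrix, params: KernelParams) -> np.ndarray:
    """Adaptive bandwidth E(x, y) from mean nearest-neighbor distances.

    The neighbor set of x is the N samples with the smallest distance to x,
    self excluded, ties broken by sample index (stable sort).
    """
    n = d.n
    if n < 2:
        raise ValueError("need at least two samples")
    k = _clamped_neighbors(n, params.n_neighbors)
    dv = d.values
    # order by (distance, index); column 0 is self (distance 0, smallest index)
    order = np.argsort(dv, axis=1, kind="stable")
    mean_nn = np.empty(n)
    for i in range(n):
        nbr = order[i][order[i] != i][:k]
        mean_nn[i] = dv[i, nbr].mean()
    e = (mean_nn[:, None] + mean_nn[None, :] + dv) / 3.0
    return e


def similarity_network(d: DistanceMatrix, params: KernelParams | None = None,
                       layer_name: str = "layer", zero_diagonal: bool = False) -> SimilarityNetwork:
    """Build the scaled-exponential similarity network from distances.

    Duplicate points (dist 0, hence E 0 when all neighbors coincide) get
    similarity 1 by the limiting convention. ``zero_diagonal`` removes
    self-similarity for sensitivity analyses; by default the diagonal stays
    at its kernel value 1 and acts as a self-loop downstream.
    """
    params = params or KernelParams()
    e = local_scale(d, params)
    dv = d.values
    s = np.ones_like(dv)
    pos = e > 0
    s[pos] = np.exp(-(dv[pos] ** 2) / (params.mu * e[pos]))
    s = (s + s.T) / 2.0  # enforce exact symmetry against rounding
    np.fill_diagonal(s, 0.0 if zero_diagonal else 1.0)
    return SimilarityNetwork(values=s, sample_ids=list(d.sample_ids),
                             layer_name=layer_name, local_scale=e)


def similarity_from_features(m: FeatureMatrix, params: KernelParams | None = None) -> SimilarityNetwork:
    """Convenience: features -> distances -> similarity network for one layer."""
    return similarity_network(pairwise_distances(m), params, layer_name=m.layer_name)
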