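"""Multiplex sample network assembly.

A multiplex network stacks L per-layer similarity networks over the same n
samples and adds inter-layer coupling blocks A_jl (ordered layer pairs,
j != l) that connect each sample to its replicas ("mirror nodes") in the
other layers. Two coupling variants are supported:

* plain fusion (``RWRF``): A_jl = I_n — every sample is linked only to its
  own mirror;
* neighbor-informed fusion (``RWRNF``): from layer j, sample x sends weight
  beta to its mirror and weight (1 - beta)/m to the mirrors of its m most
  similar neighbors *in layer j*, giving a directed, row-stochastic coupling
  that carries layer-j neighborhood structure into the other layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .similarity import SimilarityNetwork

logger = logging.getLogger("rwrfuse")

RWRF = "RWRF"
RWRNF = "RWRNF"


@dataclass
class CouplingParams:
    """Inter-layer coupling settings.

    ``variant`` selects identity (RWRF) or neighbor (RWRNF) coupling;
    ``m`` neighbors and mirror weight ``beta`` apply to RWRNF only.
    """

    variant: str = RWRF
    m: int = 10
    beta: float = 0.9

    def __post_init__(self) -> None:
        if self.variant not in (RWRF, RWRNF):
            raise ValueError(f"variant must be {RWRF!r} or {RWRNF!r}, got {self.variant!r}")
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if not 0 <= self.beta <= 1:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")


@dataclass
class MultiplexNetwork:
    """L similarity layers plus row-stochastic coupling blocks A_jl (j != l)."""

    layers: list[SimilarityNetwork]
    couplings: dict[tuple[int, int], sp.csr_matrix]
    params: CouplingParams = field(default_factory=CouplingParams)

    @property
    def n(self) -> int:
        return self.layers[0].n

    @property
    def L(self) -> int:
        return len(self.layers)

    @property
    def sample_ids(self) -> list[str]:
        return self.layers[0].sample_ids

    def full_matrix(self) -> np.ndarray:
        """Dense (L n) x (L n) block matrix — diagnostic dump only."""
        n, L = self.n, self.L
        out = np.zeros((L * n, L * n))
        for j, layer in enumerate(self.layers):
            out[j * n:(j + 1) * n, j * n:(j + 1) * n] = layer.values
        for (j, l), a in self.couplings.items():
            out[j * n:(j + 1) * n, l * n:(l + 1) * n] = a.toarray()
        return out


def build_rwrf_coupling(n: int, L: int) -> dict[tuple[int, int], sp.csr_matrix]:
    """Identity coupling: each sample linked only to its mirror in every other layer."""
    if n < 1 or L < 2:
        raise ValueError("need n >= 1 samples and L >= 2 layers")
    eye = sp.identity(n, format="csr")
    return {(j, l): eye.copy() for j in range(L) for l in range(L) if j != l}


def build_rwrnf_coupling(source: SimilarityNetwork, params: CouplingParams) -> sp.csr_matrix:
    """Directed neighbor coupling block from one source layer to another layer.

    Row x carries weight ``beta`` at the mirror column x and ``(1-beta)/m``
    at the mirrors of the m most-similar neighbors of x in the source layer
    (self excluded, ties broken by sample index). Every row sums to 1.
    """
    n = source.n
    m = params.m
    if m >= n:
        logger.warning("m=%d >= n=%d samples; clamping to %d", m, n, n - 1)
        m = n - 1
    s = source.values
    rows, cols, vals = [], [], []
    w_nbr = (1.0 - params.beta) / m
    for x in range(n):
        rows.append(x)
        cols.append(x)
        vals.append(params.beta)
        if w_nbr > 0:
            # most similar first; ties by index via stable sort on (-sim, index)
            order = np.argsort(-s[x], kind="stable")
            nbr = order[order != x][:m]
            for y in nbr:
                rows.append(x)
                cols.append(int(y))
                vals.append(w_nbr)
    a = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    a.sum_duplicates()
    return a


def assemble_multiplex(layers: list[SimilarityNetwork], params: CouplingParams | None = None) -> MultiplexNetwork:
    """Stack similarity layers into a multiplex network with per-variant couplings.

    Under RWRNF every ordered pair (j, l) gets its own block built from layer
    j's neighborhoods; under RWRF all blocks are the identity.
    """
    params = params or CouplingParams()
    if len(layers) < 2:
        raise ValueError("need at least two layers")
    ids0 = layers[0].sample_ids
    for layer in layers[1:]:
        if layer.sample_ids != ids0:
            raise ValueError(
                f"layer {layer.layer_name!r} sample ids differ from {layers[0].layer_name!r}; "
                "align layers first"
            )
    n, L = layers[0].n, len(layers)
    if params.variant == RWRF:
        couplings = build_rwrf_coupling(n, L)
    else:
        couplings = {}
        for j in range(L):
            block = build_rwrnf_coupling(layers[j], params)
            for l in range(L):
                if l != j:
                    couplings[(j, l)] = block.copy()
    return MultiplexNetwork(layers=list(layers), couplings=couplings, params=params)
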