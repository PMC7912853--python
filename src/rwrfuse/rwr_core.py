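"""Random walk with restart on the multiplex network and all-seed fusion.

The walker's state lives on the L*n multiplex nodes. One step either follows
the row-stochastic transition matrix W or teleports back to the seed
distribution with restart probability gamma:

    p_{t+1} = (1 - gamma) * W^T p_t + gamma * p_0

The iteration is run to a stationary profile p_stable for every one of the
L*n seeds; the per-layer blocks of those profiles are stacked into new
similarity matrices S'_1..S'_L, and the fused network is their symmetrized
average

    S_fusion = sum_j (S'_j + S'_j^T) / (2 L)

which for two layers is (S'_1 + S'_2 + S'_1^T + S'_2^T) / 4.

Transition structure: within layer j a walker stays with probability
lambda_j and moves along the row-normalized similarity S_j; it jumps to each
other layer l with probability (1 - lambda_j)/(L - 1) along the
row-normalized coupling block A_jl (identity under plain fusion). Restart
mass is split over layers by the seed weights: uniformly (1/L) under RWRF,
and alpha on the seed's own layer with (1 - alpha)/(L - 1) spread through
the coupling rows under RWRNF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .multiplex import RWRF, RWRNF, MultiplexNetwork

logger = logging.getLogger("rwrfuse")


@dataclass
class RWRConfig:
    """Random-walk-with-restart settings.

    Parameters
    ----------
    gamma
        Restart (teleport) probability in (0, 1]; larger values keep the
        stationary profile closer to the seed. Default 0.7.
    lambdas
        Per-layer stay probabilities summing to 1; layer j keeps mass
        ``lambdas[j]`` and distributes ``1 - lambdas[j]`` equally over jumps
        to the other layers. ``None`` means uniform 1/L.
    alpha
        RWRNF seed-layer restart weight (default 0.9); the remaining
        ``1 - alpha`` flows through the coupling rows of the other layers.
        Ignored under RWRF, where restart mass is uniform over layers.
    tol
        L1 convergence threshold on successive iterates. Default 1e-10.
    max_iter
        Iteration cap; exceeding it raises :class:`ConvergenceError`.
    """

    gamma: float = 0.7
    lambdas: np.ndarray | None = None
    alpha: float = 0.9
    tol: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ValueError(f"gamma must be in (0, 1], got {self.gamma}")
        if not 0 <= self.alpha <= 1:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")
        if self.lambdas is not None:
            lam = np.asarray(self.lambdas, dtype=float)
            if (lam < 0).any() or abs(lam.sum() - 1.0) > 1e-12:
                raise ValueError("lambdas must be nonnegative and sum to 1")
            self.lambdas = lam

    def layer_lambdas(self, L: int) -> np.ndarray:
        if self.lambdas is None:
            return np.full(L, 1.0 / L)
        if len(self.lambdas) != L:
            raise ValueError(f"expected {L} lambdas, got {len(self.lambdas)}")
        return self.lambdas


class ConvergenceError(RuntimeError):
    """RWR iteration failed to reach tolerance within max_iter."""

    def __init__(self, seed: tuple[int, int] | None, residual: float, max_iter: int):
        self.seed, self.residual, self.max_iter = seed, residual, max_iter
        where = f" for seed (layer {seed[0]}, sample {seed[1]})" if seed else ""
        super().__init__(
            f"random walk did not converge{where}: residual {residual:.3e} after {max_iter} iterations"
        )


@dataclass
class TransitionMatrix:
    """Row-stochastic (L n) x (L n) multiplex transition matrix with block layout."""

    full: np.ndarray
    n: int
    L: int

    def block(self, j: int, l: int) -> np.ndarray:
        n = self.n
        return self.full[j * n:(j + 1) * n, l * n:(l + 1) * n]


def _row_normalize(a: np.ndarray) -> np.ndarray:
    sums = a.sum(axis=1, keepdims=True)
    if (sums <= 0).any():
        raise ValueError("matrix has a nonpositive row sum; cannot normalize")
    return a / sums


def transition_matrix(mx: MultiplexNetwork, cfg: RWRConfig | None = None) -> TransitionMatrix:
    """Assemble W: stay blocks from row-normalized similarities, jump blocks
    from row-normalized couplings, weighted by the layer stay/jump split.

    Self-similarity is removed before row normalization. A unit self-loop
    competes with the off-diagonal kernel mass, and because the kernel's
    scale is layer-dependent (off-diagonal similarities shrink like
    exp(-Theta(dist)) as feature dimensionality grows), keeping it makes
    high-dimensional layers contribute arbitrarily little to the walk:
    the walker simply sits on its own node. Normalizing the off-diagonal
    similarities alone gives every layer the same total transition mass.
    A sample with no off-diagonal similarity mass at all (a fully isolated
    row, e.g. n=1) falls back to a self-loop so W stays stochastic.
    """
    cfg = cfg or RWRConfig()
    n, L = mx.n, mx.L
    lam = cfg.layer_lambdas(L)
    w = np.zeros((L * n, L * n))
    for j in range(L):
        s = mx.layers[j].values.copy()
        np.fill_diagonal(s, 0.0)
        if (s < 0).any():
            raise ValueError(f"layer {mx.layers[j].layer_name!r} has negative similarities")
        dead = s.sum(axis=1) <= 0
        if dead.any():
            s[dead, dead] = 1.0
        w[j * n:(j + 1) * n, j * n:(j + 1) * n] = lam[j] * _row_normalize(s)
        if L > 1:
            jump = (1.0 - lam[j]) / (L - 1)
            for l in range(L):
                if l == j:
                    continue
                a = mx.couplings[(j, l)].toarray()
                w[j * n:(j + 1) * n, l * n:(l + 1) * n] = jump * _row_normalize(a)
    return TransitionMatrix(full=w, n=n, L=L)


def initial_distribution(mx: MultiplexNetwork, seed: tuple[int, int],
                         cfg: RWRConfig | None = None) -> np.ndarray:
    """Restart vector p_0 for one seed (layer index, sample index).

    RWRF: every layer receives the indicator of the seed sample (its mirror)
    scaled by the uniform layer weight 1/L. RWRNF: the seed layer receives
    ``alpha`` on the seed sample; each other layer l receives
    ``(1 - alpha)/(L - 1)`` spread along row x of the coupling block A_jl
    (mirror plus neighbor mirrors).
    """
    cfg = cfg or RWRConfig()
    n, L = mx.n, mx.L
    j, x = seed
    if not (0 <= j < L and 0 <= x < n):
        raise IndexError(f"seed {seed} out of range for L={L}, n={n}")
    p0 = np.zeros(L * n)
    if mx.params.variant == RWRF:
        for l in range(L):
            p0[l * n + x] = 1.0 / L
    else:
        p0[j * n + x] = cfg.alpha
        if L > 1:
            w_other = (1.0 - cfg.alpha) / (L - 1)
            for l in range(L):
                if l == j:
                    continue
                row = np.asarray(mx.couplings[(j, l)][[x], :].todense()).ravel()
                p0[l * n:(l + 1) * n] = w_other * row
    return p0


def rwr(W: TransitionMatrix, p0: np.ndarray, cfg: RWRConfig | None = None,
        seed: tuple[int, int] | None = None) -> tuple[np.ndarray, int]:
    """Iterate the restart equation to its fixed point.

    Returns the stationary profile and the number of iterations used.
    Convergence is the L1 distance between successive iterates dropping
    below ``cfg.tol``.
    """
    cfg = cfg or RWRConfig()
    wt = W.full.T
    p = p0.copy()
    for it in range(1, cfg.max_iter + 1):
        p_next = (1.0 - cfg.gamma) * (wt @ p) + cfg.gamma * p0
        resid = np.abs(p_next - p).sum()
        p = p_next
        if resid < cfg.tol:
            return p, it
    raise ConvergenceError(seed, resid, cfg.max_iter)


def rwr_direct(W: TransitionMatrix, p0: np.ndarray, gamma: float) -> np.ndarray:
    """Exact stationary profile by linear solve: p = gamma (I - (1-gamma) W^T)^-1 p0.

    Serves as the closed-form cross-check for the iterative solver; the
    system is nonsingular for gamma > 0 because the spectral radius of
    (1-gamma) W^T is below 1.
    """
    if not 0 < gamma <= 1:
        raise ValueError(f"gamma must be in (0, 1], got {gamma}")
    m = np.eye(W.full.shape[0]) - (1.0 - gamma) * W.full.T
    return gamma * np.linalg.solve(m, p0)


@dataclass
class FusedResult:
    """Stationary profiles of all seeds arranged into the fused network.

    ``s_prime[j]`` holds, in row x, the layer-j block of the stationary
    profile seeded at (layer j, sample x); ``cross[(j, l)]`` holds the
    layer-l blocks (retained for diagnostics; the fusion uses only the
    within-layer blocks). ``s_fusion`` is the symmetrized average.
    """

    s_prime: list[np.ndarray]
    cross: dict[tuple[int, int], np.ndarray]
    s_fusion: np.ndarray
    sample_ids: list[str]
    iterations_per_seed: list[int] = field(default_factory=list)


def fuse_networks(mx: MultiplexNetwork, cfg: RWRConfig | None = None) -> FusedResult:
    """Run RWR from all L*n seeds and fuse the stationary profiles.

    Seeds are independent linear iterations, so they are advanced as columns
    of one matrix; each column is frozen the moment its own L1 residual
    drops below tolerance, which makes the result identical to running the
    seeds one at a time in order.
    """
    cfg = cfg or RWRConfig()
    n, L = mx.n, mx.L
    W = transition_matrix(mx, cfg)
    wt = W.full.T

    p0 = np.column_stack([
        initial_distribution(mx, (j, x), cfg) for j in range(L) for x in range(n)
    ])
    p = p0.copy()
    iters = np.zeros(L * n, dtype=int)
    active = np.ones(L * n, dtype=bool)
    for it in range(1, cfg.max_iter + 1):
        p_next = (1.0 - cfg.gamma) * (wt @ p[:, active]) + cfg.gamma * p0[:, active]
        resid = np.abs(p_next - p[:, active]).sum(axis=0)
        p[:, active] = p_next
        done = resid < cfg.tol
        idx = np.flatnonzero(active)
        iters[idx[done]] = it
        active[idx[done]] = False
        if not active.any():
            break
    if active.any():
        bad = int(np.flatnonzero(active)[0])
        raise ConvergenceError((bad // n, bad % n), float(resid.max()), cfg.max_iter)

    s_prime = [np.empty((n, n)) for _ in range(L)]
    cross = {(j, l): np.empty((n, n)) for j in range(L) for l in range(L) if j != l}
    for j in range(L):
        for x in range(n):
            prof = p[:, j * n + x]
            s_prime[j][x] = prof[j * n:(j + 1) * n]
            for l in range(L):
                if l != j:
                    cross[(j, l)][x] = prof[l * n:(l + 1) * n]
    s_fusion = sum(sp + sp.T for sp in s_prime) / (2.0 * L)
    return FusedResult(
        s_prime=s_prime,
        cross=cross,
        s_fusion=s_fusion,
        sample_ids=list(mx.sample_ids),
        iterations_per_seed=iters.tolist(),
    )
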