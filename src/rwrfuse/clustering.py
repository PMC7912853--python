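"""Spectral clustering of a fused network and cluster-number voting.

Subtypes are obtained by normalized spectral clustering of the sample
similarity matrix (symmetric normalized Laplacian, top-k eigenvectors,
row normalization, k-means). The number of clusters is recommended by
letting seven cluster-validity indexes — Ratkowsky–Lance, Tau, Silhouette,
C-index, SD-scat, SD-Dis, and Calinski–Harabasz — each vote for the k that
optimizes it over a scanned range, and reporting the two most-voted values.

Distance-based indexes (Silhouette, Tau, C-index) are scored on the
similarity-derived distances of :func:`similarity_to_distance` (log scale
by default, which undoes the exponential kernel's dynamic-range
compression); coordinate-based indexes (Ratkowsky–Lance,
Calinski–Harabasz, SD-scat, SD-Dis) use a classical-MDS embedding of those
distances, computed once per table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score

logger = logging.getLogger("rwrfuse")

#: index name -> whether the optimum is the maximum (True) or minimum (False)
VALIDITY_INDEXES: dict[str, bool] = {
    "ratkowsky_lance": True,
    "tau": True,
    "silhouette": True,
    "c_index": False,
    "sd_scat": False,
    "sd_dis": False,
    "calinski_harabasz": True,
}

KMEANS_RESTARTS = 20  # restarts per k-means run, best inertia kept


@dataclass
class ClusteringResult:
    """Cluster labels plus the spectral coordinates they were derived from."""

    labels: np.ndarray
    k: int
    embedding: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(np.unique(self.labels)) != self.k:
            raise ValueError(f"labels carry {len(np.unique(self.labels))} clusters, expected {self.k}")


@dataclass
class ValidityTable:
    """Per-(index, k) validity scores with per-index optima and the vote tally."""

    rows: pd.DataFrame  # columns: index, k, score
    optima: dict[str, int]
    votes: dict[int, int]
    recommended: list[int]

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


def _as_matrix(s) -> np.ndarray:
    return s.values if hasattr(s, "values") and not isinstance(s, np.ndarray) else np.asarray(s)


def spectral_embedding(s: np.ndarray, k: int) -> np.ndarray:
    """Top-k eigenvectors of the symmetrically normalized affinity, row-normalized.

    Self-affinity is removed before normalization: it carries no
    between-sample information, and keeping a unit self-loop hands every
    near-isolated sample a normalized-affinity eigenvalue of ~1, which
    pushes outlier-indicator eigenvectors ahead of the cluster structure.
    """
    s = np.array(s, dtype=float)
    np.fill_diagonal(s, 0.0)
    if (s < 0).any():
        raise ValueError("similarity matrix has negative entries")
    deg = np.maximum(s.sum(axis=1), np.finfo(float).tiny)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    m = s * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    m = (m + m.T) / 2.0
    n = s.shape[0]
    _, vecs = scipy.linalg.eigh(m, subset_by_index=(n - k, n - 1))
    u = vecs[:, ::-1]
    norms = np.linalg.norm(u, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return u / norms


def spectral_clustering(s, k: int, seed: int = 0) -> ClusteringResult:
    """Normalized spectral clustering of a similarity matrix; deterministic given seed."""
    sv = _as_matrix(s)
    n = sv.shape[0]
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must be in [2, n-1] = [2, {n - 1}], got {k}")
    emb = spectral_embedding(sv, k)
    km = KMeans(n_clusters=k, n_init=KMEANS_RESTARTS, random_state=seed)
    labels = km.fit_predict(emb)
    return ClusteringResult(labels=labels, k=k, embedding=emb)


#: exp(-_LOG_FLOOR) is the smallest similarity ratio distinguished by the
#: log-scale conversion; beyond it distances are capped.
_LOG_FLOOR = 700.0


def similarity_to_distance(s: np.ndarray, scale: str = "log") -> np.ndarray:
    """Convert a similarity matrix to a sample-pair distance matrix.

    ``scale="log"`` (default) uses d = sqrt(-log(S / max_offdiag(S))), which
    undoes the exponential kernel's compression: affinities of the scaled
    exponential family differ by many orders of magnitude, and on a linear
    scale almost every pair sits at distance ~1, flattening any geometry the
    validity indexes could measure. ``scale="linear"`` gives the plain
    d = 1 - S / max_offdiag(S). Both are zero-diagonal and symmetric.
    """
    s = np.asarray(s, dtype=float)
    off = s[~np.eye(s.shape[0], dtype=bool)]
    top = off.max()
    if top <= 0:
        raise ValueError("similarity matrix has no positive off-diagonal entry")
    if scale == "linear":
        d = 1.0 - s / top
        np.clip(d, 0.0, None, out=d)
    elif scale == "log":
        ratio = np.clip(s / top, np.exp(-_LOG_FLOOR), 1.0)
        d = np.sqrt(-np.log(ratio))
    else:
        raise ValueError(f"unknown scale {scale!r}")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def _mds_embedding(d: np.ndarray, max_dim: int = 10) -> np.ndarray:
    """Classical (Torgerson) MDS coordinates of a distance matrix."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = scipy.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > max(1e-12, 1e-9 * vals[0])
    keep[min(max_dim, n):] = False
    if not keep.any():
        keep[0] = True
        vals = np.maximum(vals, 0.0)
    return vecs[:, keep] * np.sqrt(np.maximum(vals[keep], 0.0))


# ---------------------------------------------------------------------------
# validity indexes (standard cluster-validity definitions)

def _within_between_masks(labels: np.ndarray) -> np.ndarray:
    same = labels[:, None] == labels[None, :]
    return same


def ratkowsky_lance_index(x: np.ndarray, labels: np.ndarray) -> float:
    """Mean over variables of sqrt(BGSS/TSS), divided by sqrt(k). Maximize."""
    k = len(np.unique(labels))
    grand = x.mean(axis=0)
    tss = ((x - grand) ** 2).sum(axis=0)
    bgss = np.zeros_like(tss)
    for c in np.unique(labels):
        xc = x[labels == c]
        bgss += len(xc) * (xc.mean(axis=0) - grand) ** 2
    ok = tss > 0
    if not ok.any():
        return 0.0
    sbar = np.sqrt(bgss[ok] / tss[ok]).mean()
    return float(sbar / np.sqrt(k))


def tau_index(d: np.ndarray, labels: np.ndarray) -> float:
    """Kendall-style concordance between pair distances and pair co-membership.

    s(+) counts (within, between) pair comparisons where the within-cluster
    distance is smaller, s(-) where it is larger; normalized by
    sqrt(Nb*Nw) * (Nt*(Nt-1)/2) with Nt the total pair count. Maximize.
    """
    iu = np.triu_indices_from(d, k=1)
    dist = d[iu]
    within = (labels[iu[0]] == labels[iu[1]])
    dw = np.sort(dist[within])
    db = np.sort(dist[~within])
    nw, nb = len(dw), len(db)
    if nw == 0 or nb == 0:
        return 0.0
    # for each within distance, count between distances strictly larger / smaller
    gt = nb - np.searchsorted(db, dw, side="right")  # db > dw  -> concordant
    lt = np.searchsorted(db, dw, side="left")        # db < dw  -> discordant
    s_plus = float(gt.sum())
    s_minus = float(lt.sum())
    nt = nw + nb
    denom = np.sqrt(nw * nb) * (nt * (nt - 1) / 2.0)
    return (s_plus - s_minus) / denom if denom > 0 else 0.0


def c_index(d: np.ndarray, labels: np.ndarray) -> float:
    """(Sw - Smin) / (Smax - Smin) over within-cluster pair distances. Minimize."""
    iu = np.triu_indices_from(d, k=1)
    dist = d[iu]
    within = labels[iu[0]] == labels[iu[1]]
    nw = int(within.sum())
    if nw == 0:
        return 0.0
    sw = float(dist[within].sum())
    srt = np.sort(dist)
    smin = float(srt[:nw].sum())
    smax = float(srt[-nw:].sum())
    if smax == smin:
        return 0.0
    return (sw - smin) / (smax - smin)


def sd_scat(x: np.ndarray, labels: np.ndarray) -> float:
    """Average cluster variance norm over the dataset variance norm. Minimize."""
    total = np.linalg.norm(x.var(axis=0))
    if total == 0:
        return 0.0
    cl = np.unique(labels)
    scat = sum(np.linalg.norm(x[labels == c].var(axis=0)) for c in cl) / (len(cl) * total)
    return float(scat)


def sd_dis(x: np.ndarray, labels: np.ndarray) -> float:
    """Total separation of cluster centroids: (Dmax/Dmin) * sum_i 1/sum_j ||c_i-c_j||. Minimize."""
    cl = np.unique(labels)
    cents = np.stack([x[labels == c].mean(axis=0) for c in cl])
    dd = np.linalg.norm(cents[:, None, :] - cents[None, :, :], axis=2)
    off = dd[~np.eye(len(cl), dtype=bool)]
    dmax, dmin = off.max(), off.min()
    if dmin == 0:
        return np.inf
    return float(dmax / dmin * (1.0 / dd.sum(axis=1)).sum())


def validity_index_table(s, k_range=range(2, 9), seed: int = 0) -> ValidityTable:
    """Score every candidate k with the seven validity indexes and tally votes.

    Each index votes for its own optimum (respecting its max/min direction);
    the two most-voted cluster numbers are recommended, ties resolved toward
    smaller k.
    """
    sv = _as_matrix(s)
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    n = sv.shape[0]
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    d = similarity_to_distance(sv)
    x = _mds_embedding(d)
    records = []
    for k in ks:
        labels = spectral_clustering(sv, k, seed=seed).labels
        scores = {
            "ratkowsky_lance": ratkowsky_lance_index(x, labels),
            "tau": tau_index(d, labels),
            "silhouette": float(silhouette_score(d, labels, metric="precomputed")),
            "c_index": c_index(d, labels),
            "sd_scat": sd_scat(x, labels),
            "sd_dis": sd_dis(x, labels),
            "calinski_harabasz": float(calinski_harabasz_score(x, labels)),
        }
        for name, score in scores.items():
            records.append({"index": name, "k": k, "score": score})
    rows = pd.DataFrame.from_records(records)
    optima = {}
    for name, maximize in VALIDITY_INDEXES.items():
        sub = rows[rows["index"] == name]
        pick = sub.loc[sub["score"].idxmax() if maximize else sub["score"].idxmin(), "k"]
        optima[name] = int(pick)
    votes: dict[int, int] = {}
    for k in optima.values():
        votes[k] = votes.get(k, 0) + 1
    table = ValidityTable(rows=rows, optima=optima, votes=votes, recommended=[])
    table.recommended = recommend_k(table)
    return table


def recommend_k(t: ValidityTable) -> list[int]:
    """The two most-voted cluster numbers, descending by votes, ties to smaller k."""
    ranked = sorted(t.votes.items(), key=lambda kv: (-kv[1], kv[0]))
    return [k for k, _ in ranked[:2]]
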