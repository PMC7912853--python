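"""Clustering and survival evaluation: Dunn index, NMI, log-rank, feature ranking.

The Dunn index scores a partition by the worst-case ratio of between-cluster
separation to within-cluster spread,

    DI = min_{k != l} dist(C_k, C_l) / max_m diam(C_m),

with dist(C_k, C_l) the distance of the closest pair across the two clusters
and diam(C_m) the largest within-cluster distance; larger is better.

Feature importance is scored per feature: a similarity network is built from
that feature alone, spectral-clustered at the reference k, and the NMI of
the resulting labels against the reference subtypes is the feature's score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from sklearn.metrics import normalized_mutual_info_score

from .clustering import ClusteringResult, spectral_clustering
from .data_io import FeatureMatrix, SurvivalData
from .similarity import KernelParams, pairwise_distances, similarity_network

logger = logging.getLogger("rwrfuse")


def dunn_index(labels: np.ndarray | ClusteringResult, d: np.ndarray,
               singleton_infinite: bool = False) -> float:
    """Dunn index of a partition under a precomputed distance matrix.

    ``singleton_infinite`` controls the degenerate all-zero-diameter case:
    return ``inf`` instead of raising.
    """
    if isinstance(labels, ClusteringResult):
        labels = labels.labels
    labels = np.asarray(labels)
    d = np.asarray(d, dtype=float)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("Dunn index needs at least two clusters")
    masks = [labels == c for c in clusters]
    max_diam = 0.0
    for mk in masks:
        sub = d[np.ix_(mk, mk)]
        if sub.size > 1:
            max_diam = max(max_diam, float(sub.max()))
    if max_diam == 0.0:
        if singleton_infinite:
            return np.inf
        raise ValueError("all clusters have zero diameter; Dunn index undefined")
    min_sep = np.inf
    for a in range(len(masks)):
        for b in range(a + 1, len(masks)):
            min_sep = min(min_sep, float(d[np.ix_(masks[a], masks[b])].min()))
    return min_sep / max_diam


def nmi(a, b, variant: str = "arithmetic") -> float:
    """Normalized mutual information between two labelings, in [0, 1].

    ``variant`` chooses the entropy normalization: ``"arithmetic"`` (default)
    or ``"sqrt"`` (geometric mean). Invariant to label renaming.
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    if variant not in ("arithmetic", "sqrt"):
        raise ValueError(f"unknown NMI variant {variant!r}")
    return float(normalized_mutual_info_score(a, b, average_method=variant))


def logrank_test(labels: np.ndarray | ClusteringResult, surv: SurvivalData,
                 sample_ids: list[str] | None = None) -> float:
    """Multi-group log-rank p-value for survival differences between clusters.

    ``sample_ids`` gives the ordering of ``labels``; every labeled sample
    must appear in the survival table.
    """
    if isinstance(labels, ClusteringResult):
        labels = labels.labels
    labels = np.asarray(labels)
    if sample_ids is None:
        if len(labels) != len(surv.sample_ids):
            raise ValueError("labels and survival table differ in length; pass sample_ids")
        sample_ids = surv.sample_ids
    lookup = {s: i for i, s in enumerate(surv.sample_ids)}
    missing = [s for s in sample_ids if s not in lookup]
    if missing:
        raise ValueError(f"samples absent from survival table: {missing[:5]}")
    idx = [lookup[s] for s in sample_ids]
    times, events = surv.time[idx], surv.event[idx]
    if events.sum() == 0:
        raise ValueError("no events observed; log-rank test undefined")
    res = multivariate_logrank_test(times, labels, events)
    return float(res.p_value)


@dataclass
class FeatureRanking:
    """Per-feature NMI scores against reference subtypes, best first."""

    rows: pd.DataFrame  # columns: layer_name, feature_id, nmi_score

    def top(self, n: int) -> pd.DataFrame:
        return self.rows.head(n)

    def top_fraction_within_layer(self, layer_name: str, fraction: float) -> pd.DataFrame:
        sub = self.rows[self.rows["layer_name"] == layer_name]
        n = max(1, int(np.ceil(fraction * len(sub))))
        return sub.head(n)


def rank_features(omics: list[FeatureMatrix], reference: ClusteringResult,
                  params: KernelParams | None = None, k: int | None = None,
                  seed: int = 0, skip_constant: bool = True) -> FeatureRanking:
    """Rank every feature of every layer by single-feature clustering agreement.

    For each feature, a one-dimensional similarity network is built with the
    same kernel as the full layers, spectral-clustered at the reference k,
    and scored by NMI against the reference labels. Constant features carry
    no partition information and are skipped by default (scored 0 if kept).
    """
    params = params or KernelParams()
    k = k or reference.k
    ref = reference.labels
    records = []
    for m in omics:
        if m.n_samples != len(ref):
            raise ValueError(f"layer {m.layer_name!r} has {m.n_samples} samples, labels have {len(ref)}")
        for i, fid in enumerate(m.feature_ids):
            row = m.values[i]
            if np.all(row == row[0]):
                if skip_constant:
                    logger.warning("skipping constant feature %s/%s", m.layer_name, fid)
                    continue
                records.append({"layer_name": m.layer_name, "feature_id": fid, "nmi_score": 0.0})
                continue
            one = FeatureMatrix(values=row[None, :], feature_ids=[fid],
                                sample_ids=m.sample_ids, layer_name=m.layer_name)
            s = similarity_network(pairwise_distances(one), params, layer_name=m.layer_name)
            labels = spectral_clustering(s.values, k, seed=seed).labels
            records.append({"layer_name": m.layer_name, "feature_id": fid,
                            "nmi_score": nmi(labels, ref)})
    rows = pd.DataFrame.from_records(records)
    rows = rows.sort_values(["nmi_score", "layer_name", "feature_id"],
                            ascending=[False, True, True], kind="stable").reset_index(drop=True)
    return FeatureRanking(rows=rows)
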