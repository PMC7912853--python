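"""Reading, writing, and preprocessing of feature-by-sample omics matrices.

One :class:`FeatureMatrix` holds one omics layer (e.g. mRNA expression, DNA
methylation beta values, miRNA expression) as a features x samples numeric
array with missing entries allowed. The preprocessing chain mirrors the usual
multi-omics hygiene steps:

1. keep only samples present in every layer (:func:`align_samples`),
2. drop samples, then features, with more than 20 % missing values
   (:func:`filter_missingness`),
3. impute remaining gaps with the per-feature mean over observed samples
   (:func:`impute_missing`),
4. standardize every feature to mean 0, standard deviation 1
   (:func:`normalize_features`).

:func:`preprocess` runs the whole chain over a list of layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("rwrfuse")

#: cell values treated as missing when reading delimited text (case-insensitive)
DEFAULT_NA_TOKENS = ("", "na", "nan", "null")


@dataclass
class FeatureMatrix:
    """One omics layer: a features x samples matrix with aligned identifiers.

    Parameters
    ----------
    values
        2-D float array, shape ``(n_features, n_samples)``; ``NaN`` marks a
        missing measurement.
    feature_ids, sample_ids
        Unique identifiers, in storage order.
    layer_name
        Free-text label for the omics layer (used in reports and rankings).
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    layer_name: str = "layer"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} feature ids x {len(self.sample_ids)} sample ids"
            )
        for label, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValueError(f"duplicate {label} ids: {dupes[:5]}")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_feature_matrix(
    path: str | Path,
    orientation: str = "features-by-samples",
    layer_name: str | None = None,
    na_tokens: Sequence[str] = DEFAULT_NA_TOKENS,
) -> FeatureMatrix:
    """Read a delimited feature matrix (TSV/CSV chosen by file extension).

    The file must have a header row of sample ids and a first column of
    feature ids (or the transpose with ``orientation="samples-by-features"``).
    Empty cells and ``na_tokens`` (case-insensitive) become missing values;
    any other non-numeric cell raises with its row and column named.
    """
    path = Path(path)
    if orientation not in ("features-by-samples", "samples-by-features"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split(sep)[1:]
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise ValueError(f"duplicate column ids in {path}: {dupes[:5]}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if orientation == "samples-by-features":
        df = df.T
    na = {t.lower() for t in na_tokens} | {""}

    def parse_cell(cell: str, row: str, col: str) -> float:
        s = cell.strip()
        if s.lower() in na:
            return np.nan
        try:
            return float(s)
        except ValueError:
            raise ValueError(
                f"non-numeric cell {cell!r} at feature {row!r}, sample {col!r} in {path}"
            ) from None

    values = np.empty(df.shape, dtype=float)
    cols = list(df.columns)
    for i, (ridx, row) in enumerate(df.iterrows()):
        for j, c in enumerate(cols):
            values[i, j] = parse_cell(row.iloc[j], str(ridx), str(c))
    return FeatureMatrix(
        values=values,
        feature_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in cols],
        layer_name=layer_name or path.stem,
    )


def write_feature_matrix(m: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as delimited text (TSV unless ``.csv``)."""
    path = Path(path)
    m.to_frame().to_csv(path, sep=_sep_for(path), na_rep="NA")


def align_samples(matrices: Sequence[FeatureMatrix]) -> list[FeatureMatrix]:
    """Restrict every layer to the samples measured in all layers.

    The shared samples keep the order they have in the first layer; every
    output has identical ``sample_ids``.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two layers to align")
    shared = set(matrices[0].sample_ids)
    for m in matrices[1:]:
        shared &= set(m.sample_ids)
    if not shared:
        raise ValueError("no sample is present in every layer")
    order = [s for s in matrices[0].sample_ids if s in shared]
    out = []
    for m in matrices:
        idx = [m.sample_ids.index(s) for s in order]
        out.append(replace(m, values=m.values[:, idx], sample_ids=list(order)))
    return out


def filter_missingness(
    m: FeatureMatrix,
    sample_thresh: float = 0.2,
    feature_thresh: float = 0.2,
) -> FeatureMatrix:
    """Drop samples, then features, whose missing fraction strictly exceeds 20 %.

    Samples are filtered first; feature missing fractions are then
    recomputed on the surviving samples. Because each removal changes the
    other dimension's fractions, the two steps are repeated until nothing
    more is removed, so the operation is idempotent.
    """
    for name, t in (("sample_thresh", sample_thresh), ("feature_thresh", feature_thresh)):
        if not 0 < t <= 1:
            raise ValueError(f"{name} must be in (0, 1], got {t}")
    vals = m.values
    f_ids, s_ids = list(m.feature_ids), list(m.sample_ids)
    while True:
        keep_s = np.isnan(vals).mean(axis=0) <= sample_thresh
        if not keep_s.any():
            raise ValueError("every sample exceeds the missingness threshold")
        vals = vals[:, keep_s]
        s_ids = [s for s, k in zip(s_ids, keep_s) if k]
        keep_f = np.isnan(vals).mean(axis=1) <= feature_thresh
        if not keep_f.any():
            raise ValueError("every feature exceeds the missingness threshold")
        vals = vals[keep_f]
        f_ids = [f for f, k in zip(f_ids, keep_f) if k]
        if keep_s.all() and keep_f.all():
            break
    return replace(m, values=vals, feature_ids=f_ids, sample_ids=s_ids)


def impute_missing(m: FeatureMatrix) -> FeatureMatrix:
    """Fill each missing cell with the mean of the feature over observed samples."""
    vals = m.values.copy()
    miss = np.isnan(vals)
    if not miss.any():
        return replace(m, values=vals)
    fully_missing = miss.all(axis=1)
    if fully_missing.any():
        bad = [f for f, b in zip(m.feature_ids, fully_missing) if b]
        raise ValueError(f"features with no observed value (filter first): {bad[:5]}")
    means = np.nanmean(vals, axis=1)
    rows, cols = np.nonzero(miss)
    vals[rows, cols] = means[rows]
    return replace(m, values=vals)


def normalize_features(m: FeatureMatrix, ddof: int = 0) -> FeatureMatrix:
    """Standardize every feature to mean 0 and standard deviation 1.

    Uses the population standard deviation by default (``ddof=0``).
    Zero-variance features carry no between-sample information and are
    dropped with a warning.
    """
    if np.isnan(m.values).any():
        raise ValueError("impute missing values before normalizing")
    mu = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, ddof=ddof, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.all():
        dropped = [f for f, k in zip(m.feature_ids, keep) if not k]
        logger.warning(
            "dropping %d zero-variance feature(s) in layer %s: %s%s",
            len(dropped), m.layer_name, dropped[:5], "..." if len(dropped) > 5 else "",
        )
    if not keep.any():
        raise ValueError("all features have zero variance")
    vals = (m.values[keep] - mu[keep]) / sd[keep]
    return replace(m, values=vals, feature_ids=[f for f, k in zip(m.feature_ids, keep) if k])


def preprocess(
    matrices: Sequence[FeatureMatrix],
    sample_thresh: float = 0.2,
    feature_thresh: float = 0.2,
    ddof: int = 0,
) -> list[FeatureMatrix]:
    """Full preprocessing chain: align, filter, impute, standardize.

    Missingness filtering can remove samples per layer, so layers are
    re-aligned after filtering to restore a shared sample set.
    """
    layers = align_samples(matrices)
    layers = [filter_missingness(m, sample_thresh, feature_thresh) for m in layers]
    if any(m.sample_ids != layers[0].sample_ids for m in layers[1:]):
        layers = align_samples(layers)
    layers = [impute_missing(m) for m in layers]
    return [normalize_features(m, ddof=ddof) for m in layers]


@dataclass
class SurvivalData:
    """Right-censored survival records aligned with clustering labels."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if not (len(self.sample_ids) == len(self.time) == len(self.event)):
            raise ValueError("sample_ids, time and event must have equal length")
        if (self.time < 0).any():
            raise ValueError("survival times must be nonnegative")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0 (censored) or 1 (event)")


def read_survival(path: str | Path) -> SurvivalData:
    """Read a survival table: TSV/CSV with columns sample_id, time, event."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"survival table needs columns {sorted(required)}, got {list(df.columns)}")
    return SurvivalData(
        sample_ids=df["sample_id"].astype(str).tolist(),
        time=df["time"].to_numpy(),
        event=df["event"].to_numpy(),
    )


def write_matrix_tsv(values: np.ndarray, ids: Iterable[str], path: str | Path) -> None:
    """Write a square sample-by-sample matrix (similarity or distance) as TSV."""
    ids = list(ids)
    pd.DataFrame(values, index=ids, columns=ids).to_csv(Path(path), sep="\t")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a square matrix TSV written by :func:`write_matrix_tsv`."""
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]
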