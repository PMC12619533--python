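"""Composition analysis: class proportions, Hellinger ordination, presence
thresholds, and UpSet-style intersection counts.

The Hellinger transform (square root of relative abundance) makes Euclidean
distance between samples equal the Hellinger distance, which damps the
influence of a few dominant species before PCA or clustering of community
data.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .spectra import sample_columns as _raw_sample_columns

_NON_SAMPLE = {"lipid_class", "subclass", "rf_source", "mz", "rt", "spectrum_id"}


def sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in _raw_sample_columns(table) if c not in _NON_SAMPLE]


def class_proportions(
    calibrated: pd.DataFrame,
    min_major_fraction: float = 0.01,
    class_col: str = "lipid_class",
) -> pd.DataFrame:
    """Per-sample lipid-class fractions, lumping minor classes into "other".

    A class is lumped when its median fraction across samples falls below
    ``min_major_fraction`` (default 1%). Columns sum to 1.
    """
    if calibrated.empty:
        raise ValueError("empty calibrated table")
    samples = sample_columns(calibrated)
    totals = calibrated[samples].sum(axis=0)
    zero = [s for s in samples if not totals[s] > 0]
    if zero:
        raise ValueError(f"sample(s) with zero total quantified lipids: {zero}")
    by_class = calibrated.groupby(class_col)[samples].sum()
    frac = by_class / totals
    minor = frac.median(axis=1) < min_major_fraction
    out = frac.loc[~minor].copy()
    out.loc["other"] = frac.loc[minor].sum(axis=0) if minor.any() else 0.0
    return out.sort_index()


def hellinger_transform(abundance: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """sqrt(cell / row sum); rows are samples. All-zero rows stay zero."""
    values = np.asarray(abundance, dtype=float)
    if (values < 0).any():
        raise ValueError("Hellinger transform requires non-negative input")
    sums = values.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(np.where(sums > 0, values / np.where(sums > 0, sums, 1.0), 0.0))
    if isinstance(abundance, pd.DataFrame):
        return pd.DataFrame(out, index=abundance.index, columns=abundance.columns)
    return out


def hellinger_distance(row_a: np.ndarray, row_b: np.ndarray) -> float:
    """Direct Hellinger distance between two abundance rows."""
    a = np.asarray(row_a, float)
    b = np.asarray(row_b, float)
    pa = a / a.sum() if a.sum() > 0 else a
    pb = b / b.sum() if b.sum() > 0 else b
    return float(np.sqrt(np.sum((np.sqrt(pa) - np.sqrt(pb)) ** 2)))


def pca_scores(matrix: pd.DataFrame | np.ndarray, n_components: int = 2):
    """PCA of the column-centred matrix with a fixed sign convention.

    Returns (scores, loadings, explained_variance_ratio). Each loading
    vector's largest-magnitude entry is made positive so results are
    reproducible across runs. ``n_components`` beyond the matrix rank is
    truncated with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    k = min(n_components, rank, min(X.shape))
    if k < n_components:
        warnings.warn(f"n_components truncated from {n_components} to rank {k}")
    k = max(k, 1)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1.0
            scores[:, i] *= -1.0
    return scores, loadings, pca.explained_variance_ratio_


def presence_matrix(
    calibrated: pd.DataFrame,
    threshold_fraction: float = 0.0002,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Boolean species × sample (or × group) presence matrix.

    A species is present in a sample when its fraction of that sample's
    summed quantified lipids is at least ``threshold_fraction`` (the 0.02%
    rule; the boundary is inclusive). With ``groups`` (name → sample list),
    a species is present in a group when present in at least one member.
    """
    if threshold_fraction < 0:
        raise ValueError("threshold_fraction must be >= 0")
    samples = sample_columns(calibrated)
    vals = calibrated[samples].astype(float)
    totals = vals.sum(axis=0)
    frac = vals / totals.where(totals > 0, 1.0)
    present = frac >= threshold_fraction
    if groups is None:
        return present
    out = pd.DataFrame(index=calibrated.index)
    for gname, members in groups.items():
        out[gname] = present[list(members)].any(axis=1)
    return out


def intersection_counts(presence_by_group: pd.DataFrame) -> dict[frozenset, int]:
    """Species counts per exact group combination (UpSet cells).

    Keys are frozensets of group names; a species counts in exactly the cell
    of groups where it is present. Species absent everywhere are not counted.
    """
    if presence_by_group.shape[1] < 1:
        raise ValueError("need at least one group")
    counts: dict[frozenset, int] = {}
    groups = list(presence_by_group.columns)
    for combo_size in range(1, len(groups) + 1):
        for combo in combinations(groups, combo_size):
            counts[frozenset(combo)] = 0
    for _, row in presence_by_group.iterrows():
        where = frozenset(g for g in groups if bool(row[g]))
        if where:
            counts[where] += 1
    return counts


def sum_counts(count_map: Mapping[str, int]) -> int:
    """Plain summation over a labelled count map (e.g. subclass totals)."""
    return int(sum(int(v) for v in count_map.values()))


def exclusive_counts(counts: Mapping[frozenset, int], group: str) -> int:
    """Species found only in ``group`` (the UpSet singleton cell)."""
    return counts.get(frozenset([group]), 0)


def hierarchical_clustering(abundance: pd.DataFrame, method: str = "average"):
    """Average-linkage clustering of samples on Hellinger distance.

    Rows of ``abundance`` are samples. Returns (linkage matrix, 2-cluster
    labels in row order).
    """
    transformed = hellinger_transform(abundance)
    dist = pdist(np.asarray(transformed, float), metric="euclidean")
    z = hierarchy.linkage(dist, method=method)
    labels = hierarchy.fcluster(z, t=2, criterion="maxclust")
    return z, labels
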