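"""Agglomerative clustering of seas by gene-cluster abundance patterns.

Seas are compared through symmetrized Kullback–Leibler distances between
their normalized abundance profiles over an informative subset of gene
clusters (entropy in the lowest 25%, total reads in the top 75%), and merged
by agglomerative nesting with group-average (UPGMA) linkage.  The strength of
the recovered structure is summarized by the agglomerative coefficient

    AC = mean_i (1 - m_i / m_final),

where m_i is the dissimilarity at which item i first merges and m_final the
height of the last merge; AC ranges from 0 (no structure) to 1 (clear
structure), and is 0 by construction for two items.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .ecotypes import kl_divergence
from .enrichment import sea_columns


def select_clustering_features(
    rna_table: pd.DataFrame,
    entropy_percentile: float = 25.0,
    count_percentile: float = 75.0,
) -> list[str]:
    """Clusters with entropy in the lowest ``entropy_percentile``% and total
    reads in the top ``count_percentile``% (boundaries inclusive)."""
    if rna_table.empty:
        raise ValueError("empty r.n.a. table")
    entropy = rna_table["entropy"].to_numpy()
    totals = rna_table["total_reads"].to_numpy()
    e_cut = np.percentile(entropy, entropy_percentile)
    c_cut = np.percentile(totals, 100.0 - count_percentile)
    keep = (entropy <= e_cut) & (totals >= c_cut)
    chosen = list(rna_table.index[keep])
    if not chosen:
        raise ValueError(
            "no gene clusters satisfy the feature-selection thresholds; "
            "relax entropy_percentile / count_percentile"
        )
    return chosen


def sea_dissimilarity(
    counts: pd.DataFrame,
    subset: list[str] | None = None,
    eps: float = 1e-6,
    symmetrize: bool = True,
) -> pd.DataFrame:
    """Pairwise KL dissimilarity between sea abundance profiles.

    ``counts`` is the sea-aggregated clusters x seas count matrix.  Each
    sea's per-sample normalized abundances over ``subset`` (all clusters if
    None), renormalized to sum to 1, form its profile p_s; then
    D[s,t] = ½(KL(p_s||p_t) + KL(p_t||p_s)) on eps-smoothed vectors
    (or the one-directional KL(p_s||p_t) with ``symmetrize=False``).
    """
    sub = counts if subset is None else counts.loc[subset]
    totals = sub.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            f"sea with all-zero abundance over the selected clusters: {list(zero.index)}"
        )
    P = (sub / totals).T.to_numpy(dtype=float)  # seas x clusters
    seas = list(sub.columns)
    n = len(seas)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = kl_divergence(P[i], P[j], eps=eps)
            if symmetrize:
                D[i, j] = 0.5 * (d + kl_divergence(P[j], P[i], eps=eps))
            else:
                D[i, j] = d
    return pd.DataFrame(D, index=seas, columns=seas)


@dataclass
class Dendrogram:
    """Merge tree over samples with heights and the agglomerative coefficient.

    ``merges`` lists (members_A, members_B, height) in merge order;
    ``linkage_matrix`` is the scipy-format (n-1) x 4 matrix over ``labels``.
    """

    labels: list[str]
    merges: list[tuple[frozenset, frozenset, float]]
    linkage_matrix: np.ndarray
    agglomerative_coefficient: float

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]


def _first_merge_heights(Z: np.ndarray, n: int) -> np.ndarray:
    """Height at which each original item first joins a cluster."""
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    first = np.full(n, np.nan)
    for k, (a, b, h, _) in enumerate(Z):
        merged = members.pop(int(a)) + members.pop(int(b))
        for i in merged:
            if np.isnan(first[i]):
                first[i] = h
        members[n + k] = merged
    # singletons never merge only when n == 1
    return first


def agnes(dissimilarity: pd.DataFrame) -> Dendrogram:
    """Agglomerative nesting with group-average linkage on a dissimilarity matrix.

    Requires a square symmetric non-negative matrix with zero diagonal and
    at least two items.  Merge heights are non-decreasing (average linkage
    is monotone); the agglomerative coefficient averages 1 - m_i/m_final
    over items.
    """
    D = dissimilarity.to_numpy(dtype=float)
    labels = list(dissimilarity.index)
    n = len(labels)
    if D.shape != (n, n) or list(dissimilarity.columns) != labels:
        raise ValueError("dissimilarity must be square with matching labels")
    if n < 2:
        raise ValueError("at least 2 items are required")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if (D < 0).any() or not np.allclose(np.diag(D), 0.0):
        raise ValueError("dissimilarity must be non-negative with zero diagonal")

    Z = linkage(squareform(D, checks=False), method="average")
    first = _first_merge_heights(Z, n)
    m_final = Z[-1, 2]
    ac = float(np.mean(1.0 - first / m_final)) if m_final > 0 else 0.0

    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    merges = []
    for k, (a, b, h, _) in enumerate(Z):
        A, B = members[int(a)], members[int(b)]
        merges.append((A, B, float(h)))
        members[n + k] = A | B
    return Dendrogram(
        labels=labels,
        merges=merges,
        linkage_matrix=Z,
        agglomerative_coefficient=ac,
    )


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick string with ultrametric branch lengths (leaf depth = final height / 2)."""
    Z = dendrogram.linkage_matrix
    labels = dendrogram.labels
    n = len(labels)
    height = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = Z[i - n]
        h2 = h / 2.0
        la = node(int(a))
        lb = node(int(b))
        return f"({la}:{h2 - height[int(a)]:.10g},{lb}:{h2 - height[int(b)]:.10g})"

    for k, (a, b, h, _) in enumerate(Z):
        height[n + k] = h / 2.0
    return node(n + len(Z) - 1) + ";"


class SeaClusterer:
    """Estimator wrapper: feature selection -> KL dissimilarity -> AGNES.

    Parameters mirror the underlying functions.  After ``fit(counts,
    rna_table)``: ``features_`` (selected cluster ids), ``dissimilarity_``
    (DataFrame), ``dendrogram_`` and ``agglomerative_coefficient_``.
    """

    def __init__(
        self,
        entropy_percentile: float = 25.0,
        count_percentile: float = 75.0,
        eps: float = 1e-6,
        symmetrize: bool = True,
    ):
        self.entropy_percentile = entropy_percentile
        self.count_percentile = count_percentile
        self.eps = eps
        self.symmetrize = symmetrize

    def get_params(self, deep: bool = True) -> dict:
        return {
            "entropy_percentile": self.entropy_percentile,
            "count_percentile": self.count_percentile,
            "eps": self.eps,
            "symmetrize": self.symmetrize,
        }

    def set_params(self, **params) -> "SeaClusterer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, counts: pd.DataFrame, rna_table: pd.DataFrame) -> "SeaClusterer":
        self.features_ = select_clustering_features(
            rna_table, self.entropy_percentile, self.count_percentile
        )
        self.dissimilarity_ = sea_dissimilarity(
            counts, self.features_, eps=self.eps, symmetrize=self.symmetrize
        )
        self.dendrogram_ = agnes(self.dissimilarity_)
        self.agglomerative_coefficient_ = self.dendrogram_.agglomerative_coefficient
        return self
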