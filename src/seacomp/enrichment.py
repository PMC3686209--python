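"""Relative normalized abundance, Shannon entropy, and enrichment calling.

The central statistic is the *relative normalized abundance* (r.n.a.): read
counts per gene cluster are first normalized within each sea to the total
recruited reads of that sea, and the resulting fractions are then normalized
across the seas within each cluster, so every cluster's r.n.a. vector sums
to 1 over the seas.  It answers "how is this cluster's abundance distributed
among the seas, library sizes aside?".  The Shannon entropy (natural log) of
that vector flags clusters concentrated in few seas.

A cluster is called over- (under-) represented in a sea when three percentile
conditions hold simultaneously: its r.n.a. for that sea is in the top
(bottom) 10% of clusters, its entropy is in the lowest 15% (Prochlorococcus,
SAR11) or 25% (cyanophage), and its total read count across all seas is in
the top 75%.  Clusters with 20 or fewer total reads are removed before any
normalization.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy
from sklearn.base import BaseEstimator

RNA_META_COLUMNS = ("entropy", "total_reads", "retained")

#: entropy percentile by taxon group: a looser cutoff for cyanophage, whose
#: gene clusters are fewer and patchier across phage types
ENTROPY_PERCENTILE = {"prochlorococcus": 15.0, "sar11": 15.0, "cyanophage": 25.0}

MIN_TOTAL_READS = 21  # "20 or less" removed


def shannon_entropy(p: Sequence[float], atol: float = 1e-9) -> float:
    """Shannon entropy H = -sum p_i ln p_i (nats), with 0·ln0 = 0.

    ``p`` must be a probability vector: entries in [0, 1] and summing to 1
    within ``atol``.  Printed 3-decimal vectors can be checked with a looser
    ``atol``.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a nonempty 1-D vector")
    if (p < -atol).any() or (p > 1 + atol).any():
        raise ValueError("p entries must lie in [0, 1]")
    if abs(p.sum() - 1.0) > atol:
        raise ValueError(f"p must sum to 1 (got {p.sum():.6f})")
    return float(-xlogy(p, p).sum() + 0.0)  # +0.0 avoids returning -0.0


def filter_low_count(
    matrix: pd.DataFrame, min_total: int = MIN_TOTAL_READS
) -> tuple[pd.DataFrame, list[str]]:
    """Drop clusters whose total count across all columns is below ``min_total``.

    Returns (filtered matrix, removed cluster ids).  The default boundary
    retains totals of 21 and removes 20.
    """
    if matrix.empty:
        warnings.warn("empty count matrix passed to filter_low_count")
        return matrix, []
    totals = matrix.sum(axis=1)
    keep = totals >= min_total
    removed = list(matrix.index[~keep])
    return matrix.loc[keep], removed


def relative_normalized_abundance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Two-stage r.n.a. table from a clusters x seas count matrix.

    rna[g, s] = (c[g,s] / T_s) / sum_s' (c[g,s'] / T_s'), with T_s the total
    count of sea s over the (already filtered) clusters.  Returns a DataFrame
    with one column per sea plus ``entropy``, ``total_reads`` and
    ``retained``.
    """
    totals = matrix.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sea with zero total recruited reads: {list(zero.index)}")
    frac = matrix / totals
    denom = frac.sum(axis=1)
    if (denom <= 0).any():
        raise ValueError("cluster with zero counts in every sea; filter first")
    rna = frac.div(denom, axis=0)
    out = rna.copy()
    out["entropy"] = [shannon_entropy(row) for row in rna.to_numpy()]
    out["total_reads"] = matrix.sum(axis=1).astype(int)
    out["retained"] = True
    return out


def build_rna_table(
    matrix: pd.DataFrame, min_total: int = MIN_TOTAL_READS
) -> tuple[pd.DataFrame, list[str]]:
    """Low-count filter followed by r.n.a. normalization.

    Returns (RnaTable over retained clusters, removed cluster ids).
    """
    kept, removed = filter_low_count(matrix, min_total=min_total)
    if kept.empty:
        warnings.warn("no clusters retained after the low-count filter")
        cols = list(matrix.columns) + list(RNA_META_COLUMNS)
        return pd.DataFrame(columns=cols), removed
    return relative_normalized_abundance(kept), removed


def sea_columns(rna_table: pd.DataFrame) -> list[str]:
    return [c for c in rna_table.columns if c not in RNA_META_COLUMNS]


class EnrichmentCaller(BaseEstimator):
    """Percentile-threshold caller for over/under-represented gene clusters.

    Parameters
    ----------
    taxon_group : "prochlorococcus" | "sar11" | "cyanophage"
        Sets the entropy percentile (15 / 15 / 25) unless
        ``entropy_percentile`` is given explicitly.
    rna_percentile : float, default 10.0
        A cluster's r.n.a. must be in the top (over) or bottom (under) this
        percent of clusters for the sea.
    count_percentile : float, default 75.0
        Total read count must be in the top this percent.
    pooled_rna : bool, default False
        Rank r.n.a. against the pooled values of all seas instead of each
        sea's own distribution.

    All percentile conditions are inclusive at the boundary (ties qualify);
    percentiles use linear interpolation.  In addition, a cluster whose
    r.n.a. vector is perfectly even (entropy = ln n_seas) is never called:
    the entropy screen exists to select *nonuniform* distributions.

    Attributes (after ``fit``)
    --------------------------
    thresholds_ : dict of the realized cutoffs.
    calls_ : DataFrame with columns cluster_id, sea, direction.
    """

    def __init__(
        self,
        taxon_group: str = "prochlorococcus",
        rna_percentile: float = 10.0,
        entropy_percentile: float | None = None,
        count_percentile: float = 75.0,
        pooled_rna: bool = False,
    ):
        self.taxon_group = taxon_group
        self.rna_percentile = rna_percentile
        self.entropy_percentile = entropy_percentile
        self.count_percentile = count_percentile
        self.pooled_rna = pooled_rna

    def _entropy_pct(self) -> float:
        if self.entropy_percentile is not None:
            return float(self.entropy_percentile)
        try:
            return ENTROPY_PERCENTILE[self.taxon_group]
        except KeyError:
            raise ValueError(f"unknown taxon group {self.taxon_group!r}") from None

    def fit(self, rna_table: pd.DataFrame, y=None) -> "EnrichmentCaller":
        if rna_table.empty:
            raise ValueError("empty r.n.a. table")
        seas = sea_columns(rna_table)
        if len(rna_table) < 10:
            warnings.warn(
                f"only {len(rna_table)} retained clusters; percentile "
                "thresholds are unstable"
            )
        entropy = rna_table["entropy"].to_numpy()
        totals = rna_table["total_reads"].to_numpy()
        e_cut = float(np.percentile(entropy, self._entropy_pct()))
        c_cut = float(np.percentile(totals, 100.0 - self.count_percentile))
        h_max = np.log(len(seas))
        nonuniform = entropy < h_max - 1e-12

        thresholds = {
            "entropy_max": e_cut,
            "total_reads_min": c_cut,
            "rna_percentile": self.rna_percentile,
            "entropy_percentile": self._entropy_pct(),
            "count_percentile": self.count_percentile,
        }
        pooled = rna_table[seas].to_numpy().ravel()
        calls = []
        for sea in seas:
            vals = pooled if self.pooled_rna else rna_table[sea].to_numpy()
            hi = float(np.percentile(vals, 100.0 - self.rna_percentile))
            lo = float(np.percentile(vals, self.rna_percentile))
            thresholds[f"rna_hi[{sea}]"] = hi
            thresholds[f"rna_lo[{sea}]"] = lo
            col = rna_table[sea].to_numpy()
            base = (entropy <= e_cut) & nonuniform & (totals >= c_cut)
            for cid in rna_table.index[(col >= hi) & base]:
                calls.append((cid, sea, "over"))
            for cid in rna_table.index[(col <= lo) & base]:
                calls.append((cid, sea, "under"))
        self.thresholds_ = thresholds
        self.calls_ = pd.DataFrame(calls, columns=["cluster_id", "sea", "direction"])
        return self

    def fit_predict(self, rna_table: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(rna_table).calls_


def call_enrichment(rna_table: pd.DataFrame, taxon_group: str, **kwargs) -> pd.DataFrame:
    """Functional wrapper over :class:`EnrichmentCaller`."""
    return EnrichmentCaller(taxon_group=taxon_group, **kwargs).fit_predict(rna_table)


def single_copy_summary(
    rna_table: pd.DataFrame, catalog: pd.DataFrame, calls: pd.DataFrame
) -> dict:
    """Share of differentially represented clusters among single- vs multi-copy ones.

    A cluster counts as differentially represented when it appears in any
    call.  Proportions are None when a group is empty.
    """
    flag = catalog.groupby("cluster_id")["single_copy"].first()
    called = set(calls["cluster_id"]) if len(calls) else set()
    out = {}
    for label, want in (("single_copy", True), ("non_single_copy", False)):
        ids = [c for c in rna_table.index if flag.get(c, True) == want]
        n_called = sum(c in called for c in ids)
        out[label] = {
            "n": len(ids),
            "n_called": n_called,
            "proportion": (n_called / len(ids)) if ids else None,
        }
    return out


def write_rna_table(rna_table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# relative normalized abundance per sea (rows sum to 1); "
            "entropy in nats (natural log)\n"
        )
        rna_table.to_csv(fh, sep="\t", index_label="cluster_id")


def read_rna_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df["retained"] = df["retained"].astype(bool)
    return df
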