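"""Ecotype composition of gene clusters and KL-distance outlier flagging.

For each gene cluster and sea, the reads assigned to the cluster are split by
the ecotype of their rank-1 hit genome (e.g. Prochlorococcus HLI / HLII / LL
clades, or cyanophage T4-like vs T7-like types), giving a frequency vector
over ecotypes.  Per sea, those vectors are summarized as Tukey box statistics
per ecotype axis, and over-represented clusters whose composition deviates
from the crowd are flagged in two stages: a box-plot pre-screen (outside the
w=1.5 whiskers on any ecotype axis), then a Kullback–Leibler screen — the
cluster's KL distance from the per-sea mean composition must exceed the 80th
percentile of the KL distances of the non-over-represented clusters.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import rel_entr
from sklearn.base import BaseEstimator

from .catalog import genome_to_ecotype

PROFILE_META = ("cluster_id", "sea", "n_reads", "kl_from_mean", "prescreen_outlier", "outlier")


def kl_divergence(
    p: Sequence[float], q: Sequence[float], eps: float = 0.0
) -> float:
    """KL(p || q) = sum p_i ln(p_i / q_i) in nats, on eps-smoothed vectors.

    ``p`` and ``q`` must be probability vectors of equal length.  With
    ``eps > 0`` both are smoothed as (v + eps) / (1 + n·eps) before the
    divergence, so exact zeros never produce infinities.  With ``eps = 0``
    the 0·ln 0 convention applies and a zero in ``q`` against a positive
    ``p`` yields ``inf``.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("p and q must be 1-D vectors of equal length")
    for name, v in (("p", p), ("q", q)):
        if (v < 0).any():
            raise ValueError(f"{name} has negative entries")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1 (got {v.sum():.6f})")
    if eps > 0:
        n = p.size
        p = (p + eps) / (1.0 + n * eps)
        q = (q + eps) / (1.0 + n * eps)
    return float(rel_entr(p, q).sum())


def ecotype_frequencies(
    assignments: pd.DataFrame,
    catalog: pd.DataFrame,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Per-(cluster, sea) ecotype frequency profiles from top-hit genomes.

    ``assignments`` needs columns read_id, sample_id, cluster_id, top_genome
    (unassigned reads are ignored).  Returns one row per (cluster, sea) on
    the full catalog x sample-sheet grid, with one frequency column per
    ecotype and ``n_reads``; rows with no reads carry NaN frequencies and
    are excluded from downstream statistics.
    """
    eco_of = genome_to_ecotype(catalog)
    ecotypes = sorted(set(eco_of.values()))
    sea_of = dict(zip(samples["sample_id"], samples["sea"]))
    seas = list(dict.fromkeys(samples["sea"]))
    clusters = list(dict.fromkeys(catalog["cluster_id"]))

    asg = assignments[assignments["top_genome"].notna()].copy()
    unknown = sorted(set(asg["top_genome"]) - set(eco_of))
    if unknown:
        raise KeyError(f"genomes without ecotype mapping: {unknown[:5]}")
    asg["sea"] = asg["sample_id"].map(sea_of)
    asg["ecotype"] = asg["top_genome"].map(eco_of)

    counts = (
        asg.groupby(["cluster_id", "sea", "ecotype"], sort=False)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=ecotypes, fill_value=0)
    )
    grid = pd.MultiIndex.from_product([clusters, seas], names=["cluster_id", "sea"])
    counts = counts.reindex(grid, fill_value=0)
    n = counts.sum(axis=1)
    freq = counts.div(n.where(n > 0), axis=0)  # NaN rows where n_reads = 0
    out = freq.reset_index()
    out["n_reads"] = n.to_numpy().astype(int)
    return out


def tukey_fences(values: np.ndarray, w: float = 1.5) -> tuple[float, float, float, float, float]:
    """(q1, median, q3, lower whisker, upper whisker) with type-7 quantiles.

    Whiskers extend at most w x IQR beyond the quartiles, clipped to the most
    extreme data point inside the fences.
    """
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_f, hi_f = q1 - w * iqr, q3 + w * iqr
    inside = values[(values >= lo_f) & (values <= hi_f)]
    lo = float(inside.min()) if inside.size else float(q1)
    hi = float(inside.max()) if inside.size else float(q3)
    return float(q1), float(med), float(q3), lo, hi


def box_summary(profiles: pd.DataFrame, w: float = 1.5) -> pd.DataFrame:
    """Tukey box statistics per (sea, ecotype axis) over clusters with reads.

    Returns rows (sea, ecotype, q1, median, q3, whisker_lo, whisker_hi,
    n, n_outliers, outlier_clusters).
    """
    eco_cols = [c for c in profiles.columns if c not in PROFILE_META]
    rows = []
    for sea, grp in profiles[profiles["n_reads"] > 0].groupby("sea", sort=False):
        for eco in eco_cols:
            vals = grp[eco].to_numpy(dtype=float)
            q1, med, q3, lo, hi = tukey_fences(vals, w=w)
            out_mask = (vals < lo) | (vals > hi)
            rows.append(
                {
                    "sea": sea,
                    "ecotype": eco,
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                    "whisker_lo": lo,
                    "whisker_hi": hi,
                    "n": len(vals),
                    "n_outliers": int(out_mask.sum()),
                    "outlier_clusters": ";".join(grp["cluster_id"].to_numpy()[out_mask]),
                }
            )
    return pd.DataFrame(rows)


class EcotypeOutlierDetector(BaseEstimator):
    """Two-stage KL-outlier flagging of over-represented gene clusters.

    Stage 1 (pre-screen): per sea, a cluster is a candidate when its
    frequency on any ecotype axis falls outside the Tukey whiskers
    (``w`` x IQR) of that axis across clusters.  Stage 2: candidates that are
    over-represented in the sea are flagged as outliers when their
    KL(cluster || mean composition) strictly exceeds the
    ``null_percentile``-th percentile of the KL distances of the
    non-over-represented clusters of that sea.

    The mean composition is the arithmetic mean of the cluster frequency
    vectors (clusters weighted equally), renormalized; KL uses
    ``eps``-smoothing.
    """

    def __init__(self, w: float = 1.5, null_percentile: float = 80.0, eps: float = 1e-6):
        self.w = w
        self.null_percentile = null_percentile
        self.eps = eps

    def fit_transform(self, profiles: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
        eco_cols = [c for c in profiles.columns if c not in PROFILE_META]
        over = set(
            zip(calls.loc[calls["direction"] == "over", "cluster_id"],
                calls.loc[calls["direction"] == "over", "sea"])
        ) if len(calls) else set()

        out = profiles.copy()
        out["kl_from_mean"] = np.nan
        out["prescreen_outlier"] = False
        out["outlier"] = False
        self.null_cutoffs_ = {}
        self.mean_profiles_ = {}

        for sea, grp in out[out["n_reads"] > 0].groupby("sea", sort=False):
            X = grp[eco_cols].to_numpy(dtype=float)
            mean = X.mean(axis=0)
            mean = mean / mean.sum()
            self.mean_profiles_[sea] = dict(zip(eco_cols, mean))
            kl = np.array([kl_divergence(x, mean, eps=self.eps) for x in X])
            out.loc[grp.index, "kl_from_mean"] = kl

            pre = np.zeros(len(grp), dtype=bool)
            for j, eco in enumerate(eco_cols):
                _, _, _, lo, hi = tukey_fences(X[:, j], w=self.w)
                pre |= (X[:, j] < lo) | (X[:, j] > hi)
            out.loc[grp.index, "prescreen_outlier"] = pre

            is_over = np.array([(c, sea) in over for c in grp["cluster_id"]])
            null_kl = kl[~is_over]
            if null_kl.size == 0:
                raise ValueError(
                    f"no non-over-represented clusters in sea {sea!r}; "
                    "the null percentile is undefined"
                )
            if null_kl.size < 5:
                warnings.warn(
                    f"only {null_kl.size} non-over-represented clusters in "
                    f"sea {sea!r}; the KL null percentile is unstable"
                )
            cut = float(np.percentile(null_kl, self.null_percentile))
            self.null_cutoffs_[sea] = cut
            out.loc[grp.index, "outlier"] = is_over & pre & (kl > cut)
        return out


def flag_ecotype_outliers(
    profiles: pd.DataFrame,
    calls: pd.DataFrame,
    w: float = 1.5,
    null_percentile: float = 80.0,
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Functional wrapper over :class:`EcotypeOutlierDetector`."""
    return EcotypeOutlierDetector(
        w=w, null_percentile=null_percentile, eps=eps
    ).fit_transform(profiles, calls)
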