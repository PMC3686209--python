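"""Read-to-gene-cluster assignment from tabular alignment hits.

A read is assigned to a gene cluster when its top hits, ranked by bit score,
all belong to the same cluster — the "top-three-hit agreement" rule.  Ties in
bit score are broken by subject gene id (lexicographic ascending) so the
assignment is deterministic and invariant to input hit order.  By default a
read with only one or two catalog hits is assigned when all of them agree
(the rule applied to ``min(3, n)`` hits); ``require_three=True`` switches to
the strict reading that demands three agreeing hits.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .catalog import HIT_COLUMNS, gene_to_cluster, validate_catalog

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"


class ReadAssigner(BaseEstimator):
    """Assign reads to gene clusters by top-hit agreement.

    Parameters
    ----------
    require_three : bool, default False
        If True, a read needs at least three catalog hits (all agreeing) to
        be assigned; otherwise the agreement rule is applied to however many
        hits are available (1, 2 or 3).
    min_bit_score : float or None, default None
        Optional score floor; hits below it are discarded before ranking.

    Attributes
    ----------
    gene_to_cluster_ : pandas.Series mapping gene_id -> cluster_id.
    n_unknown_gene_hits_ : int, hits dropped because their gene is absent
        from the catalog (each occurrence is also logged).
    """

    def __init__(self, require_three: bool = False, min_bit_score: float | None = None):
        self.require_three = require_three
        self.min_bit_score = min_bit_score

    def fit(self, catalog: pd.DataFrame, y=None) -> "ReadAssigner":
        validate_catalog(catalog)
        self.gene_to_cluster_ = gene_to_cluster(catalog)
        self.gene_to_genome_ = catalog.set_index("gene_id")["genome_id"]
        self.n_unknown_gene_hits_ = 0
        return self

    def transform(self, hits: pd.DataFrame) -> pd.DataFrame:
        """Assign every read in a hit table.

        Returns a DataFrame with one row per read: ``read_id``,
        ``cluster_id`` (or ``UNASSIGNED``) and ``top_genome`` (genome of the
        rank-1 hit, NA when unassigned).
        """
        if not hasattr(self, "gene_to_cluster_"):
            raise RuntimeError("ReadAssigner must be fit on a catalog first")
        h = hits.copy()
        if self.min_bit_score is not None:
            h = h[h["bit_score"] >= self.min_bit_score]
        h["cluster_id"] = h["gene_id"].map(self.gene_to_cluster_)
        unknown = h["cluster_id"].isna()
        if unknown.any():
            n = int(unknown.sum())
            self.n_unknown_gene_hits_ += n
            logger.warning(
                "dropped %d hits to genes absent from the catalog (e.g. %s)",
                n,
                h.loc[unknown, "gene_id"].iloc[0],
            )
            h = h[~unknown]
        if h.empty:
            out = pd.DataFrame(
                {"read_id": pd.unique(hits["read_id"]), "cluster_id": UNASSIGNED}
            )
            out["top_genome"] = pd.NA
            return out

        # deterministic ranking: bit score desc, gene id asc; stable sort
        h = h.sort_values(
            ["read_id", "bit_score", "gene_id"],
            ascending=[True, False, True],
            kind="mergesort",
        )
        top = h.groupby("read_id", sort=False).head(3)
        grp = top.groupby("read_id", sort=False)
        agree = grp["cluster_id"].nunique() == 1
        if self.require_three:
            agree &= grp.size() >= 3
        first = grp.first()
        result = pd.DataFrame(
            {
                "read_id": first.index,
                "cluster_id": np.where(agree, first["cluster_id"], UNASSIGNED),
                "top_genome": first["gene_id"].map(self.gene_to_genome_),
            }
        ).reset_index(drop=True)
        result.loc[result["cluster_id"] == UNASSIGNED, "top_genome"] = pd.NA
        # reads whose every hit fell below the floor / off the catalog
        seen = set(result["read_id"])
        missing = [r for r in pd.unique(hits["read_id"]) if r not in seen]
        if missing:
            result = pd.concat(
                [
                    result,
                    pd.DataFrame(
                        {"read_id": missing, "cluster_id": UNASSIGNED, "top_genome": pd.NA}
                    ),
                ],
                ignore_index=True,
            )
        return result.sort_values("read_id", kind="mergesort").reset_index(drop=True)


def assign_read(
    hits_for_one_read: pd.DataFrame | Sequence[tuple],
    catalog: pd.DataFrame,
    require_three: bool = False,
) -> str:
    """Assign a single read; hits may be unsorted.  Returns a cluster id or UNASSIGNED."""
    if not isinstance(hits_for_one_read, pd.DataFrame):
        hits_for_one_read = pd.DataFrame(
            hits_for_one_read, columns=["read_id", "gene_id", "bit_score"]
        )
    df = hits_for_one_read.reindex(columns=HIT_COLUMNS, fill_value=0)
    df["read_id"] = "r0"
    out = ReadAssigner(require_three=require_three).fit(catalog).transform(df)
    return str(out["cluster_id"].iloc[0])


def count_assignments(
    assignments: dict[str, pd.DataFrame] | pd.DataFrame,
    catalog: pd.DataFrame,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Count assigned reads per cluster per sample.

    ``assignments`` is either a mapping sample_id -> assignment frame (as
    produced by :class:`ReadAssigner`) or one frame with a ``sample_id``
    column.  Unassigned reads are excluded.  A duplicate read id within a
    sample raises (double-counting guard).
    """
    if isinstance(assignments, dict):
        frames = []
        for sid, df in assignments.items():
            f = df.copy()
            f["sample_id"] = sid
            frames.append(f)
        asg = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["read_id", "cluster_id", "sample_id"]
        )
    else:
        asg = assignments
    dup = asg.duplicated(subset=["sample_id", "read_id"])
    if dup.any():
        r = asg.loc[dup].iloc[0]
        raise ValueError(
            f"duplicate read id {r['read_id']!r} in sample {r['sample_id']!r}"
        )
    clusters = pd.Index(dict.fromkeys(catalog["cluster_id"]), name="cluster_id")
    sample_ids = list(samples["sample_id"])
    kept = asg[asg["cluster_id"] != UNASSIGNED]
    unknown = set(kept["cluster_id"]) - set(clusters)
    if unknown:
        raise ValueError(f"assignments reference unknown clusters: {sorted(unknown)[:5]}")
    mat = (
        kept.groupby(["cluster_id", "sample_id"], sort=False)
        .size()
        .unstack(fill_value=0)
        .reindex(index=clusters, columns=sample_ids, fill_value=0)
        .astype(np.int64)
    )
    mat.index.name = "cluster_id"
    return mat


def aggregate_samples(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    mode: str = "by_sea",
    sea_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Sum count columns over samples sharing a sea (or sea+stratum) key.

    Column order follows ``sea_order`` when given, else first appearance in
    the sample sheet.  Aggregation conserves total counts exactly.
    """
    if mode not in ("by_sea", "by_sea_stratum"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    meta = samples.set_index("sample_id")
    missing = [c for c in matrix.columns if c not in meta.index]
    if missing:
        raise ValueError(f"samples absent from sample sheet: {missing[:5]}")
    seas = meta.loc[list(matrix.columns), "sea"]
    if sea_order is not None:
        bad = sorted(set(seas) - set(sea_order))
        if bad:
            raise ValueError(f"unknown sea labels: {bad}")
    if mode == "by_sea":
        keys = list(seas)
        order = list(sea_order) if sea_order else list(dict.fromkeys(keys))
    else:
        strata = meta.loc[list(matrix.columns), "stratum"]
        keys = [f"{s}|{t}" for s, t in zip(seas, strata)]
        if sea_order:
            present = list(dict.fromkeys(keys))
            order = sorted(present, key=lambda k: (list(sea_order).index(k.split("|")[0]), k))
        else:
            order = list(dict.fromkeys(keys))
    agg = matrix.T.groupby(pd.Index(keys, name="key"), sort=False).sum().T
    return agg[[k for k in order if k in agg.columns]]
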