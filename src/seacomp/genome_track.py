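"""Project gene-cluster abundance statistics onto a reference genome.

Each gene cluster retained in the r.n.a. table is placed at the coordinates
of its member gene(s) on a chosen reference genome (the most-represented
genome by rank-1 hits), carrying its per-sea r.n.a., entropy, total reads and
a differential flag; annotated hypervariable regions (HVRs) are attached as
intervals.  Clusters with several member genes on the reference yield one
record per copy.  Coordinates are 0-based half-open internally and 1-based
inclusive on rendered output (stated in the file header).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import sea_columns

logger = logging.getLogger(__name__)


@dataclass
class GenomeTrack:
    reference_genome_id: str
    records: pd.DataFrame  # sorted by start
    hvrs: pd.DataFrame  # columns start, end, label
    n_skipped: int = 0  # retained clusters with no member gene on the reference


def pick_reference(assignments: pd.DataFrame) -> str:
    """Genome with the highest rank-1 hit count; ties broken lexicographically."""
    top = assignments["top_genome"].dropna()
    if top.empty:
        raise ValueError("no assigned reads; cannot pick a reference genome")
    counts = top.value_counts()
    best = counts[counts == counts.max()].index.min()
    return str(best)


def read_hvr_bed(path: str | Path) -> pd.DataFrame:
    """BED-style (chrom, start, end[, label]) intervals; empty file -> no rows."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["genome_id", "start", "end", "label"])
    df = df.iloc[:, :4]
    df.columns = ["genome_id", "start", "end", "label"][: df.shape[1]]
    if "label" not in df.columns:
        df["label"] = [f"HVR{i+1}" for i in range(len(df))]
    return df


def build_track(
    rna_table: pd.DataFrame,
    catalog: pd.DataFrame,
    reference_genome_id: str,
    calls: pd.DataFrame | None = None,
    count_percentile: float = 75.0,
    hvrs: pd.DataFrame | None = None,
) -> GenomeTrack:
    """Genome track of clusters in the top ``count_percentile``% by total reads.

    The ``differential`` flag marks clusters with at least one over/under
    call in ``calls`` (the percentile rule of the enrichment caller), so the
    track is consistent with the caller by construction.  Clusters without a
    member gene on the reference are counted in ``n_skipped``.
    """
    seas = sea_columns(rna_table)
    totals = rna_table["total_reads"].to_numpy()
    c_cut = np.percentile(totals, 100.0 - count_percentile)
    shown = rna_table[rna_table["total_reads"] >= c_cut]

    called = set(calls["cluster_id"]) if calls is not None and len(calls) else set()
    on_ref = catalog[catalog["genome_id"] == reference_genome_id]
    genes = on_ref.set_index("gene_id")

    rows = []
    n_skipped = 0
    for cid, stats in shown.iterrows():
        placements = on_ref[on_ref["cluster_id"] == cid]
        if placements.empty:
            n_skipped += 1
            continue
        for g in placements.itertuples():
            rows.append(
                {
                    "cluster_id": cid,
                    "start": int(g.start),
                    "end": int(g.end),
                    "strand": g.strand,
                    **{s: float(stats[s]) for s in seas},
                    "entropy": float(stats["entropy"]),
                    "total_reads": int(stats["total_reads"]),
                    "differential": cid in called,
                }
            )
    records = pd.DataFrame(
        rows,
        columns=["cluster_id", "start", "end", "strand", *seas, "entropy",
                 "total_reads", "differential"],
    )
    if len(records):
        records = records.sort_values(
            ["start", "cluster_id"], kind="mergesort"
        ).reset_index(drop=True)
    if n_skipped:
        logger.info(
            "%d retained clusters have no member gene on %s",
            n_skipped,
            reference_genome_id,
        )
    if hvrs is None:
        hvrs = pd.DataFrame(columns=["genome_id", "start", "end", "label"])
    else:
        hvrs = hvrs[hvrs["genome_id"] == reference_genome_id].reset_index(drop=True)
    return GenomeTrack(
        reference_genome_id=reference_genome_id,
        records=records,
        hvrs=hvrs,
        n_skipped=n_skipped,
    )


def write_track(track: GenomeTrack, path: str | Path) -> None:
    """BED-compatible TSV: chrom, start, end, name, score (entropy x 1000), strand, ...

    Start/end are written 1-based inclusive (header states conventions).
    """
    rec = track.records.copy()
    with open(path, "w") as fh:
        fh.write(
            "# genome track; coordinates 1-based inclusive; score = entropy "
            "(nats) x 1000, rounded\n"
        )
        fh.write(f"# reference: {track.reference_genome_id}; "
                 f"clusters_without_placement: {track.n_skipped}\n")
        if rec.empty:
            fh.write("")
            return
        out = pd.DataFrame(
            {
                "chrom": track.reference_genome_id,
                "start": rec["start"] + 1,
                "end": rec["end"],
                "name": rec["cluster_id"],
                "score": (rec["entropy"] * 1000).round().astype(int),
                "strand": rec["strand"],
            }
        )
        extra = [c for c in rec.columns if c not in ("cluster_id", "start", "end", "strand")]
        for c in extra:
            out[c] = rec[c].to_numpy()
        out.to_csv(fh, sep="\t", index=False)
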