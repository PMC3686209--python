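"""Gene-cluster catalogs, sample sheets and the tabular formats they travel in.

A *gene cluster* is a group of orthologous genes pooled across the sequenced
reference genomes of one taxon group (Prochlorococcus, cyanophage or SAR11);
it is the unit metagenomic reads are counted against.  The catalog is kept as
a flat, gene-level :class:`pandas.DataFrame` (one row per member gene) because
every downstream operation — hit lookup, ecotype mapping, genome-track
placement — is a join against member genes.  Cluster-level attributes
(single-copy flag, annotation) are repeated per row and must be consistent
within a cluster.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

TAXON_GROUPS = ("prochlorococcus", "cyanophage", "sar11")
STRATA = ("mixed_layer", "sub_mixed_layer", "deep_chl_max", "unspecified")

#: gene-level catalog columns, in canonical order
CATALOG_COLUMNS = [
    "gene_id",
    "cluster_id",
    "genome_id",
    "ecotype",
    "start",
    "end",
    "strand",
    "single_copy",
    "annotation",
    "taxon_group",
]

SAMPLE_COLUMNS = ["sample_id", "sea", "depth_m", "stratum", "library_size"]

#: 12-column tabular alignment format (BLAST outfmt 6)
HIT_COLUMNS = [
    "read_id",
    "gene_id",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bit_score",
]


class CatalogError(ValueError):
    """Raised when a catalog violates its structural invariants."""


@dataclass(frozen=True)
class SampleSpec:
    """One metagenome sample: where and how deep it was taken."""

    sample_id: str
    sea: str
    depth_m: float = 0.0
    stratum: str = "unspecified"
    library_size: int = 0

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValueError(
                f"unknown stratum {self.stratum!r}; expected one of {STRATA}"
            )


def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Check catalog invariants and return the frame (column-ordered).

    Invariants: required columns present; every cluster has at least one
    member gene; a gene_id maps to exactly one cluster; start < end; the
    single-copy flag is constant within a cluster.
    """
    missing = [c for c in CATALOG_COLUMNS if c not in catalog.columns]
    if missing:
        raise CatalogError(f"catalog missing columns: {missing}")
    if catalog.empty:
        raise CatalogError("catalog has no member genes")
    dup = catalog["gene_id"].duplicated()
    if dup.any():
        raise CatalogError(
            f"gene_id maps to more than one row: {sorted(catalog.loc[dup, 'gene_id'])[:5]}"
        )
    bad = catalog["start"] >= catalog["end"]
    if bad.any():
        raise CatalogError(
            f"genes with start >= end: {sorted(catalog.loc[bad, 'gene_id'])[:5]}"
        )
    sc = catalog.groupby("cluster_id")["single_copy"].nunique()
    if (sc > 1).any():
        raise CatalogError(
            f"inconsistent single_copy flag within clusters: {list(sc[sc > 1].index[:5])}"
        )
    return catalog[CATALOG_COLUMNS]


def gene_to_cluster(catalog: pd.DataFrame) -> pd.Series:
    """Mapping gene_id -> cluster_id as a Series indexed by gene_id."""
    return catalog.set_index("gene_id")["cluster_id"]


def genome_to_ecotype(catalog: pd.DataFrame) -> dict[str, str]:
    """Mapping genome_id -> ecotype label.

    Raises :class:`CatalogError` if a genome carries genes of more than one
    ecotype (the catalog's genomes are ecotype representatives).
    """
    grouped = catalog.groupby("genome_id")["ecotype"].unique()
    bad = grouped[grouped.map(len) > 1]
    if len(bad):
        raise CatalogError(f"genomes with multiple ecotypes: {list(bad.index)}")
    return {g: e[0] for g, e in grouped.items()}


def cluster_table(catalog: pd.DataFrame) -> pd.DataFrame:
    """Cluster-level view: one row per cluster with membership summaries."""
    return (
        catalog.groupby("cluster_id")
        .agg(
            n_genes=("gene_id", "size"),
            n_genomes=("genome_id", "nunique"),
            ecotypes=("ecotype", lambda e: tuple(sorted(set(e)))),
            single_copy=("single_copy", "first"),
            annotation=("annotation", "first"),
            taxon_group=("taxon_group", "first"),
        )
        .reset_index()
    )


# ---------------------------------------------------------------------------
# tabular I/O


def read_catalog(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str, "cluster_id": str, "genome_id": str})
    df["single_copy"] = df["single_copy"].astype(bool)
    return validate_catalog(df)


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    validate_catalog(catalog).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "sea": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogError(f"sample sheet missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise CatalogError("duplicate sample_id in sample sheet")
    return df[SAMPLE_COLUMNS]


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a 12-column tab-separated alignment hit table (no header)."""
    return pd.read_csv(
        path, sep="\t", names=HIT_COLUMNS, dtype={"read_id": str, "gene_id": str}
    )


def write_hit_table(hits: pd.DataFrame, path: str | Path) -> None:
    hits[HIT_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a clusters x samples count matrix written by :func:`write_count_matrix`."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df.astype(int)


def write_count_matrix(matrix: pd.DataFrame, path: str | Path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write("# read counts per gene cluster (rows) and sample/sea (columns)\n")
        if comment:
            fh.write(f"# {comment}\n")
        matrix.to_csv(fh, sep="\t", index_label="cluster_id")


def samples_as_specs(samples: pd.DataFrame) -> list[SampleSpec]:
    return [
        SampleSpec(
            sample_id=r.sample_id,
            sea=r.sea,
            depth_m=float(r.depth_m),
            stratum=r.stratum,
            library_size=int(r.library_size),
        )
        for r in samples.itertuples()
    ]
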