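"""Synthetic comparative-metagenomics data with planted sea-specific enrichments.

The generator emulates the statistical structure of a multi-sea pyrosequencing
survey of Prochlorococcus / cyanophage / SAR11 populations without simulating
any sequence: a gene-cluster catalog over per-ecotype pseudo-genomes, read
counts per cluster per sample (multinomial given the library size, with
selected (cluster, sea) weights multiplied by a fold-change), the ecotype of
origin of every read, and 12-column alignment hit tables consistent with the
top-three-hit assignment rule.

Defaults reproduce the benchmark design used throughout the package: 500 gene
clusters with log-normal baseline abundances, four seas (RS, MED, BATS, HOT)
with one 100,000-read sample each, ten clusters planted with an 8-fold
enrichment in one sea, and noise-free hit tables.

Determinism: every stage draws from its own :class:`numpy.random.Generator`
seeded by ``(config.seed, stage index)``, so ``simulate_catalog``,
``simulate_counts`` and ``simulate_hits`` are individually reproducible and a
fixed seed yields byte-identical outputs end to end.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import CATALOG_COLUMNS, HIT_COLUMNS, SAMPLE_COLUMNS, validate_catalog

GENE_LENGTH = 100  # fixed mock gene length; genome_context only needs an ordering

_STAGE_CATALOG, _STAGE_COUNTS, _STAGE_HITS = 0, 1, 2

DEFAULT_SEAS = ("RS", "MED", "BATS", "HOT")
DEFAULT_ECOTYPES = ("HLI", "HLII", "LL")
#: per-sea ecotype mixing proportions (HLI, HLII, LL).  HLII dominates
#: everywhere except MED, where HLI does; LL is more prominent in the
#: gyre sites that include deeper samples.
DEFAULT_MIXTURES: Mapping[str, tuple[float, ...]] = {
    "RS": (0.08, 0.87, 0.05),
    "MED": (0.60, 0.30, 0.10),
    "BATS": (0.15, 0.65, 0.20),
    "HOT": (0.10, 0.70, 0.20),
}


class SimConfigError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass(frozen=True)
class SimConfig:
    """Design of one synthetic survey.

    Parameters
    ----------
    n_clusters : number of gene clusters in the catalog.
    seas : ordered sea labels.
    depths : per sea, list of (depth in metres, stratum label); one sample is
        generated per entry.
    library_size : reads per sample.
    baseline_sigma : sigma of the log-normal(0, sigma) baseline cluster
        weights, so the top-75%-by-count filter has nontrivial action.
    planted_enrichments : explicit (cluster index or id, sea, fold >= 1)
        triples, or ``None`` to plant ``n_planted`` clusters at
        ``planted_fold`` assigned round-robin over the seas.
    ecotypes / ecotype_mixtures : ecotype labels and per-sea mixing
        proportions (each summing to 1).
    membership_prob : probability that a given ecotype's pseudo-genome
        carries a member gene of a cluster (at least one is guaranteed).
    multi_copy_prob : probability that a cluster gets a second gene copy in
        one member genome (and is therefore flagged non-single-copy).
    hit_noise_rate : probability that a read's hit table violates the
        top-three agreement rule (a discordant top 3 is emitted).
    """

    n_clusters: int = 500
    seas: Sequence[str] = DEFAULT_SEAS
    depths: Mapping[str, Sequence[tuple[float, str]]] | None = None
    library_size: int = 100_000
    baseline_sigma: float = 1.0
    planted_enrichments: Sequence[tuple[object, str, float]] | None = None
    n_planted: int = 10
    planted_fold: float = 8.0
    ecotypes: Sequence[str] = DEFAULT_ECOTYPES
    ecotype_mixtures: Mapping[str, Sequence[float]] | None = None
    membership_prob: float = 0.7
    multi_copy_prob: float = 0.2
    hit_noise_rate: float = 0.0
    taxon_group: str = "prochlorococcus"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise SimConfigError("n_clusters must be >= 1")
        if self.library_size < 0:
            raise SimConfigError("library_size must be >= 0")
        if not self.seas:
            raise SimConfigError("at least one sea is required")
        if not self.ecotypes:
            raise SimConfigError("ecotype_set must be nonempty")
        if not (0.0 <= self.hit_noise_rate <= 1.0):
            raise SimConfigError("hit_noise_rate must be in [0, 1]")
        if not (0.0 < self.membership_prob <= 1.0):
            raise SimConfigError("membership_prob must be in (0, 1]")
        for sea, mix in self.mixtures().items():
            if len(mix) != len(self.ecotypes):
                raise SimConfigError(f"mixture for {sea} has wrong length")
            if abs(sum(mix) - 1.0) > 1e-9 or min(mix) < 0:
                raise SimConfigError(f"mixture for {sea} must sum to 1")
        if self.planted_enrichments is not None:
            for _, sea, fold in self.planted_enrichments:
                if sea not in self.seas:
                    raise SimConfigError(f"planted enrichment names unknown sea {sea!r}")
                if fold < 1.0:
                    raise SimConfigError("fold-changes must be >= 1")

    def mixtures(self) -> dict[str, tuple[float, ...]]:
        if self.ecotype_mixtures is not None:
            return {s: tuple(self.ecotype_mixtures[s]) for s in self.seas}
        if tuple(self.ecotypes) == DEFAULT_ECOTYPES:
            base = DEFAULT_MIXTURES
            return {
                s: base.get(s, tuple([1.0 / len(self.ecotypes)] * len(self.ecotypes)))
                for s in self.seas
            }
        k = len(self.ecotypes)
        return {s: tuple([1.0 / k] * k) for s in self.seas}

    def sample_sheet(self) -> pd.DataFrame:
        """One sample per configured (sea, depth) entry."""
        depths = self.depths or {s: [(25.0, "mixed_layer")] for s in self.seas}
        rows = []
        for sea in self.seas:
            for depth_m, stratum in depths.get(sea, [(25.0, "mixed_layer")]):
                rows.append(
                    {
                        "sample_id": f"{sea}_{depth_m:g}m",
                        "sea": sea,
                        "depth_m": depth_m,
                        "stratum": stratum,
                        "library_size": self.library_size,
                    }
                )
        return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stage]))


@dataclass
class SimTruth:
    """Ground truth of one simulated survey.

    Attributes
    ----------
    counts : clusters x samples integer DataFrame (column sums = library sizes).
    planted : set of planted (cluster_id, sea) pairs.
    planted_folds : mapping (cluster_id, sea) -> fold-change.
    reads : one row per simulated read — read_id, sample_id, sea, true
        cluster_id, true ecotype, and the ecotype's pseudo-genome.
    """

    counts: pd.DataFrame
    planted: set[tuple[str, str]]
    planted_folds: dict[tuple[str, str], float] = field(default_factory=dict)
    reads: pd.DataFrame | None = None


def _cluster_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"GC{i:0{width}d}" for i in range(n)]


def simulate_catalog(config: SimConfig) -> pd.DataFrame:
    """Generate a gene-level catalog over one pseudo-genome per ecotype.

    Each cluster is carried by a random subset of the ecotype genomes
    (Bernoulli(membership_prob) per genome, at least one); with probability
    ``multi_copy_prob`` one member genome carries a second copy and the
    cluster is flagged non-single-copy.  Genes are laid end to end on each
    pseudo-genome in cluster order with a fixed length of 100 units.
    """
    rng = config.rng(_STAGE_CATALOG)
    ecotypes = list(config.ecotypes)
    genomes = {e: f"G_{e}" for e in ecotypes}
    ids = _cluster_ids(config.n_clusters)

    member = rng.random((config.n_clusters, len(ecotypes))) < config.membership_prob
    # guarantee >= 1 member genome per cluster
    empty = ~member.any(axis=1)
    forced = rng.integers(0, len(ecotypes), size=int(empty.sum()))
    member[np.flatnonzero(empty), forced] = True
    multi = rng.random(config.n_clusters) < config.multi_copy_prob

    rows: list[tuple] = []
    offsets = {g: 0 for g in genomes.values()}
    for i, cid in enumerate(ids):
        member_ecos = [e for j, e in enumerate(ecotypes) if member[i, j]]
        # the extra copy goes to the first member genome, deterministically
        copy_host = member_ecos[0] if multi[i] else None
        for e in member_ecos:
            n_copies = 2 if e == copy_host else 1
            g = genomes[e]
            for k in range(n_copies):
                start = offsets[g]
                offsets[g] += GENE_LENGTH
                rows.append(
                    (
                        f"{cid}|{g}|{k}",
                        cid,
                        g,
                        e,
                        start,
                        start + GENE_LENGTH,
                        "+" if (i + k) % 2 == 0 else "-",
                        not multi[i],
                        f"simulated protein {i}",
                        config.taxon_group,
                    )
                )
    return validate_catalog(pd.DataFrame(rows, columns=CATALOG_COLUMNS))


def _resolve_planted(
    config: SimConfig, ids: list[str], rng: np.random.Generator
) -> dict[tuple[str, str], float]:
    """Planted (cluster_id, sea) -> fold map; auto-plant round-robin if unset."""
    if config.planted_enrichments is not None:
        out: dict[tuple[str, str], float] = {}
        for cl, sea, fold in config.planted_enrichments:
            cid = ids[cl] if isinstance(cl, (int, np.integer)) else str(cl)
            if cid not in ids:
                raise SimConfigError(f"planted enrichment references unknown cluster {cid!r}")
            out[(cid, sea)] = float(fold)
        return out
    n = min(config.n_planted, config.n_clusters)
    chosen = rng.choice(config.n_clusters, size=n, replace=False)
    return {
        (ids[c], config.seas[j % len(config.seas)]): float(config.planted_fold)
        for j, c in enumerate(chosen)
    }


def simulate_counts(
    catalog: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw read counts per cluster per sample and per-read ecotype origins.

    Each sample's column is a multinomial draw of ``library_size`` reads over
    clusters with probabilities proportional to the log-normal baseline
    weights, after multiplying planted (cluster, sea) weights by their
    fold-change.  Each read's ecotype is drawn from the sea's mixing
    proportions restricted to the ecotypes that actually carry the cluster.
    """
    rng = config.rng(_STAGE_COUNTS)
    ids = list(dict.fromkeys(catalog["cluster_id"]))
    if len(ids) != config.n_clusters:
        raise SimConfigError("catalog and config disagree on n_clusters")
    samples = config.sample_sheet()
    weights = rng.lognormal(mean=0.0, sigma=config.baseline_sigma, size=len(ids))
    planted = _resolve_planted(config, ids, rng)

    idx = {c: i for i, c in enumerate(ids)}
    counts = np.zeros((len(ids), len(samples)), dtype=np.int64)
    for j, srow in enumerate(samples.itertuples()):
        w = weights.copy()
        for (cid, sea), fold in planted.items():
            if sea == srow.sea:
                w[idx[cid]] *= fold
        counts[:, j] = rng.multinomial(int(srow.library_size), w / w.sum())

    count_df = pd.DataFrame(counts, index=pd.Index(ids, name="cluster_id"),
                            columns=list(samples["sample_id"]))

    # per-read ecotypes: mixture restricted to member ecotypes of the cluster
    eco_labels = list(config.ecotypes)
    mixtures = config.mixtures()
    members = catalog.groupby("cluster_id")["ecotype"].agg(lambda e: sorted(set(e)))
    genome_of = {e: f"G_{e}" for e in eco_labels}

    read_sample: list[np.ndarray] = []
    read_cluster: list[np.ndarray] = []
    read_eco: list[np.ndarray] = []
    for j, srow in enumerate(samples.itertuples()):
        mix = np.asarray(mixtures[srow.sea], dtype=float)
        for i, cid in enumerate(ids):
            c = counts[i, j]
            if c == 0:
                continue
            mem = members[cid]
            p = np.array([mix[eco_labels.index(e)] for e in mem])
            if p.sum() <= 0:
                p = np.ones(len(mem))
            draw = rng.multinomial(int(c), p / p.sum())
            for e, k in zip(mem, draw):
                if k:
                    read_sample.append(np.repeat(srow.sample_id, k))
                    read_cluster.append(np.repeat(cid, k))
                    read_eco.append(np.repeat(e, k))
    if read_sample:
        reads = pd.DataFrame(
            {
                "sample_id": np.concatenate(read_sample),
                "cluster_id": np.concatenate(read_cluster),
                "ecotype": np.concatenate(read_eco),
            }
        )
    else:
        reads = pd.DataFrame(columns=["sample_id", "cluster_id", "ecotype"])
    # stable per-sample read ids after a deterministic shuffle within sample
    reads = (
        reads.sample(frac=1.0, random_state=np.random.RandomState(config.seed % (2**31)))
        .sort_values("sample_id", kind="stable")
        .reset_index(drop=True)
    )
    reads["read_id"] = (
        reads["sample_id"] + "_r" + reads.groupby("sample_id").cumcount().astype(str)
    )
    sea_of = dict(zip(samples["sample_id"], samples["sea"]))
    reads["sea"] = reads["sample_id"].map(sea_of)
    reads["genome_id"] = reads["ecotype"].map(genome_of)
    reads = reads[["read_id", "sample_id", "sea", "cluster_id", "ecotype", "genome_id"]]

    truth = SimTruth(
        counts=count_df,
        planted=set(planted),
        planted_folds=planted,
        reads=reads,
    )
    return count_df, truth


def simulate_hits(
    catalog: pd.DataFrame, truth: SimTruth, config: SimConfig
) -> dict[str, pd.DataFrame]:
    """Emit a 12-column alignment hit table per sample.

    For each read, >= 3 hits are generated with strictly decreasing bit
    scores.  With probability ``1 - hit_noise_rate`` the top three hits are
    genes of the read's true cluster (its rank-1 hit lying on the pseudo-genome
    of its true ecotype, so top-hit genomes reproduce ecotype origins); a
    fourth, lower-scoring decoy hit from another cluster is appended.  With
    probability ``hit_noise_rate`` the third hit is swapped for the decoy,
    producing a discordant top 3 that the assignment rule must reject.
    """
    if truth.reads is None or truth.reads.empty:
        raise SimConfigError("SimTruth carries no simulated reads")
    rng = config.rng(_STAGE_HITS)

    by_cluster: dict[str, list[tuple[str, str, int]]] = {}
    for r in catalog.itertuples():
        by_cluster.setdefault(r.cluster_id, []).append((r.gene_id, r.genome_id, r.start))
    all_ids = list(by_cluster)
    gene_pool = list(catalog["gene_id"])
    pool_cluster = list(catalog["cluster_id"])

    n_reads = len(truth.reads)
    noisy = rng.random(n_reads) < config.hit_noise_rate
    base_scores = rng.uniform(80.0, 120.0, size=n_reads)
    decrements = rng.uniform(0.5, 5.0, size=(n_reads, 4))
    decoy_pick = rng.integers(0, len(gene_pool), size=n_reads)

    tables: dict[str, list[list]] = {s: [] for s in truth.reads["sample_id"].unique()}
    for i, read in enumerate(truth.reads.itertuples()):
        genes = by_cluster[read.cluster_id]
        # rank-1 hit on the read's own ecotype genome
        own = [g for g in genes if g[1] == read.genome_id]
        others = [g for g in genes if g[1] != read.genome_id]
        ordered = (own + others) if own else genes
        top3 = [ordered[k % len(ordered)] for k in range(3)]

        # decoy from a different cluster (for noisy reads it invades rank 3)
        d = int(decoy_pick[i])
        while pool_cluster[d] == read.cluster_id:
            d = (d + 1) % len(gene_pool)
        decoy_gene = gene_pool[d]
        decoy_row = next(
            g for g in by_cluster[pool_cluster[d]] if g[0] == decoy_gene
        )

        if noisy[i]:
            hit_rows = [top3[0], top3[1], decoy_row, top3[2]]
        else:
            hit_rows = [top3[0], top3[1], top3[2], decoy_row]

        score = float(base_scores[i])
        out = tables[read.sample_id]
        for k, (gene_id, _genome, start) in enumerate(hit_rows):
            out.append(
                [
                    read.read_id,
                    gene_id,
                    round(100.0 - 2.0 * k, 1),
                    GENE_LENGTH - 10,
                    2 * k,
                    0,
                    1,
                    GENE_LENGTH - 10,
                    start + 1,
                    start + GENE_LENGTH - 10,
                    10.0 ** (-30 + 3 * k),
                    round(score, 1),
                ]
            )
            score -= float(decrements[i, k])
    return {
        s: pd.DataFrame(rows, columns=HIT_COLUMNS) for s, rows in tables.items()
    }


def simulate_survey(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth, dict[str, pd.DataFrame]]:
    """Run catalog -> counts -> hits; returns (catalog, samples, counts, truth, hits)."""
    cat = simulate_catalog(config)
    counts, truth = simulate_counts(cat, config)
    hits = simulate_hits(cat, truth, config)
    return cat, config.sample_sheet(), counts, truth, hits
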