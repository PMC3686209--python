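"""End-to-end orchestration: simulate/load -> assign -> enrich -> ecotypes ->
sea clustering -> genome track, with a reproducibility manifest.

A run is described by a single :class:`RunConfig` that either points at real
inputs (hit tables, catalog, sample sheet, optional HVR BED) or carries a
simulation block.  All thresholds default to the study values: 20-read
low-count filter, 10% r.n.a. percentile, 15%/25% entropy percentile by taxon
group, 75% count percentile, 80% KL null percentile, whisker length 1.5,
smoothing eps 1e-6.  A fixed config and seed reproduce every output file
byte for byte; the manifest records a config hash, per-stage row counts and
the sha256 of each written table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import catalog as cat
from .assign import ReadAssigner, aggregate_samples, count_assignments
from .clustering import SeaClusterer, to_newick
from .ecotypes import EcotypeOutlierDetector, box_summary, ecotype_frequencies
from .enrichment import (
    EnrichmentCaller,
    build_rna_table,
    single_copy_summary,
    write_rna_table,
)
from .genome_track import build_track, pick_reference, read_hvr_bed, write_track
from .simulate import SimConfig, simulate_survey

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class Thresholds:
    min_total_reads: int = 21
    rna_percentile: float = 10.0
    entropy_percentile: float | None = None  # None -> by taxon group (15 or 25)
    count_percentile: float = 75.0
    clustering_entropy_percentile: float = 25.0
    kl_null_percentile: float = 80.0
    whisker: float = 1.5
    eps: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("rna_percentile", "count_percentile",
                     "clustering_entropy_percentile", "kl_null_percentile"):
            v = getattr(self, name)
            if not (0 < v < 100):
                raise ValueError(f"{name} must lie in (0, 100)")


@dataclass
class RunConfig:
    outdir: str | Path = "seacomp_out"
    taxon_group: str = "prochlorococcus"
    seas: tuple[str, ...] | None = None
    seed: int = 0
    simulate: SimConfig | None = None
    hit_tables: dict[str, str] | None = None  # sample_id -> path
    catalog_path: str | None = None
    sample_sheet_path: str | None = None
    hvr_bed_path: str | None = None
    require_three: bool = False
    thresholds: Thresholds = field(default_factory=Thresholds)

    def __post_init__(self) -> None:
        real = self.hit_tables is not None
        if real == (self.simulate is not None):
            raise ValueError(
                "exactly one of {hit tables + catalog + sample sheet, "
                "simulate block} must be configured"
            )
        if real and not (self.catalog_path and self.sample_sheet_path):
            raise ValueError("real-input runs need catalog_path and sample_sheet_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            if "planted_enrichments" in sim and sim["planted_enrichments"]:
                sim["planted_enrichments"] = [tuple(t) for t in sim["planted_enrichments"]]
            raw["simulate"] = SimConfig(**sim)
        if "thresholds" in raw and raw["thresholds"] is not None:
            raw["thresholds"] = Thresholds(**raw["thresholds"])
        if "seas" in raw and raw["seas"] is not None:
            raw["seas"] = tuple(raw["seas"])
        return cls(**raw)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, (tuple, list)):
                return [enc(v) for v in o]
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in o.items()}
            if isinstance(o, Path):
                return str(o)
            return o
        payload = enc(self)
        payload.pop("outdir", None)  # the hash identifies the analysis, not its location
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_inputs(
    catalog: pd.DataFrame,
    hit_tables: dict[str, pd.DataFrame],
    samples: pd.DataFrame,
    seas: tuple[str, ...] | None = None,
) -> list[dict]:
    """Referential-integrity report (never raises): orphan genes, unknown
    seas, duplicate reads, samples without hits."""
    issues: list[dict] = []
    known_genes = set(catalog["gene_id"])
    known_samples = set(samples["sample_id"])
    sea_set = set(seas) if seas else set(samples["sea"])
    for r in samples.itertuples():
        if r.sea not in sea_set:
            issues.append(
                {"category": "sea", "message": f"sample {r.sample_id} has unknown sea {r.sea!r}"}
            )
    for sid, hits in hit_tables.items():
        if sid not in known_samples:
            issues.append(
                {"category": "sample", "message": f"hit table for unknown sample {sid!r}"}
            )
        orphans = sorted(set(hits["gene_id"]) - known_genes)
        if orphans:
            issues.append(
                {
                    "category": "gene",
                    "message": f"sample {sid}: {len(orphans)} hits to genes absent "
                               f"from the catalog (e.g. {orphans[0]})",
                }
            )
        dup = hits[["read_id", "gene_id", "bit_score"]].duplicated()
        if dup.any():
            issues.append(
                {"category": "read", "message": f"sample {sid}: duplicated hit rows"}
            )
    return issues


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage, write outputs under ``config.outdir``, return the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "taxon_group": config.taxon_group,
        "stages": {},
        "outputs": {},
    }

    stage = "load"
    try:
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            catalog, samples, true_counts, truth, hit_tables = simulate_survey(sim)
            cat.write_catalog(catalog, out / "catalog.tsv")
            cat.write_sample_sheet(samples, out / "samples.tsv")
            hits_dir = out / "hits"
            hits_dir.mkdir(exist_ok=True)
            for sid, hits in hit_tables.items():
                cat.write_hit_table(hits, hits_dir / f"{sid}.hits.tsv")
            truth.counts.to_csv(out / "true_counts.tsv", sep="\t")
        else:
            catalog = cat.read_catalog(config.catalog_path)
            samples = cat.read_sample_sheet(config.sample_sheet_path)
            missing = [p for p in config.hit_tables.values() if not Path(p).exists()]
            if missing:
                raise FileNotFoundError(f"missing hit tables: {missing}")
            hit_tables = {
                sid: cat.read_hit_table(p) for sid, p in config.hit_tables.items()
            }
        manifest["stages"]["load"] = {
            "n_genes": len(catalog),
            "n_clusters": catalog["cluster_id"].nunique(),
            "n_samples": len(samples),
        }

        stage = "validate"
        issues = validate_inputs(catalog, hit_tables, samples, config.seas)
        manifest["stages"]["validate"] = {"n_issues": len(issues), "issues": issues}

        stage = "assign"
        assigner = ReadAssigner(require_three=config.require_three).fit(catalog)
        assignments = {sid: assigner.transform(h) for sid, h in hit_tables.items()}
        n_reads = sum(len(a) for a in assignments.values())
        n_assigned = sum(
            int((a["cluster_id"] != "UNASSIGNED").sum()) for a in assignments.values()
        )
        counts = count_assignments(assignments, catalog, samples)
        manifest["stages"]["assign"] = {
            "reads_seen": n_reads,
            "reads_assigned": n_assigned,
            "reads_unassigned": n_reads - n_assigned,
        }
        cat.write_count_matrix(counts, out / "counts_by_sample.tsv")

        stage = "aggregate"
        sea_order = config.seas or tuple(dict.fromkeys(samples["sea"]))
        by_sea = aggregate_samples(counts, samples, "by_sea", sea_order)
        cat.write_count_matrix(by_sea, out / "counts_by_sea.tsv")
        manifest["stages"]["aggregate"] = {"seas": list(by_sea.columns)}

        stage = "normalize"
        rna, removed = build_rna_table(by_sea, min_total=th.min_total_reads)
        write_rna_table(rna, out / "rna.tsv")
        manifest["stages"]["normalize"] = {
            "clusters_retained": len(rna),
            "clusters_removed_low_count": len(removed),
        }

        stage = "enrichment"
        caller = EnrichmentCaller(
            taxon_group=config.taxon_group,
            rna_percentile=th.rna_percentile,
            entropy_percentile=th.entropy_percentile,
            count_percentile=th.count_percentile,
        ).fit(rna)
        calls = caller.calls_
        calls.to_csv(out / "enrichment_calls.tsv", sep="\t", index=False)
        sc = single_copy_summary(rna, catalog, calls)
        manifest["stages"]["enrichment"] = {
            "n_calls": len(calls),
            "single_copy_summary": sc,
        }

        stage = "ecotypes"
        merged = pd.concat(
            [a.assign(sample_id=sid) for sid, a in assignments.items()],
            ignore_index=True,
        )
        profiles = ecotype_frequencies(merged, catalog, samples)
        flagged = EcotypeOutlierDetector(
            w=th.whisker, null_percentile=th.kl_null_percentile, eps=th.eps
        ).fit_transform(profiles, calls)
        flagged.to_csv(out / "ecotype_profiles.tsv", sep="\t", index=False)
        boxes = box_summary(profiles, w=th.whisker)
        boxes.to_csv(out / "ecotype_box_summary.tsv", sep="\t", index=False)
        manifest["stages"]["ecotypes"] = {
            "n_profiles": int((flagged["n_reads"] > 0).sum()),
            "n_outliers": int(flagged["outlier"].sum()),
        }

        stage = "sea_clustering"
        clusterer = SeaClusterer(
            entropy_percentile=th.clustering_entropy_percentile,
            count_percentile=th.count_percentile,
            eps=th.eps,
        ).fit(by_sea, rna)
        clusterer.dissimilarity_.to_csv(out / "sea_dissimilarity.tsv", sep="\t")
        (out / "sea_dendrogram.nwk").write_text(to_newick(clusterer.dendrogram_) + "\n")
        manifest["stages"]["sea_clustering"] = {
            "n_features": len(clusterer.features_),
            "agglomerative_coefficient": round(clusterer.agglomerative_coefficient_, 6),
        }

        stage = "genome_track"
        reference = pick_reference(merged)
        hvrs = read_hvr_bed(config.hvr_bed_path) if config.hvr_bed_path else None
        track = build_track(
            rna, catalog, reference, calls=calls,
            count_percentile=th.count_percentile, hvrs=hvrs,
        )
        write_track(track, out / "genome_track.tsv")
        manifest["stages"]["genome_track"] = {
            "reference": reference,
            "n_records": len(track.records),
            "n_skipped": track.n_skipped,
            "n_hvrs": len(track.hvrs),
        }
    except Exception as e:  # noqa: BLE001 - re-raise with the failing stage named
        raise PipelineError(f"stage {stage!r} failed: {e}") from e

    for p in sorted(out.rglob("*.tsv")) + sorted(out.glob("*.nwk")):
        manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
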