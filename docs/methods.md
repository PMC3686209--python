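# Methods

## Scope and data model

`seacomp` analyses pre-binned tabular alignment hits: one 12-column
(BLAST outfmt-6 style) table per sample per taxon group, already restricted
to reads of that group. Taxonomic binning of raw reads (BLASTX against a
general protein database) is upstream of this package and out of scope, as
are 16S profiling and de novo detection of hypervariable regions (HVRs are
consumed as BED annotations).

The in-memory containers are plain pandas objects: a gene-level catalog
(one row per member gene of a cluster, with genome, ecotype, 0-based
half-open coordinates, strand and a per-cluster single-copy flag), a sample
sheet (sea, depth, stratum, library size), and a clusters × samples integer
count matrix.

## Read assignment

Hits are ranked within a read by bit score descending, ties broken by
subject gene id ascending — the tie-break makes assignment deterministic
and invariant to input order. A read is assigned when the top three hits
share one cluster. Reads with only one or two catalog hits are assigned when
all of them agree (the rule applied to `min(3, n)` hits); the strict variant
requiring three hits is available (`require_three=True`). Hits to genes
absent from the catalog are dropped with a logged warning; multiple hits to
different genes of one genome, or repeated HSPs to one gene, count as
separate hits. No bit-score floor is applied by default (`min_bit_score`).

## Normalization and enrichment calling

Clusters with ≤ 20 reads summed over all samples are removed before any
normalization, and all percentiles below are computed on the retained set.
The r.n.a. is the two-stage normalization

    rna[g,s] = (c[g,s]/T_s) / Σ_s' (c[g,s']/T_s'),

with T_s the retained-cluster total of sea s. Shannon entropy uses the
natural logarithm with 0·ln 0 = 0 (the published worked examples — a point
mass giving 0.000, and e.g. (0.540, 0.000, 0.197, 0.263) giving 1.004 —
reproduce only under ln).

Enrichment calls require all three percentile conditions at once, evaluated
with numpy's linear-interpolation percentiles. Boundaries are inclusive
(≥ for "top", ≤ for "lowest"), mirroring the inclusive "20 or less" filter;
all ties at a cutoff land on the qualifying side, so no arbitrary dropping
occurs. The r.n.a. percentile is computed per sea (each sea's own column
ranked); ranking against the pooled values of all seas is available behind
`pooled_rna=True`. The entropy percentile is computed on the retained set.

One additional guard: a cluster whose r.n.a. vector is exactly even
(entropy = ln n_seas) is never called, whatever the percentile landscape —
the entropy screen exists to select *nonuniform* distributions, and in a
degenerate table where every cluster is uniform, inclusive ties would
otherwise call everything. With real (noisy) data the guard is vacuous.

## Ecotype analysis

Ecotype composition uses the rank-1 hit genome of each assigned read;
cluster/sea combinations with zero reads are carried with empty frequencies
and excluded from statistics. The mean composition of a sea is the
arithmetic mean of the per-cluster frequency vectors, renormalized —
clusters, not reads, are the unit of observation, matching the box-plot
view of the data. KL distances are computed as KL(cluster ‖ mean) after
smoothing both vectors by (v + ε)/(1 + nε) with ε = 1e-6; smoothing
preserves the ordering of distances (verified statistically in the tests).
The two-stage outlier rule: a per-axis Tukey pre-screen (outside w = 1.5
whiskers on any ecotype axis, type-7 quantiles), then, among over-represented
clusters passing the pre-screen, KL strictly greater than the 80th
percentile of the non-over-represented clusters' KL distances, computed per
sea. SAR11 has no settled ecotype paradigm; the module is generic over any
ecotype labelling, so SAR11 subgroups can still be profiled descriptively.

## Sea clustering

Per-sea profiles are the per-sample normalized abundances restricted to the
selected clusters (entropy lowest 25%, reads top 75%, boundaries inclusive)
and renormalized to sum to 1 — note the library normalization cancels under
this renormalization, so the profiles are simply the column-normalized
counts over the subset. Because KL is asymmetric and agglomerative
clustering needs a dissimilarity, the default distance is the symmetrized
½(KL(p‖q) + KL(q‖p)) with the shared ε-smoothing; one-directional KL is
available (`symmetrize=False`). Agglomeration is group-average (UPGMA)
linkage — the classical AGNES default — delegated to
`scipy.cluster.hierarchy.linkage` and cross-checked in the tests against a
naive O(n³) trace. The agglomerative coefficient is
`AC = mean_i (1 − m_i/m_final)` over items i, with m_i the height of item
i's first merge; AC = 0 identically for two items. Newick export places
internal nodes at half the merge height (the ultrametric convention), so
every leaf sits at final-height/2.

## Genome tracks

The reference genome is the one with the most rank-1 hits (ties broken
lexicographically). The track keeps clusters in the top 75% by total reads,
one record per member gene on the reference (multi-copy clusters appear once
per copy), sorted by start. The `differential` flag is membership in the
enrichment caller's output under the same thresholds, which keeps the track
consistent with the caller by construction. Coordinates are 0-based
half-open internally and 1-based inclusive in written files (stated in the
header); the BED-style score column is entropy × 1000, rounded. Strand is
recorded but not interpreted.

## Synthetic surveys

The generator emulates the statistical structure the pipeline consumes, not
sequences (no FASTA/FASTQ, no 454 error model):

- **Catalog** — one pseudo-genome per ecotype; each cluster is carried by
  each ecotype genome with probability 0.7 (at least one guaranteed), and
  with probability 0.2 one member genome carries a second copy (cluster
  flagged non-single-copy). Genes are laid end to end with a fixed
  100-unit length — downstream only needs an ordering.
- **Counts** — per sample, a multinomial draw of `library_size` reads over
  clusters with probabilities proportional to log-normal(0, 1) baseline
  weights; planted (cluster, sea) weights are multiplied by their fold
  before normalization. Column sums therefore equal library sizes exactly.
  The log-normal baseline is a modelling choice (the abundance distribution
  of real gene-cluster catalogs is not documented); σ = 1 gives the
  top-75%-by-count filter nontrivial action.
- **Ecotypes** — each read's ecotype is drawn from its sea's mixing
  proportions restricted to the ecotypes carrying the cluster. Default
  mixtures make HLII dominant everywhere except MED (HLI-dominated), with
  more LL in the gyre sites — the qualitative pattern observed in these
  oceans.
- **Hits** — per read, ≥ 3 hits with strictly decreasing bit scores. The
  rank-1 hit lies on the read's own ecotype genome, so top-hit-based
  ecotype frequencies reproduce the simulated origins exactly in the
  noiseless case. With probability `hit_noise_rate` the third hit is
  swapped for a decoy from another cluster, producing a discordant top 3
  that assignment must reject; the unassigned fraction therefore estimates
  the noise rate.

Defaults are the benchmark design used throughout: 500 clusters, four seas
(RS, MED, BATS, HOT) with one 100,000-read sample each, ten clusters planted
with an 8-fold enrichment assigned round-robin over seas, noiseless hits.
Determinism: each stage (catalog / counts / hits) derives its own
`numpy.random.Generator` from `(seed, stage index)`, so stages are
individually reproducible without replaying their predecessors, and a fixed
seed makes the whole survey — and every pipeline output file — byte-stable.

What passing tests on these surveys do *not* show: robustness to alignment
noise structure (chimeras, conserved domains shared across clusters),
uneven gene lengths, within-ecotype genome diversity, or compositional
coupling between clusters beyond the multinomial constraint. Results on
real surveys depend on those factors; the synthetic benchmark only
establishes that the statistical machinery recovers planted structure under
its own assumptions.

## Problem sizes and numerical conventions

Read-level tests and the determinism round-trip run on reduced designs
(40–120 clusters, 1,500–20,000 reads per sample) — ample for exact
round-trip checks, which are size-independent. The planted-enrichment
benchmark runs at the full default design over five seeds and requires
≥ 8/10 planted pairs recovered with ≤ 5% of unplanted clusters flagged per
seed (observed: 8–10/10 recovered, ≤ 2.4% flagged).

Tolerances: r.n.a. row sums are exact to 1e-9; published 3-decimal r.n.a.
vectors reproduce their printed entropies within ±0.005 (input rounding) and
sum to 1 within ±0.001. Probability-vector validation uses an absolute
tolerance of 1e-9 by default, relaxed explicitly when feeding rounded
printed vectors. Degenerate inputs raise early with named offenders: a sea
with zero total reads, an empty feature selection, an asymmetric
dissimilarity, an empty KL null set, a duplicate read id within a sample.

## Known limitations

- Percentile-threshold calls carry no error control; they rank, they do not
  test. This mirrors the method implemented; a resampling-based FDR would be
  a separate addition.
- The KL null percentile is unstable for seas with < 5 non-over-represented
  clusters (warned).
- `aggregate_samples` assumes each sample maps to exactly one sea/stratum;
  transect-style designs need pre-splitting.
- The generator plants enrichment multiplicatively on one sea at a time;
  correlated multi-sea enrichment patterns are not simulated.
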