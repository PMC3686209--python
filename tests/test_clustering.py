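"""Feature selection, KL dissimilarity, AGNES and the agglomerative coefficient."""

import io
import math

import numpy as np
import pandas as pd
import pytest

import seacomp as sc
from seacomp.clustering import agnes, sea_dissimilarity, select_clustering_features, to_newick

SEAS = ["RS", "MED", "BATS", "HOT"]


def rna_from_counts(counts):
    rna, _ = sc.build_rna_table(counts)
    return rna


class TestFeatureSelection:
    def test_all_identical_rows_all_retained(self):
        counts = pd.DataFrame(np.full((6, 4), 50), columns=SEAS,
                              index=[f"C{i}" for i in range(6)])
        rna = rna_from_counts(counts)
        assert select_clustering_features(rna) == list(rna.index)

    def test_matches_bruteforce_scan(self, rng):
        lam = rng.lognormal(1.5, 1.0, size=(40, 4)) * 10
        counts = pd.DataFrame(rng.poisson(lam) + 6, columns=SEAS,
                              index=[f"C{i:02d}" for i in range(40)])
        rna = rna_from_counts(counts)
        got = select_clustering_features(rna, 25.0, 75.0)
        e_cut = np.percentile(rna["entropy"], 25)
        c_cut = np.percentile(rna["total_reads"], 25)
        expected = [c for c in rna.index
                    if rna.loc[c, "entropy"] <= e_cut
                    and rna.loc[c, "total_reads"] >= c_cut]
        assert got == expected

    def test_planted_clusters_overrepresented_in_subset(self):
        cfg = sc.SimConfig(n_clusters=200, library_size=20_000, n_planted=8, seed=4)
        cat = sc.simulate_catalog(cfg)
        counts, truth = sc.simulate_counts(cat, cfg)
        by_sea = counts.rename(columns=dict(zip(counts.columns, cfg.seas)))
        rna = rna_from_counts(by_sea)
        subset = set(select_clustering_features(rna))
        planted = {c for c, _ in truth.planted}
        rate_planted = len(planted & subset) / len(planted)
        rate_overall = len(subset) / len(rna)
        assert rate_planted > rate_overall

    def test_empty_selection_is_an_error(self):
        rna = pd.DataFrame(columns=[*SEAS, "entropy", "total_reads", "retained"])
        with pytest.raises(ValueError):
            select_clustering_features(rna)


class TestSeaDissimilarity:
    def test_identical_seas_have_zero_distance(self):
        counts = pd.DataFrame({"RS": [10, 30], "MED": [10, 30]}, index=["A", "B"])
        D = sea_dissimilarity(counts)
        assert np.allclose(D.to_numpy(), 0.0, atol=1e-9)

    def test_four_term_hand_computation(self):
        # profiles p = (0.5, 0.5), q = (0.9, 0.1), eps = 0
        counts = pd.DataFrame({"p": [5, 5], "q": [9, 1]}, index=["A", "B"])
        D = sea_dissimilarity(counts, eps=0.0)
        klpq = 0.5 * math.log(0.5 / 0.9) + 0.5 * math.log(0.5 / 0.1)
        klqp = 0.9 * math.log(0.9 / 0.5) + 0.1 * math.log(0.1 / 0.5)
        assert D.loc["p", "q"] == pytest.approx(0.5 * (klpq + klqp))
        assert D.loc["q", "p"] == D.loc["p", "q"]

    def test_permutation_of_clusters_irrelevant(self, rng):
        counts = pd.DataFrame(rng.integers(1, 50, (20, 4)), columns=SEAS,
                              index=[f"C{i}" for i in range(20)])
        D1 = sea_dissimilarity(counts)
        D2 = sea_dissimilarity(counts.sample(frac=1.0, random_state=1))
        assert np.allclose(D1.to_numpy(), D2.to_numpy(), atol=1e-12)

    def test_valid_dissimilarity(self, rng):
        counts = pd.DataFrame(rng.integers(0, 50, (15, 4)) + 1, columns=SEAS,
                              index=[f"C{i}" for i in range(15)])
        D = sea_dissimilarity(counts).to_numpy()
        assert np.allclose(D, D.T) and (D >= 0).all()
        assert np.allclose(np.diag(D), 0.0)

    def test_all_zero_subset_is_an_error(self):
        counts = pd.DataFrame({"RS": [5, 1], "MED": [0, 3]}, index=["A", "B"])
        with pytest.raises(ValueError, match="all-zero"):
            sea_dissimilarity(counts, subset=["A"])


def naive_average_linkage(D):
    """O(n^3) group-average agglomeration over the original dissimilarities."""
    labels = list(D.index)
    clusters = {i: frozenset([l]) for i, l in enumerate(labels)}
    dist = {frozenset([a, b]): D.loc[la, lb]
            for a, la in enumerate(labels) for b, lb in enumerate(labels) if a < b}
    merges = []
    first = {}
    active = dict(clusters)
    while len(active) > 1:
        (a, b), h = min(
            (((i, j), dist[frozenset([i, j])])
             for i in active for j in active if i < j),
            key=lambda kv: kv[1],
        )
        A, B = active.pop(a), active.pop(b)
        merges.append((A, B, h))
        for m in A | B:
            first.setdefault(m, h)
        new = max(max(active, default=-1), a, b) + 1
        for k, K in list(active.items()):
            na, nb = len(A), len(B)
            dA = dist[frozenset([a, k])]
            dB = dist[frozenset([b, k])]
            dist[frozenset([new, k])] = (na * dA + nb * dB) / (na + nb)
        active[new] = A | B
    m_final = merges[-1][2]
    ac = float(np.mean([1 - first[l] / m_final for l in labels])) if m_final > 0 else 0.0
    return merges, ac


def random_dissimilarity(rng, n):
    X = rng.random((n, 5))
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    labels = [chr(65 + i) for i in range(n)]
    return pd.DataFrame(D, index=labels, columns=labels)


class TestAgnes:
    def test_two_items_merge_at_distance_with_zero_ac(self):
        D = pd.DataFrame([[0, 3.5], [3.5, 0]], index=["A", "B"], columns=["A", "B"])
        d = agnes(D)
        assert d.merges == [(frozenset({"A"}), frozenset({"B"}), 3.5)]
        assert d.agglomerative_coefficient == 0.0

    def test_three_item_hand_trace(self):
        # d(A,B)=1, d(A,C)=d(B,C)=5: merge {A,B}@1 then {AB,C}@5;
        # AC = mean(1-1/5, 1-1/5, 1-5/5) = mean(0.8, 0.8, 0)
        D = pd.DataFrame(
            [[0, 1, 5], [1, 0, 5], [5, 5, 0]],
            index=list("ABC"), columns=list("ABC"),
        )
        d = agnes(D)
        assert d.heights == [1.0, 5.0]
        assert d.merges[0][:2] == (frozenset({"A"}), frozenset({"B"}))
        assert d.agglomerative_coefficient == pytest.approx(np.mean([0.8, 0.8, 0.0]))

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_naive_average_linkage(self, n, rng):
        for _ in range(20):
            D = random_dissimilarity(rng, n)
            d = agnes(D)
            merges, ac = naive_average_linkage(D)
            assert len(d.merges) == len(merges)
            for (A, B, h), (A2, B2, h2) in zip(d.merges, merges):
                assert {A, B} == {A2, B2}
                assert h == pytest.approx(h2)
            assert d.agglomerative_coefficient == pytest.approx(ac)

    def test_heights_monotone_and_ac_in_unit_interval(self, rng):
        for n in (3, 5, 7):
            d = agnes(random_dissimilarity(rng, n))
            assert np.all(np.diff(d.heights) >= -1e-12)
            assert 0.0 <= d.agglomerative_coefficient <= 1.0

    def test_scaling_distances_scales_heights_only(self, rng):
        D = random_dissimilarity(rng, 5)
        a, b = agnes(D), agnes(D * 4.0)
        for (A1, B1, h1), (A2, B2, h2) in zip(a.merges, b.merges):
            assert {A1, B1} == {A2, B2}
            assert h2 == pytest.approx(4 * h1)
        assert b.agglomerative_coefficient == pytest.approx(a.agglomerative_coefficient)

    def test_asymmetric_matrix_rejected(self):
        D = pd.DataFrame([[0, 1], [2, 0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError, match="symmetric"):
            agnes(D)

    def test_paired_design_recovered(self):
        """Two pairs of seas drawn from two distinct profiles pair up."""
        counts = pd.DataFrame(
            {"RS": [80, 10, 10], "HOT": [78, 12, 10],
             "MED": [10, 45, 45], "BATS": [12, 44, 44]},
            index=["A", "B", "C"],
        )
        D = sea_dissimilarity(counts)
        d = agnes(D)
        first_two = [frozenset().union(m[0], m[1]) for m in d.merges[:2]]
        assert frozenset({"RS", "HOT"}) in first_two
        assert frozenset({"MED", "BATS"}) in first_two


class TestNewick:
    def test_roundtrip_preserves_topology_and_depths(self, rng):
        dendropy = pytest.importorskip("dendropy")
        D = random_dissimilarity(rng, 5)
        d = agnes(D)
        nwk = to_newick(d)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {l.taxon.label for l in tree.leaf_node_iter()} == set(d.labels)
        # ultrametric: every leaf sits at final height / 2
        final = d.heights[-1] / 2
        for leaf in tree.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(final, rel=1e-6)

    def test_seaclusterer_end_to_end(self, survey):
        counts = sc.aggregate_samples(
            survey["counts"], survey["samples"], "by_sea", survey["config"].seas
        )
        rna, _ = sc.build_rna_table(counts)
        m = sc.SeaClusterer().fit(counts, rna)
        assert set(m.dissimilarity_.index) == set(survey["config"].seas)
        assert 0.0 <= m.agglomerative_coefficient_ <= 1.0
        assert to_newick(m.dendrogram_).endswith(";")
        assert m.get_params()["entropy_percentile"] == 25.0
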