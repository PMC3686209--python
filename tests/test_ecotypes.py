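"""Ecotype frequency profiles, KL divergence, box statistics, outlier flags."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import seacomp as sc
from seacomp.ecotypes import tukey_fences

from conftest import make_catalog, make_samples

CAT = make_catalog(
    [
        ("a1", "A", "G_HLII", "HLII", 0, 100),
        ("a2", "A", "G_HLI", "HLI", 0, 100),
        ("b1", "B", "G_HLII", "HLII", 100, 200),
        ("b2", "B", "G_LL", "LL", 0, 100),
    ]
)
SAMPLES = make_samples([("s1", "RS"), ("s2", "MED")])


def asg(rows):
    return pd.DataFrame(rows, columns=["read_id", "sample_id", "cluster_id", "top_genome"])


class TestKl:
    def test_identical_distributions_have_zero_divergence(self):
        assert sc.kl_divergence([0.5, 0.5], [0.5, 0.5]) == 0.0

    def test_two_term_hand_computation(self):
        expected = 0.5 * math.log(0.5 / 0.9) + 0.5 * math.log(0.5 / 0.1)
        assert sc.kl_divergence([0.5, 0.5], [0.9, 0.1]) == pytest.approx(expected)

    def test_zero_in_p_contributes_nothing(self):
        # (1,0) vs (0.5,0.5) without smoothing: the 0-term vanishes -> ln 2
        assert sc.kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(math.log(2))

    def test_smoothing_keeps_divergence_finite(self):
        assert sc.kl_divergence([0.5, 0.5], [1.0, 0.0]) == math.inf
        d = sc.kl_divergence([0.5, 0.5], [1.0, 0.0], eps=1e-6)
        assert 0 < d < math.inf

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sc.kl_divergence([1.0], [0.5, 0.5])

    def test_smoothing_preserves_distance_ordering(self, rng):
        """Rank correlation ~= 1 between raw and eps-smoothed KL to a common
        reference on strictly positive random vectors."""
        q = rng.dirichlet(np.ones(5) * 5)
        ps = rng.dirichlet(np.ones(5), size=80)
        raw = [sc.kl_divergence(p, q) for p in ps]
        sm = [sc.kl_divergence(p, q, eps=1e-5) for p in ps]
        rho = spearmanr(raw, sm).statistic
        assert rho > 0.999


class TestFrequencies:
    def test_single_ecotype_dominates(self):
        out = sc.ecotype_frequencies(
            asg([("r1", "s1", "A", "G_HLII"), ("r2", "s1", "A", "G_HLII")]),
            CAT, SAMPLES,
        )
        row = out[(out.cluster_id == "A") & (out.sea == "RS")].iloc[0]
        assert row["HLII"] == 1.0 and row["HLI"] == 0.0 and row["n_reads"] == 2

    def test_forced_tally(self):
        reads = [("r%d" % i, "s1", "A", "G_HLII") for i in range(8)]
        reads += [("r%d" % i, "s1", "A", "G_HLI") for i in range(8, 10)]
        out = sc.ecotype_frequencies(asg(reads), CAT, SAMPLES)
        row = out[(out.cluster_id == "A") & (out.sea == "RS")].iloc[0]
        assert row["HLII"] == pytest.approx(0.8) and row["HLI"] == pytest.approx(0.2)

    def test_empty_profiles_have_nan_freq_and_zero_reads(self):
        out = sc.ecotype_frequencies(asg([("r1", "s1", "A", "G_HLII")]), CAT, SAMPLES)
        empty = out[(out.cluster_id == "B") & (out.sea == "MED")].iloc[0]
        assert empty["n_reads"] == 0 and np.isnan(empty["HLII"])

    def test_invariant_to_read_duplication(self):
        reads = [("r1", "s1", "A", "G_HLII"), ("r2", "s1", "A", "G_HLI")]
        doubled = reads + [(f"{r}x", s, c, g) for r, s, c, g in reads]
        a = sc.ecotype_frequencies(asg(reads), CAT, SAMPLES)
        b = sc.ecotype_frequencies(asg(doubled), CAT, SAMPLES)
        cols = ["HLI", "HLII", "LL"]
        pd.testing.assert_frame_equal(a[cols], b[cols])

    def test_unmapped_genome_rejected(self):
        with pytest.raises(KeyError, match="G_mystery"):
            sc.ecotype_frequencies(asg([("r1", "s1", "A", "G_mystery")]), CAT, SAMPLES)

    def test_recovers_configured_mixtures(self, survey):
        """Top-hit ecotype frequencies reproduce the simulated per-read
        ecotypes exactly (noiseless hits), hence the mixtures up to binomial
        error."""
        cat, samples = survey["catalog"], survey["samples"]
        assigner = sc.ReadAssigner().fit(cat)
        merged = pd.concat(
            [assigner.transform(h).assign(sample_id=s) for s, h in survey["hits"].items()],
            ignore_index=True,
        )
        out = sc.ecotype_frequencies(merged, cat, samples)
        truth = survey["truth"].reads
        # aggregate over clusters: read-weighted mean frequency = ecotype share
        for sea in ("RS", "MED"):
            grp = out[(out.sea == sea) & (out.n_reads > 0)]
            t = truth[truth.sea == sea]["ecotype"].value_counts(normalize=True)
            for eco in ("HLI", "HLII", "LL"):
                observed = np.average(grp[eco], weights=grp["n_reads"])
                assert observed == pytest.approx(t.get(eco, 0.0), abs=1e-12)


class TestBoxSummary:
    def _profiles(self, values, sea="RS"):
        return pd.DataFrame(
            {
                "cluster_id": [f"C{i}" for i in range(len(values))],
                "sea": sea,
                "E1": values,
                "E2": [1 - v for v in values],
                "n_reads": 10,
            }
        )

    def test_single_profile_degenerate_box(self):
        out = sc.box_summary(self._profiles([0.4]))
        row = out[out.ecotype == "E1"].iloc[0]
        assert row["median"] == 0.4 and row["q1"] == row["q3"] == 0.4
        assert row["n_outliers"] == 0

    def test_lone_extreme_value_is_flagged(self):
        # {0,0,0,0,1}: q3 = 0, IQR = 0, whiskers collapse at 0 -> the 1 is out
        out = sc.box_summary(self._profiles([0, 0, 0, 0, 1]))
        row = out[out.ecotype == "E1"].iloc[0]
        q1, med, q3, lo, hi = tukey_fences(np.array([0, 0, 0, 0, 1.0]))
        assert (row["q1"], row["median"], row["q3"]) == (q1, med, q3)
        assert row["n_outliers"] == 1 and row["outlier_clusters"] == "C4"

    def test_symmetric_data_median_equals_mean(self):
        vals = [0.1, 0.2, 0.3, 0.4, 0.5]
        out = sc.box_summary(self._profiles(vals))
        assert out[out.ecotype == "E1"].iloc[0]["median"] == pytest.approx(np.mean(vals))

    def test_whiskers_clip_to_data(self, rng):
        vals = rng.beta(2, 2, size=30)
        out = sc.box_summary(self._profiles(list(vals)))
        row = out[out.ecotype == "E1"].iloc[0]
        assert row["whisker_lo"] >= vals.min() - 1e-12
        assert row["whisker_hi"] <= vals.max() + 1e-12


def brute_force_outliers(profiles, calls, w=1.5, pct=80.0, eps=1e-6):
    """Independent loop re-implementation of the two-stage flagging rule."""
    meta = ("cluster_id", "sea", "n_reads", "kl_from_mean", "prescreen_outlier", "outlier")
    eco = [c for c in profiles.columns if c not in meta]
    over = set(zip(calls[calls.direction == "over"].cluster_id,
                   calls[calls.direction == "over"].sea))
    flagged = set()
    for sea in profiles["sea"].unique():
        grp = profiles[(profiles.sea == sea) & (profiles.n_reads > 0)]
        X = grp[eco].to_numpy(float)
        mean = X.mean(axis=0)
        mean /= mean.sum()
        kl = np.array([sc.kl_divergence(x, mean, eps=eps) for x in X])
        pre = np.zeros(len(grp), bool)
        for j in range(len(eco)):
            _, _, _, lo, hi = tukey_fences(X[:, j], w=w)
            pre |= (X[:, j] < lo) | (X[:, j] > hi)
        null = [k for k, c in zip(kl, grp.cluster_id) if (c, sea) not in over]
        cut = np.percentile(null, pct)
        for i, c in enumerate(grp.cluster_id):
            if (c, sea) in over and pre[i] and kl[i] > cut:
                flagged.add((c, sea))
    return flagged


class TestOutlierFlags:
    def _profiles(self, vecs, sea="RS"):
        return pd.DataFrame(
            {
                "cluster_id": [f"C{i}" for i in range(len(vecs))],
                "sea": sea,
                "E1": [v[0] for v in vecs],
                "E2": [v[1] for v in vecs],
                "E3": [v[2] for v in vecs],
                "n_reads": 20,
            }
        )

    def _calls(self, ids, sea="RS"):
        return pd.DataFrame(
            {"cluster_id": ids, "sea": sea, "direction": "over"}
        )

    def test_identical_profiles_yield_no_outliers(self):
        prof = self._profiles([(0.3, 0.4, 0.3)] * 12)
        out = sc.flag_ecotype_outliers(prof, self._calls(["C0"]))
        assert not out["outlier"].any()
        assert np.allclose(out["kl_from_mean"], 0.0, atol=1e-9)

    def test_vertex_profile_flagged_and_matches_bruteforce(self, rng):
        vecs = [tuple(rng.dirichlet([30, 30, 30])) for _ in range(20)]
        vecs.append((0.98, 0.01, 0.01))  # enriched cluster at a vertex
        prof = self._profiles(vecs)
        calls = self._calls(["C20"])
        out = sc.flag_ecotype_outliers(prof, calls)
        assert bool(out.loc[out.cluster_id == "C20", "outlier"].iloc[0])
        got = set(zip(out[out.outlier].cluster_id, out[out.outlier].sea))
        assert got == brute_force_outliers(prof, calls)

    def test_cluster_at_the_mean_never_flagged(self, rng):
        vecs = [tuple(rng.dirichlet([5, 5, 5])) for _ in range(15)]
        mean = np.mean(vecs, axis=0)
        vecs.append(tuple(mean / mean.sum()))
        prof = self._profiles(vecs)
        out = sc.flag_ecotype_outliers(prof, self._calls(["C15"]))
        assert not bool(out.loc[out.cluster_id == "C15", "outlier"].iloc[0])

    def test_matches_bruteforce_on_random_tables(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 30))
            vecs = [tuple(rng.dirichlet(rng.uniform(0.5, 5, 3))) for _ in range(n)]
            prof = self._profiles(vecs)
            k = int(rng.integers(1, max(2, n // 4)))
            calls = self._calls([f"C{i}" for i in rng.choice(n, k, replace=False)])
            out = sc.flag_ecotype_outliers(prof, calls)
            got = set(zip(out[out.outlier].cluster_id, out[out.outlier].sea))
            assert got == brute_force_outliers(prof, calls)

    def test_empty_null_set_is_an_error(self):
        prof = self._profiles([(0.5, 0.3, 0.2)] * 3)
        with pytest.raises(ValueError, match="non-over-represented"):
            sc.flag_ecotype_outliers(prof, self._calls(["C0", "C1", "C2"]))
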