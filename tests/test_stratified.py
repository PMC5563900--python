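import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from riboload.annotation import ElementTable
from riboload.stratified import (
    cluster_profiles,
    compare_by_element,
    ecdf_and_median,
    enrich_clusters,
    hypergeometric_test,
    permutation_null_pvalues,
    read_gmt,
    wilcoxon_rank_sum,
)


def brute_force_ranksum_p(a, b, alternative="two-sided"):
    """Independent oracle: enumerate every C(n, n_a) assignment of the
    pooled values to group a and count rank sums as extreme as observed.

    Uses midranks for ties, like the convention under test, but computes
    the null distribution by raw itertools enumeration.
    """
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    n, n_a = len(pooled), len(a)
    ranks = rankdata(pooled)
    w_obs = ranks[:n_a].sum()
    mu = n_a * (n + 1) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n_a):
        w = ranks[list(idx)].sum()
        total += 1
        if alternative == "greater":
            hit = w >= w_obs - 1e-9
        elif alternative == "less":
            hit = w <= w_obs + 1e-9
        else:
            hit = abs(w - mu) >= abs(w_obs - mu) - 1e-9
        count += hit
    return count / total


class TestWilcoxonRankSum:
    def test_identical_multisets_give_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        _, p = wilcoxon_rank_sum(a, list(a))
        assert p == pytest.approx(1.0)

    def test_fully_separated_small_groups(self):
        """{1,2,3} vs {4,5,6}: 2 of the 20 rank assignments are as
        extreme, so the exact two-sided p is 0.1."""
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_constant_data_degenerate_p_one(self):
        _, p = wilcoxon_rank_sum([5.0] * 4, [5.0] * 5)
        assert p == pytest.approx(1.0)
        # same degenerate case through the large-sample path
        _, p = wilcoxon_rank_sum([5.0] * 20, [5.0] * 20)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_exact_path_matches_brute_force_enumeration(self, alternative, rng):
        """Randomised small instances, ties included, against the
        itertools enumeration oracle."""
        for _ in range(60):
            n_a = int(rng.integers(2, 6))
            n_b = int(rng.integers(2, 6))
            # draw from few distinct values to force ties often
            a = rng.integers(0, 5, n_a).astype(float)
            b = rng.integers(0, 5, n_b).astype(float)
            _, p = wilcoxon_rank_sum(a, b, alternative)
            assert p == pytest.approx(
                brute_force_ranksum_p(a, b, alternative), abs=1e-9
            )

    def test_large_sample_path_close_to_scipy(self, rng):
        from scipy.stats import mannwhitneyu

        a = rng.normal(0, 1, 40)
        b = rng.normal(0.5, 1, 35)
        u, p = wilcoxon_rank_sum(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_shifted_groups_detected(self, rng):
        a = rng.normal(1.0, 1, 100)
        b = rng.normal(0.0, 1, 100)
        _, p = wilcoxon_rank_sum(a, b)
        assert p < 1e-6

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1.0], [2.0, 3.0])


class TestCompareByElement:
    def test_split_and_medians(self, elements_two_groups):
        values = pd.Series(
            [2.0, 2.0, 2.0, 2.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
            index=[f"G{i:03d}" for i in range(10)],
        )
        c = compare_by_element(values, elements_two_groups, "uORF")
        assert (c.n_with, c.n_without) == (4, 6)
        assert c.median_with == 2.0 and c.median_without == 1.0
        assert c.n_with + c.n_without == values.notna().sum()

    def test_all_false_flags_error(self):
        values = pd.Series([1.0, 2.0, 3.0], index=["A", "B", "C"])
        empty = ElementTable({g: (False, False, False) for g in values.index})
        with pytest.raises(ValueError, match="empty group"):
            compare_by_element(values, empty, "uORF")

    def test_nan_values_dropped_before_split(self, elements_two_groups):
        values = pd.Series(
            [2.0, np.nan, 2.0, 2.0, 1.0, 1.0, np.nan, 1.0, 1.0, 1.0],
            index=[f"G{i:03d}" for i in range(10)],
        )
        c = compare_by_element(values, elements_two_groups, "uORF")
        assert (c.n_with, c.n_without) == (3, 5)

    def test_boosted_group_significant_one_sided(self, rng):
        genes = [f"G{i:03d}" for i in range(200)]
        flags = {g: (i < 60, False, False) for i, g in enumerate(genes)}
        vals = rng.normal(0, 1, 200)
        vals[:60] += 1.2
        c = compare_by_element(
            pd.Series(vals, index=genes), ElementTable(flags), "uORF",
            alternative="greater",
        )
        assert c.p_value < 1e-4
        assert c.median_with > c.median_without


class TestHypergeometric:
    def test_k_zero_gives_one(self):
        assert hypergeometric_test(0, 5, 5, 20) == pytest.approx(1.0)

    def test_full_overlap_combinatorial_value(self):
        # all 5 draws inside the 5-gene set from a 10-gene universe
        assert hypergeometric_test(5, 5, 5, 10) == pytest.approx(
            1 / comb(10, 5), rel=1e-12
        )

    def test_guards(self):
        with pytest.raises(ValueError):
            hypergeometric_test(6, 5, 5, 20)
        with pytest.raises(ValueError):
            hypergeometric_test(1, 25, 5, 20)

    def test_matches_exact_combinatorics_on_grid(self):
        """Upper-tail p agrees with direct Fraction summation to 1e-12."""
        for N in (7, 20, 41, 60):
            for K in range(0, N + 1, max(1, N // 4)):
                for n in range(0, N + 1, max(1, N // 4)):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        exact = float(
                            sum(
                                Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
                                for j in range(k, min(K, n) + 1)
                            )
                        )
                        assert hypergeometric_test(k, K, n, N) == pytest.approx(
                            exact, abs=1e-12
                        )

    def test_pmf_sums_to_one(self):
        from scipy.stats import hypergeom

        N, K, n = 60, 23, 17
        total = sum(hypergeom.pmf(j, N, K, n) for j in range(0, n + 1))
        assert total == pytest.approx(1.0, abs=1e-12)


class TestClustering:
    def test_two_archetypes_recovered(self, rng):
        """Rising and falling profiles with sigma=0.1 noise split
        perfectly into two clusters (up to label permutation)."""
        up = np.array([0.5, 1.0, 1.5])
        down = -up
        rows, truth = [], []
        for i in range(40):
            arch = up if i % 2 == 0 else down
            rows.append(arch + rng.normal(0, 0.1, 3))
            truth.append(i % 2)
        fc = pd.DataFrame(rows, index=[f"G{i}" for i in range(40)],
                          columns=["1h", "2h", "4h"])
        result = cluster_profiles(fc, k=2, seed=3)
        labels = result.labels.to_numpy()
        truth = np.array(truth)
        agree = max((labels == truth).mean(), (labels == 1 - truth).mean())
        assert agree == 1.0

    def test_k_one_rejected(self):
        fc = pd.DataFrame(np.ones((5, 3)))
        with pytest.raises(ValueError):
            cluster_profiles(fc, k=1, seed=0)

    def test_deterministic_given_seed(self, rng):
        fc = pd.DataFrame(rng.normal(0, 1, (30, 3)),
                          index=[f"G{i}" for i in range(30)])
        r1 = cluster_profiles(fc, k=3, seed=42)
        r2 = cluster_profiles(fc, k=3, seed=42)
        assert (r1.labels == r2.labels).all()

    def test_identical_profiles_stable_under_seed_change(self):
        fc = pd.DataFrame(
            np.tile([1.0, 2.0, 3.0], (12, 1)),
            index=[f"G{i}" for i in range(12)],
        )
        r1 = cluster_profiles(fc, k=2, seed=0)
        r2 = cluster_profiles(fc, k=2, seed=99)
        # flat z-scores: every gene in one effective cluster either way
        assert r1.labels.nunique() == r2.labels.nunique() == 1


class TestEnrichment:
    def test_enriched_cluster_found(self):
        labels = pd.Series(
            [0] * 10 + [1] * 10, index=[f"G{i:02d}" for i in range(20)]
        )
        gene_sets = {"setA": {f"G{i:02d}" for i in range(8)}}
        table = enrich_clusters(labels, gene_sets)
        p0 = table[table["cluster"] == 0]["p_value"].iloc[0]
        p1 = table[table["cluster"] == 1]["p_value"].iloc[0]
        assert p0 < 0.01 < p1

    def test_gmt_reader(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("setA\tdesc\tG1\tG2\nsetB\tdesc\tG3\n")
        sets = read_gmt(str(p))
        assert sets == {"setA": {"G1", "G2"}, "setB": {"G3"}}


class TestEcdf:
    def test_even_sample_median_is_central_pair_mean(self):
        table, med = ecdf_and_median([4.0, 1.0, 3.0, 2.0])
        assert med == pytest.approx(2.5)
        assert list(table["x"]) == [1.0, 2.0, 3.0, 4.0]
        assert list(table["F"]) == [0.25, 0.5, 0.75, 1.0]

    def test_ecdf_reaches_one(self, rng):
        table, _ = ecdf_and_median(rng.normal(0, 1, 101))
        assert table["F"].iloc[-1] == pytest.approx(1.0)
        assert table["x"].is_monotonic_increasing


def test_permutation_null_p_uniformity_quick(rng):
    """With random labels the rank-sum p-values are roughly uniform;
    a light 200-permutation check (the full calibration runs in the
    acceptance suite)."""
    values = pd.Series(rng.normal(0, 1, 300),
                       index=[f"G{i}" for i in range(300)])
    ps = permutation_null_pvalues(values, 60, 200, seed=5)
    frac = (ps < 0.05).mean()
    assert 0.01 <= frac <= 0.10
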