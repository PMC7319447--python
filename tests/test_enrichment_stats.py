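"""Unit tests for the statistics, each checked against an independent oracle
(direct PMF summation, exhaustive enumeration, or a reference library)."""

import itertools
import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom as sp_binom
from scipy.stats import wilcoxon as sp_wilcoxon

from mirnet.annotation_io import ScoreTable, TargetPredictionTable
from mirnet.enrichment_stats import (
    benjamini_hochberg,
    binomial_upper_tail,
    count_hit_pairs,
    exact_wilcoxon_signed_rank,
    family_export_test,
    global_permutation_test,
    local_binomial_test,
    run_local_tests_all_groups,
    target_set_enrichment,
)
from mirnet.network_build import MiRNANetwork
from mirnet.overlay import HitSet


def net_of(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return MiRNANetwork("custom", None, "syn", g)


# ---------------------------------------------------------------- binomial


def binom_tail_oracle(k, n, p):
    """Naive direct PMF summation (independent of the log-space path)."""
    return float(sp_binom.pmf(np.arange(k, n + 1), n, p).sum()) if k <= n else 0.0


class TestBinomialUpperTail:
    def test_poor_prognosis_cluster_value(self):
        # 24 hits of 48 measured, background 44/241
        assert binomial_upper_tail(24, 48, 44 / 241) == pytest.approx(6.1e-7, rel=0.01)

    def test_small_cluster_value(self):
        # 2 hits of 7 measured, background 44/241
        assert binomial_upper_tail(2, 7, 44 / 241) == pytest.approx(0.37, abs=0.005)

    def test_zero_hits_gives_one(self):
        assert binomial_upper_tail(0, 10, 0.3) == 1.0

    def test_derived_explicit_sum(self):
        # n=4, p=0.3, k=2: 1 - 0.7^4 - 4*0.3*0.7^3 = 0.3483
        assert binomial_upper_tail(2, 4, 0.3) == pytest.approx(0.3483, abs=1e-10)

    def test_matches_oracle_on_grid(self):
        for n in (1, 2, 3, 5, 8, 13, 30, 60):
            for p in (0.01, 0.1, 0.25, 0.5, 0.75, 0.9, 0.99):
                for k in range(n + 1):
                    expected = binom_tail_oracle(k, n, p)
                    got = binomial_upper_tail(k, n, p)
                    assert got == pytest.approx(expected, rel=1e-10), (k, n, p)

    def test_deep_tail_accuracy(self):
        # 1e-30-scale tails must not underflow to junk
        got = binomial_upper_tail(30, 30, 0.1)
        assert got == pytest.approx(0.1**30, rel=1e-12)

    def test_monotone_in_k(self):
        tails = [binomial_upper_tail(k, 20, 0.2) for k in range(21)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_edge_probabilities(self):
        assert binomial_upper_tail(3, 5, 0.0) == 0.0
        assert binomial_upper_tail(3, 5, 1.0) == 1.0

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            binomial_upper_tail(6, 5, 0.5)
        with pytest.raises(ValueError):
            binomial_upper_tail(1, 5, 1.5)


class TestLocalBinomialTest:
    def _setup(self, n_nodes, n_hits, n_cluster, k_hits):
        nodes = [f"m{i}" for i in range(n_nodes)]
        network = net_of([], nodes)
        hit_ids = set(nodes[:k_hits]) | set(nodes[n_cluster : n_cluster + (n_hits - k_hits)])
        hits = HitSet(set(nodes), hit_ids, "planted")
        group = set(nodes[:n_cluster])
        return group, hits, network

    def test_reference_cluster_counts(self):
        group, hits, network = self._setup(241, 44, 48, 24)
        res = local_binomial_test(group, hits, network, group_id="14q32")
        assert res.n_nodes == 241 and res.n_hits == 44
        assert res.n_cluster == 48 and res.k_hits == 24
        assert res.background_p == pytest.approx(44 / 241)
        assert res.pvalue == pytest.approx(6.1e-7, rel=0.01)

    def test_small_cluster_not_enriched(self):
        group, hits, network = self._setup(241, 44, 7, 2)
        res = local_binomial_test(group, hits, network)
        assert res.pvalue == pytest.approx(0.37, abs=0.005)

    def test_zero_hits_in_group(self):
        group, hits, network = self._setup(10, 3, 4, 0)
        assert local_binomial_test(group, hits, network).pvalue == 1.0

    def test_unmeasured_excluded_from_background(self):
        nodes = [f"m{i}" for i in range(10)]
        network = net_of([], nodes)
        # only 6 measured; background = 3/6, not 3/10
        hits = HitSet(set(nodes[:6]), set(nodes[:3]), "x")
        res = local_binomial_test(set(nodes[:4]), hits, network)
        assert res.n_nodes == 6 and res.background_p == 0.5
        assert res.n_cluster == 4  # all 4 group members measured

    def test_group_without_measured_nodes_errors(self):
        nodes = [f"m{i}" for i in range(6)]
        network = net_of([], nodes)
        hits = HitSet(set(nodes[:3]), {nodes[0]}, "x")
        with pytest.raises(ValueError, match="no measured"):
            local_binomial_test(set(nodes[4:]), hits, network)

    def test_group_outside_network_errors(self):
        network = net_of([], ["a"])
        hits = HitSet({"a"}, {"a"}, "x")
        with pytest.raises(ValueError, match="outside"):
            local_binomial_test({"zzz"}, hits, network)


# ---------------------------------------------------------------- global test


def global_tail_oracle(network, measured, n_hits, observed):
    """Exact P(randomized hit pairs > observed) by exhaustive enumeration."""
    measured = sorted(measured)
    exceeding = total = 0
    for combo in itertools.combinations(measured, n_hits):
        total += 1
        if count_hit_pairs(network, set(combo)) > observed:
            exceeding += 1
    return exceeding / total


class TestGlobalPermutationTest:
    def path4(self):
        return net_of([("A", "B"), ("B", "C"), ("C", "D")])

    def test_path_hits_AC_converges_to_half(self):
        net = self.path4()
        hits = HitSet({"A", "B", "C", "D"}, {"A", "C"}, "x")
        # exhaustive: 3 of the 6 placements have 1 hit pair > observed 0
        assert global_tail_oracle(net, hits.measured_ids, 2, 0) == 0.5
        res = global_permutation_test(net, hits, n_trials=20_000, rng_seed=1)
        assert res.observed_hit_pairs == 0
        se = math.sqrt(0.5 * 0.5 / 20_000)
        assert abs(res.pvalue_strict - 0.5) < 3 * se

    def test_path_hits_AB_maximum(self):
        net = self.path4()
        hits = HitSet({"A", "B", "C", "D"}, {"A", "B"}, "x")
        res = global_permutation_test(net, hits, n_trials=5_000, rng_seed=2)
        assert res.observed_hit_pairs == 1
        assert res.pvalue_strict == 0.0  # nothing can exceed the maximum
        assert res.pvalue_corrected == pytest.approx(1 / 5001)

    def test_all_measured_are_hits(self):
        net = self.path4()
        nodes = {"A", "B", "C", "D"}
        hits = HitSet(nodes, nodes, "x")
        res = global_permutation_test(net, hits, n_trials=1_000, rng_seed=3)
        assert res.observed_hit_pairs == 3
        assert res.pvalue_strict == 0.0
        assert res.pvalue_corrected == pytest.approx(1 / 1001)

    def test_fewer_than_two_hits_warns(self):
        net = self.path4()
        hits = HitSet({"A", "B", "C", "D"}, {"A"}, "x")
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = global_permutation_test(net, hits, n_trials=10, rng_seed=0)
        assert res.observed_hit_pairs == 0 and res.pvalue_strict == 1.0

    def test_deterministic_for_fixed_seed(self):
        net = self.path4()
        hits = HitSet({"A", "B", "C", "D"}, {"A", "C"}, "x")
        a = global_permutation_test(net, hits, n_trials=2_000, rng_seed=9)
        b = global_permutation_test(net, hits, n_trials=2_000, rng_seed=9)
        assert a == b

    def test_converges_to_enumeration_on_random_graph(self):
        rng = np.random.default_rng(4)
        g = nx.gnp_random_graph(10, 0.35, seed=5)
        g = nx.relabel_nodes(g, {i: f"m{i}" for i in g.nodes})
        net = MiRNANetwork("custom", None, "syn", g)
        measured = set(g.nodes)
        hit_ids = set(sorted(measured)[:4])
        observed = count_hit_pairs(net, hit_ids)
        exact = global_tail_oracle(net, measured, 4, observed)
        hits = HitSet(measured, hit_ids, "x")
        res = global_permutation_test(net, hits, n_trials=50_000, rng_seed=6)
        se = math.sqrt(max(exact * (1 - exact), 1e-9) / 50_000)
        assert abs(res.pvalue_strict - exact) <= 3 * se + 1e-12

    def test_hits_measured_only_randomization(self):
        # unmeasured nodes must not enter the pool: with all measured nodes
        # hits, the randomized count is constant
        net = net_of([("A", "B"), ("B", "C"), ("C", "X")], nodes=["X"])
        hits = HitSet({"A", "B", "C"}, {"A", "B", "C"}, "x")
        res = global_permutation_test(net, hits, n_trials=500, rng_seed=0)
        assert res.observed_hit_pairs == 2  # A-B, B-C; C-X excluded
        assert res.n_trials_exceeding == 0


# ---------------------------------------------------------------- wilcoxon


def wilcoxon_oracle(diffs):
    """Two-sided p by literal enumeration of all 2^n sign assignments."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = d.size
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product((1, -1), repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s > 0))
    ws = np.asarray(ws)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    p_le = np.mean(ws <= w_obs + 1e-9)
    return min(1.0, 2 * min(p_ge, p_le))


class TestExactWilcoxon:
    def test_ten_same_sign(self):
        res = exact_wilcoxon_signed_rank([0.3, 0.5, 0.7, 1.0, 1.1, 1.3, 1.7, 2.0, 2.5, 3.0])
        assert res.method == "exact"
        assert res.pvalue_two_sided == pytest.approx(2 / 2**10)

    def test_fifteen_same_sign(self):
        diffs = [0.1 * i for i in range(1, 16)]
        res = exact_wilcoxon_signed_rank(diffs)
        assert res.pvalue_two_sided == pytest.approx(2 / 2**15)

    def test_single_nonzero_difference(self):
        assert exact_wilcoxon_signed_rank([1.5]).pvalue_two_sided == 1.0

    def test_zeros_dropped(self):
        res = exact_wilcoxon_signed_rank([0.0, 0.0, 1.0, 2.0, -0.5])
        assert res.n_pairs_used == 3 and res.n_zeros_dropped == 2

    def test_all_zero_error(self):
        with pytest.raises(ValueError, match="zero"):
            exact_wilcoxon_signed_rank([0.0, 0.0])

    def test_symmetric_data_p_one(self):
        # W+ equals the distribution mean -> two-sided p capped at 1
        res = exact_wilcoxon_signed_rank([1.0, -2.0, -3.0, 4.0])
        assert res.statistic == 5.0
        assert res.pvalue_two_sided == 1.0

    def test_ties_fall_back_to_normal_approximation(self):
        res = exact_wilcoxon_signed_rank([1.0, 1.0, 2.0, -1.0, 3.0, 2.5, -0.5, 4.0])
        assert res.method == "normal-approximation"

    def test_large_n_uses_approximation(self):
        diffs = list(np.linspace(0.1, 3.0, 30))
        res = exact_wilcoxon_signed_rank(diffs)
        assert res.method == "normal-approximation"

    def test_matches_enumeration_small_n(self):
        rng = np.random.default_rng(0)
        for n in (2, 3, 5, 8):
            for _ in range(5):
                diffs = rng.normal(size=n)
                while len(np.unique(np.abs(diffs))) < n or (diffs == 0).any():
                    diffs = rng.normal(size=n)
                mine = exact_wilcoxon_signed_rank(diffs)
                assert mine.method == "exact"
                assert mine.pvalue_two_sided == pytest.approx(wilcoxon_oracle(diffs))

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            diffs = rng.normal(size=12)
            mine = exact_wilcoxon_signed_rank(diffs)
            ref = sp_wilcoxon(diffs, method="exact" if mine.method == "exact" else "approx",
                              correction=True)
            assert mine.pvalue_two_sided == pytest.approx(ref.pvalue, rel=1e-8)

    @given(st.lists(st.sampled_from([1, -1]), min_size=1, max_size=10))
    @settings(max_examples=60, deadline=None)
    def test_sign_symmetry(self, signs):
        magnitudes = np.arange(1, len(signs) + 1) * 0.5
        d = magnitudes * np.asarray(signs)
        p1 = exact_wilcoxon_signed_rank(d).pvalue_two_sided
        p2 = exact_wilcoxon_signed_rank(-d).pvalue_two_sided
        assert p1 == pytest.approx(p2)


def family_scores(rows, columns):
    df = pd.DataFrame(rows, columns=["mirna_id", *columns]).set_index("mirna_id")
    return ScoreTable(data=df)


class TestFamilyExportTest:
    def test_five_members_two_pairs(self):
        members = [f"m{i}" for i in range(5)]
        rows = [(m, 5.0 + i * 0.1, 6.0 + i * 0.23, 3.0) for i, m in enumerate(members)]
        scores = family_scores(rows, ["exoA", "exoB", "cells"])
        res = family_export_test(members, [("exoA", "cells"), ("exoB", "cells")], scores)
        assert res.n_pairs_used == 10
        assert res.pvalue_two_sided == pytest.approx(2 / 2**10)

    def test_five_members_three_pairs(self):
        members = [f"m{i}" for i in range(5)]
        rows = [
            (m, 5.0 + i * 0.1, 6.0 + i * 0.23, 7.0 + i * 0.37, 3.0)
            for i, m in enumerate(members)
        ]
        scores = family_scores(rows, ["exoA", "exoB", "mv", "cells"])
        res = family_export_test(
            members, [("exoA", "cells"), ("exoB", "cells"), ("mv", "cells")], scores
        )
        assert res.n_pairs_used == 15
        assert res.pvalue_two_sided == pytest.approx(2 / 2**15)

    def test_missing_member_difference_dropped(self):
        rows = [("m0", 5.0, 3.0), ("m1", math.nan, 3.0), ("m2", 6.0, 3.0)]
        scores = family_scores(rows, ["exo", "cells"])
        res = family_export_test(["m0", "m1", "m2"], [("exo", "cells")], scores)
        assert res.n_pairs_used == 2

    def test_too_few_differences_error(self):
        scores = family_scores([("m0", 5.0, 3.0)], ["exo", "cells"])
        with pytest.raises(ValueError, match="fewer than 2"):
            family_export_test(["m0"], [("exo", "cells")], scores)


# ---------------------------------------------------------------- batch + BH


class TestBenjaminiHochberg:
    def test_two_values_by_hand(self):
        assert benjamini_hochberg([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_single_value_unchanged(self):
        assert benjamini_hochberg([0.03]) == [0.03]

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.random(25)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert benjamini_hochberg(p.tolist()) == pytest.approx(ref.tolist())

    def test_bounds(self):
        rng = np.random.default_rng(3)
        p = rng.random(40)
        adj = np.asarray(benjamini_hochberg(p.tolist()))
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()


class TestRunLocalTestsAllGroups:
    def test_components_grouping(self):
        net = net_of([("a", "b"), ("b", "c"), ("x", "y")])
        hits = HitSet({"a", "b", "c", "x", "y"}, {"a", "b"}, "p")
        results = run_local_tests_all_groups(net, hits)
        assert len(results) == 2
        assert [r.pvalue for r in results] == sorted(r.pvalue for r in results)
        assert all(r.pvalue_bh is not None for r in results)

    def test_single_group_bh_equals_raw(self):
        net = net_of([("a", "b")])
        hits = HitSet({"a", "b"}, {"a"}, "p")
        (res,) = run_local_tests_all_groups(net, hits, [("g", {"a", "b"})])
        assert res.pvalue_bh == pytest.approx(res.pvalue)

    def test_unmeasured_groups_skipped(self):
        net = net_of([("a", "b")], nodes=["c"])
        hits = HitSet({"a", "b"}, {"a"}, "p")
        results = run_local_tests_all_groups(net, hits, [("g1", {"a", "b"}), ("g2", {"c"})])
        assert [r.group_id for r in results] == ["g1"]


# ---------------------------------------------------------------- hypergeometric


class TestTargetSetEnrichment:
    def test_derived_exhaustive_fraction(self):
        # universe 20, gene set 5, 4 targets, overlap 3:
        # (C(5,3)C(15,1) + C(5,4)C(15,0)) / C(20,4) = 155/4845
        universe = {f"g{i}" for i in range(20)}
        gene_set = {f"g{i}" for i in range(5)}
        targets = TargetPredictionTable("x", {"m1": {"g0", "g1", "g2", "g10"}})
        table = target_set_enrichment(targets, gene_set, universe)
        expected = Fraction(
            math.comb(5, 3) * math.comb(15, 1) + math.comb(5, 4) * math.comb(15, 0),
            math.comb(20, 4),
        )
        assert expected == Fraction(155, 4845)
        assert table.loc[0, "pvalue"] == pytest.approx(float(expected))

    def test_zero_overlap_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        gene_set = {"g0", "g1"}
        targets = TargetPredictionTable("x", {"m1": {"g10", "g11"}, "m2": set()})
        table = target_set_enrichment(targets, gene_set, universe).set_index("mirna_id")
        assert table.loc["m1", "pvalue"] == 1.0
        assert table.loc["m2", "pvalue"] == 1.0

    def test_degenerate_population(self):
        universe = {"g0", "g1", "g2"}
        targets = TargetPredictionTable("x", {"m1": {"g0", "g1"}})
        table = target_set_enrichment(targets, set(universe), universe)
        assert table.loc[0, "pvalue"] == pytest.approx(1.0)

    def test_validation(self):
        targets = TargetPredictionTable("x", {"m1": {"g0"}})
        with pytest.raises(ValueError, match="empty"):
            target_set_enrichment(targets, set(), set())
        with pytest.raises(ValueError, match="subset"):
            target_set_enrichment(targets, {"nope"}, {"g0"})

    def test_targets_intersected_with_universe(self):
        universe = {f"g{i}" for i in range(10)}
        gene_set = {"g0", "g1", "g2"}
        # 3 targets inside the universe, 2 outside (ignored)
        targets = TargetPredictionTable("x", {"m1": {"g0", "g1", "g5", "zz1", "zz2"}})
        table = target_set_enrichment(targets, gene_set, universe)
        assert table.loc[0, "n_in_universe"] == 3
        expected = sum(
            math.comb(3, k) * math.comb(7, 3 - k) for k in (2, 3)
        ) / math.comb(10, 3)
        assert table.loc[0, "pvalue"] == pytest.approx(expected)
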