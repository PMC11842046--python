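"""Win counting, bootstrap mechanics, summaries, FDR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from benchfield.bootstrap import (
    BootstrapDistribution,
    bh_fdr,
    bootstrap_replicate,
    pairwise_wins,
    run_bootstrap,
    sample_tool_benchmark_pairs,
    summarize,
    summarize_all,
    tally_pairs,
)
from benchfield.corpus import BenchmarkRanking, Corpus, ToolRecord
from oracles import bh_step_up, brute_force_tally


class TestPairwiseWins:
    @pytest.mark.parametrize(
        "rank, ranks, expected",
        [
            (2, list(range(1, 12)), (9, 10)),  # second of 11
            (1, [1, 2, 3, 4, 5], (4, 4)),  # best beats all
            (5, [1, 2, 3, 4, 5], (0, 4)),  # worst beats none
            (2, [1, 2, 2, 3], (1, 3)),  # a tie is a comparison, not a win
            (2, [2, 2], (0, 1)),  # all tied
        ],
    )
    def test_examples(self, rank, ranks, expected):
        assert pairwise_wins(rank, ranks) == expected

    def test_degenerate_benchmark_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pairwise_wins(1, [1])

    @settings(max_examples=50, deadline=None)
    @given(ranks=st.lists(st.integers(1, 8), min_size=2, max_size=10),
           pick=st.integers(0, 9))
    def test_matches_exhaustive_enumeration(self, ranks, pick):
        rank = ranks[pick % len(ranks)]
        others = list(ranks)
        others.remove(rank)
        wins, comps = pairwise_wins(rank, ranks)
        assert comps == len(ranks) - 1
        assert wins == sum(1 for r in others if r > rank)


class TestReplicateTallies:
    def test_two_tools_one_benchmark_trivial_tally(self):
        corpus = Corpus(
            tools=(ToolRecord("A", "a", ("F",)), ToolRecord("B", "b", ("G",))),
            benchmarks=(BenchmarkRanking("bm", "p", ".", (("A", 1), ("B", 2))),),
        )
        fmap = {"A": frozenset({"F"}), "B": frozenset({"G"})}
        tallies = tally_pairs(corpus, [("A", "bm"), ("B", "bm")], fmap)
        by_field = {t.field_label: (t.wins, t.comparisons) for t in tallies}
        assert by_field == {"F": (1, 1), "G": (0, 1)}

    def test_matches_brute_force_oracle(self, toy_corpus, toy_field_map):
        rng = np.random.default_rng(123)
        pairs = sample_tool_benchmark_pairs(toy_corpus, rng, sample_size=40)
        tallies = tally_pairs(toy_corpus, pairs, toy_field_map)
        expected = brute_force_tally(toy_corpus, pairs, toy_field_map)
        assert {t.field_label: (t.wins, t.comparisons) for t in tallies} == expected

    def test_replicate_deterministic_under_seed(self, toy_corpus, toy_field_map):
        t1 = bootstrap_replicate(
            toy_corpus, toy_field_map, None, np.random.default_rng(7), sample_size=25
        )
        t2 = bootstrap_replicate(
            toy_corpus, toy_field_map, None, np.random.default_rng(7), sample_size=25
        )
        assert t1 == t2

    def test_ineligible_field_not_tallied_but_still_compared(self, toy_corpus, toy_field_map):
        tallies = tally_pairs(
            toy_corpus,
            [("A", "bm1"), ("B", "bm1")],
            toy_field_map,
            eligible_fields={"Genetics"},
        )
        assert {t.field_label for t in tallies} == {"Genetics"}
        # A's comparisons still count B and C even though they are not tallied
        genetics = tallies[0]
        assert genetics.comparisons == 2

    def test_dual_affiliation_contributes_fully_to_both_fields(self, toy_corpus, toy_field_map):
        tallies = tally_pairs(toy_corpus, [("C", "bm2")], toy_field_map)
        by_field = {t.field_label: (t.wins, t.comparisons) for t in tallies}
        assert by_field == {
            "Genetics": (0, 1),
            "Computer Science": (0, 1),
        }


class TestRunBootstrap:
    def _single_field_corpus(self):
        tools = tuple(ToolRecord(t, t, ("F",)) for t in "ABC")
        bms = (BenchmarkRanking("bm", "p", ".", (("A", 1), ("B", 2), ("C", 3))),)
        return Corpus(tools=tools, benchmarks=bms), {
            t: frozenset({"F"}) for t in "ABC"
        }

    def test_shared_field_wins_and_losses_cancel(self):
        # within one group the 3-tool benchmark contributes 2+1+0 wins over
        # 6 comparisons, so every replicate proportion would be 0.5 if tools
        # were drawn evenly; across replicates the mean must converge there
        corpus, fmap = self._single_field_corpus()
        dists = run_bootstrap(corpus, fmap, n_replicates=300, sample_size=60, seed=3)
        assert len(dists) == 1
        mean = np.mean(dists[0].replicate_proportions)
        assert abs(mean - 0.5) < 0.02

    def test_dominant_field_proportion_is_one(self):
        tools = (ToolRecord("A", "a", ("F",)), ToolRecord("B", "b", ("G",)))
        bms = (BenchmarkRanking("bm", "p", ".", (("A", 1), ("B", 2))),)
        corpus = Corpus(tools=tools, benchmarks=bms)
        fmap = {"A": frozenset({"F"}), "B": frozenset({"G"})}
        dists = run_bootstrap(corpus, fmap, n_replicates=50, sample_size=10, seed=11)
        f = next(d for d in dists if d.field_label == "F")
        assert set(f.replicate_proportions) == {1.0}

    def test_same_seed_reproduces_distributions(self, toy_corpus, toy_field_map):
        d1 = run_bootstrap(toy_corpus, toy_field_map, n_replicates=20, sample_size=30, seed=5)
        d2 = run_bootstrap(toy_corpus, toy_field_map, n_replicates=20, sample_size=30, seed=5)
        assert d1 == d2

    def test_proportions_bounded(self, toy_corpus, toy_field_map):
        for d in run_bootstrap(toy_corpus, toy_field_map, n_replicates=50,
                               sample_size=15, seed=2):
            assert all(0.0 <= p <= 1.0 for p in d.replicate_proportions)

    def test_vectorized_path_matches_pairwise_tally_path(self, toy_corpus, toy_field_map):
        # run_bootstrap's array accumulation must agree with the explicit
        # per-pair tally for the same spawned draw streams
        seed = 17
        n_reps, size = 8, 21
        dists = run_bootstrap(toy_corpus, toy_field_map, n_replicates=n_reps,
                              sample_size=size, seed=seed)
        children = np.random.SeedSequence(seed).spawn(n_reps)
        expected: dict[str, list[float]] = {}
        for child in children:
            tallies = bootstrap_replicate(
                toy_corpus, toy_field_map, None, np.random.default_rng(child),
                sample_size=size,
            )
            for t in tallies:
                expected.setdefault(t.field_label, []).append(t.proportion)
        got = {d.field_label: list(d.replicate_proportions) for d in dists}
        assert got.keys() == expected.keys()
        for label in got:
            assert got[label] == pytest.approx(expected[label])


class TestSummarize:
    def _dist(self, props, n_tools=12):
        return BootstrapDistribution("F", "specific", tuple(props), n_tools)

    def test_null_coincidence_gives_zero_z(self):
        s = summarize(self._dist([0.5, 0.5, 0.5, 0.5]))
        assert s.z == 0.0
        assert s.p_raw == 0.5

    def test_z_formula_orientation(self):
        # mean above the null gives negative z under z = (0.5 - mu) / sd
        rng = np.random.default_rng(0)
        props = rng.normal(0.6, 0.05, size=4000)
        s = summarize(self._dist(props))
        assert s.z == pytest.approx(-2.0, abs=0.1)
        assert s.neg_z == -s.z

    def test_tail_probability_at_1_96(self):
        # construct a distribution whose |z| is essentially 1.96
        rng = np.random.default_rng(1)
        props = rng.normal(0.5 + 1.96 * 0.02, 0.02, size=200_000)
        s = summarize(self._dist(props))
        assert s.p_raw == pytest.approx(0.025, abs=0.002)

    def test_degenerate_zero_sd(self):
        s = summarize(self._dist([1.0, 1.0, 1.0]))
        assert s.z == -math.inf
        assert s.p_raw == 0.0

    def test_ci_orders_around_mean(self):
        rng = np.random.default_rng(2)
        s = summarize(self._dist(rng.beta(5, 5, size=500)))
        assert 0.0 <= s.ci_low <= s.mean_win_prop <= s.ci_high <= 1.0

    def test_two_sided_doubles_the_tail(self):
        rng = np.random.default_rng(3)
        props = rng.normal(0.55, 0.05, size=1000)
        one = summarize(self._dist(props))
        two = summarize(self._dist(props), two_sided=True)
        assert two.p_raw == pytest.approx(min(1.0, 2 * one.p_raw))


class TestFdr:
    def test_frozen_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_equal_inputs_fixed_point(self):
        assert bh_fdr([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_empty(self):
        assert bh_fdr([]) == []

    @settings(max_examples=100, deadline=None)
    @given(ps=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_matches_step_up_oracle(self, ps):
        assert bh_fdr(ps) == pytest.approx(bh_step_up(ps))

    def test_summarize_all_adjusts_within_the_family(self, toy_corpus, toy_field_map):
        dists = run_bootstrap(toy_corpus, toy_field_map, n_replicates=50,
                              sample_size=20, seed=9)
        summaries = summarize_all(dists)
        assert all(s.p_fdr >= s.p_raw - 1e-12 for s in summaries)
        assert bh_fdr([s.p_raw for s in summaries]) == pytest.approx(
            [s.p_fdr for s in summaries]
        )
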