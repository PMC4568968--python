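import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from agepath.ontology import GoDag
from agepath.semsim import (
    EdgeWeights,
    WangSimilarity,
    overlap_vs_background_test,
    pairwise_set_similarities,
    rank_sum_test,
    svalues,
    term_similarity,
)
from conftest import naive_svalues, random_dag


class TestSValues:
    def test_chain_hand_recursion(self, chain_dag):
        table = svalues("C", chain_dag)
        assert table.s_values == pytest.approx({"C": 1.0, "A": 0.8, "R": 0.64})
        assert table.sv_total == pytest.approx(2.44)

    def test_root_term(self, chain_dag):
        table = svalues("R", chain_dag)
        assert table.s_values == {"R": 1.0}
        assert table.sv_total == 1.0

    def test_diamond_takes_max_over_paths(self, diamond_dag):
        table = svalues("F", diamond_dag)
        assert table.s_values["R"] == pytest.approx(0.64)
        assert table.sv_total == pytest.approx(1 + 0.8 + 0.8 + 0.64)

    def test_part_of_weight_used(self):
        terms = {t: {"name": t, "namespace": "biological_process", "obsolete": False}
                 for t in ("R", "P")}
        dag = GoDag(terms=terms, parents={"P": (("R", "part_of"),)})
        assert svalues("P", dag).s_values["R"] == pytest.approx(0.6)

    def test_unknown_term_fatal(self, chain_dag):
        with pytest.raises(KeyError):
            svalues("NOPE", chain_dag)

    def test_sweep_matches_per_path_enumeration_on_random_dags(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            dag = random_dag(rng, int(rng.integers(5, 31)))
            engine = WangSimilarity(dag)
            for term in sorted(dag.terms):
                expected = naive_svalues(dag, term)
                got = engine.svalues(term)
                assert got.s_values == pytest.approx(expected)
                assert got.sv_total == pytest.approx(sum(expected.values()))


class TestTermSimilarity:
    def test_self_similarity_is_one(self, chain_dag, diamond_dag):
        for dag in (chain_dag, diamond_dag):
            for t in dag.terms:
                assert term_similarity(t, t, dag) == pytest.approx(1.0)

    def test_siblings_hand_value(self, sibling_dag):
        assert term_similarity("A", "B", sibling_dag) == pytest.approx(
            (0.8 + 0.8) / (1.8 + 1.8)
        )

    def test_chain_parent_hand_value(self, chain_dag):
        assert term_similarity("C", "A", chain_dag) == pytest.approx(
            3.24 / 4.24, abs=5e-5
        )

    def test_symmetric_and_bounded_on_random_dag(self):
        rng = np.random.default_rng(9)
        dag = random_dag(rng, 25)
        engine = WangSimilarity(dag)
        ids = sorted(dag.terms)
        for a, b in itertools.combinations(ids[:12], 2):
            s1, s2 = engine.sim(a, b), engine.sim(b, a)
            assert s1 == pytest.approx(s2)
            assert 0.0 <= s1 <= 1.0

    def test_chain_similarity_decays_with_distance(self):
        terms = {t: {"name": t, "namespace": "biological_process", "obsolete": False}
                 for t in ("R", "A", "B", "C")}
        dag = GoDag(terms=terms, parents={
            "A": (("R", "is_a"),), "B": (("A", "is_a"),), "C": (("B", "is_a"),),
        })
        eng = WangSimilarity(dag)
        assert eng.sim("C", "B") > eng.sim("C", "A") > eng.sim("C", "R")

    def test_cross_namespace_is_fatal(self):
        terms = {
            "B1": {"name": "b", "namespace": "biological_process", "obsolete": False},
            "M1": {"name": "m", "namespace": "molecular_function", "obsolete": False},
        }
        dag = GoDag(terms=terms, parents={})
        with pytest.raises(ValueError, match="namespace"):
            term_similarity("B1", "M1", dag)


class TestPairwiseSetSimilarities:
    def test_two_terms_one_value(self, sibling_dag):
        values, skipped = pairwise_set_similarities({"A", "B"}, sibling_dag)
        assert len(values) == 1 and skipped == 0

    def test_three_siblings_equal_values(self):
        terms = {t: {"name": t, "namespace": "biological_process", "obsolete": False}
                 for t in ("R", "A", "B", "C")}
        dag = GoDag(terms=terms, parents={
            t: (("R", "is_a"),) for t in ("A", "B", "C")
        })
        values, _ = pairwise_set_similarities({"A", "B", "C"}, dag)
        assert len(values) == 3
        assert np.allclose(values, values[0])

    def test_single_term_fatal(self, sibling_dag):
        with pytest.raises(ValueError):
            pairwise_set_similarities({"A"}, sibling_dag)


def brute_force_ranksum_p(x, y):
    """Oracle: full enumeration over all rank assignments (ties via midranks)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    observed = ranks[: len(x)].sum()
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), len(x)):
        total += 1
        if sum(ranks[i] for i in idx) >= observed - 1e-9:
            hits += 1
    return hits / total


class TestRankSumTest:
    def test_textbook_four_value_fixture(self):
        result = rank_sum_test(np.array([0.9, 0.8]), np.array([0.1, 0.2]))
        assert result.p_value == pytest.approx(1 / 6)
        assert result.method == "exact"
        assert result.statistic == 7.0  # ranks 3 + 4

    def test_no_effect_direction_gives_large_p(self):
        x = np.array([0.3, 0.5, 0.7])
        result = rank_sum_test(x, x.copy())
        assert result.p_value >= 0.5

    def test_all_tied_degenerate(self):
        result = rank_sum_test(np.full(3, 0.4), np.full(5, 0.4))
        assert result.p_value == 1.0 and result.all_tied

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_p_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(2, 6))
        n2 = int(rng.integers(2, 13 - n1))
        # quantized values force ties through a genuinely discrete support
        x = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n1)
        y = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n2)
        result = rank_sum_test(x, y)
        assert result.p_value == pytest.approx(brute_force_ranksum_p(x, y))

    def test_continuous_exact_matches_enumeration(self):
        rng = np.random.default_rng(77)
        x, y = rng.random(4), rng.random(5)
        result = rank_sum_test(x, y)
        assert result.method == "exact"
        assert result.p_value == pytest.approx(brute_force_ranksum_p(x, y))

    def test_normal_path_p_decreases_with_sample_size(self):
        rng = np.random.default_rng(123)
        previous = 1.0
        for n in (50, 200, 800):
            x = rng.normal(0.6, 0.1, size=n)
            y = rng.normal(0.5, 0.1, size=4 * n)
            p = rank_sum_test(x, y, exact_limit=10).p_value
            assert p < previous
            previous = p

    def test_calibrated_under_exchangeable_sampling(self):
        # when the overlap sample is a uniform draw of independent values the
        # one-sided rejection rate sits at alpha (this is the permutation null)
        rng = np.random.default_rng(99)
        rejections = 0
        n_reps = 800
        for _ in range(n_reps):
            pooled = rng.random(120)
            x, y = pooled[:20], pooled[20:]
            if rank_sum_test(x, y, exact_limit=10).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_reps <= 0.07


class TestOverlapVsBackground:
    def test_planted_tight_cluster_rejects(self):
        rng = np.random.default_rng(4)
        dag = random_dag(rng, 30)
        engine = WangSimilarity(dag)
        ids = sorted(dag.terms)
        # overlap: a parent and its children (high mutual similarity)
        children = [t for t in ids if any(p == ids[1] for p, _ in dag.parents.get(t, ()))]
        overlap_terms = set(children[:3]) | {ids[1]}
        if len(overlap_terms) < 3:
            overlap_terms |= {ids[2]}
        result = overlap_vs_background_test(overlap_terms, set(ids[1:]), dag,
                                            engine=engine)
        assert result.mean_overlap > result.mean_background

    def test_requires_two_terms_each(self, sibling_dag):
        with pytest.raises(ValueError):
            overlap_vs_background_test({"A"}, {"A", "B"}, sibling_dag)
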