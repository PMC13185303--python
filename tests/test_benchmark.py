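import math

import numpy as np
import pytest

from oracles import (
    oracle_consensus,
    oracle_hypergeom_ia,
    oracle_ia,
    oracle_n_ndcg,
    oracle_ndcg,
    oracle_nia,
)

from drugsig.benchmark import (
    average_indication_accuracy,
    build_consensus_list,
    expected_ndcg_random,
    hypergeometric_control_ia,
    indication_accuracy,
    monte_carlo_consensus_control,
    n_ndcg_for_indication,
    ndcg_for_indication,
    new_indication_accuracy,
    run_benchmark,
)
from drugsig.synthetic import generate_null_lists
from drugsig.types import IndicationMapping
from conftest import make_lists


def orders_of(lists):
    return {q: [n.compound_id for n in sl.neighbors] for q, sl in lists.lists.items()}


class TestIndicationAccuracy:
    def test_hand_counted_toy(self, toy_lists):
        assert indication_accuracy(toy_lists, {"A", "B", "C"}, 2) == pytest.approx(
            100 * 2 / 3
        )

    def test_perfect_recovery(self, toy_lists):
        assert indication_accuracy(toy_lists, {"D", "E"}, 1) == 100.0

    def test_miss_case(self):
        lists = make_lists(
            {"A": ["C", "D", "B"], "B": ["C", "D", "A"],
             "C": ["A", "B", "D"], "D": ["A", "B", "C"]}
        )
        assert indication_accuracy(lists, {"A", "B"}, 2) == 0.0

    def test_requires_two_approved(self, toy_lists):
        with pytest.raises(ValueError, match="at least 2"):
            indication_accuracy(toy_lists, {"A"}, 2)


class TestAverageIndicationAccuracy:
    def test_hand_mean(self, toy_lists):
        mapping = IndicationMapping({"I1": {"A", "B", "C"}, "I2": {"D", "E"}})
        assert average_indication_accuracy(toy_lists, mapping, 2) == pytest.approx(
            (100 * 2 / 3 + 100.0) / 2
        )

    def test_singleton_mapping(self, toy_lists):
        mapping = IndicationMapping({"I2": {"D", "E"}})
        assert average_indication_accuracy(toy_lists, mapping, 1) == 100.0

    def test_empty_mapping_fails(self, toy_lists):
        with pytest.raises(ValueError, match="empty"):
            average_indication_accuracy(toy_lists, IndicationMapping({}), 2)


class TestConsensus:
    def test_three_voter_toy(self, consensus_toy_lists):
        cl = build_consensus_list(consensus_toy_lists, {"A", "B", "C"}, 2)
        head = cl.entries[0]
        assert head.compound_id == "D"
        assert head.consensus_score == 3
        assert head.average_score == pytest.approx(4 / 3)

    def test_single_voter(self):
        lists = make_lists({"A": ["X", "B"], "B": ["X", "A"], "X": ["A", "B"]})
        cl = build_consensus_list(lists, {"A"}, 1)
        assert len(cl) == 1
        assert cl.entries[0].compound_id == "X"
        assert cl.entries[0].consensus_score == 1

    def test_vote_bound_with_disjoint_tops(self):
        lists = make_lists(
            {"A": ["X", "B"], "B": ["Y", "A"], "X": ["A", "B"], "Y": ["A", "B"]}
        )
        cl = build_consensus_list(lists, {"A", "B"}, 1)
        assert all(e.consensus_score <= 1 for e in cl)

    def test_zero_similarity_neighbor_casts_no_vote(self, consensus_toy_lists):
        # push A's top neighbor D to distance 1: it loses A's vote
        sl = consensus_toy_lists["A"]
        N = type(sl.neighbors[0])
        sl.neighbors = [N("D", 1.0, 1)] + sl.neighbors[1:]
        cl = build_consensus_list(consensus_toy_lists, {"A", "B", "C"}, 2)
        d = next(e for e in cl if e.compound_id == "D")
        assert d.consensus_score == 2

    def test_ordering_ties_by_average_then_id(self, consensus_toy_lists):
        cl = build_consensus_list(consensus_toy_lists, {"A", "B", "C"}, 2)
        # consensus-1 block: E (avg 1.0 from C's list), then A vs B (avg 2.0, id order)
        assert cl.compound_ids() == ["D", "E", "A", "B"]


class TestNewIndicationAccuracy:
    def test_toy_top2_misses_approved(self, consensus_toy_lists):
        cl = build_consensus_list(consensus_toy_lists, {"A", "B", "C"}, 2)
        assert new_indication_accuracy(cl, {"A", "B", "C"}, 2) == 0.0

    def test_full_recovery_with_exhaustive_cutoff(self, consensus_toy_lists):
        cl = build_consensus_list(consensus_toy_lists, {"A", "B", "C"}, 4)
        assert new_indication_accuracy(cl, {"A", "B", "C"}, len(cl)) == 100.0


class TestNDCG:
    def test_ideal_ranking(self, toy_lists):
        assert ndcg_for_indication(toy_lists, {"D", "E"}, 10) == pytest.approx(1.0)

    def test_single_relevant_at_rank_three(self):
        lists = make_lists(
            {"A": ["X", "Y", "B"], "B": ["X", "Y", "A"],
             "X": ["A", "B", "Y"], "Y": ["A", "B", "X"]}
        )
        assert ndcg_for_indication(lists, {"A", "B"}, 10) == pytest.approx(
            1 / math.log2(4)
        )

    def test_zero_when_no_hit_inside_cutoff(self):
        lists = make_lists(
            {"A": ["X", "Y", "B"], "B": ["X", "Y", "A"],
             "X": ["A", "B", "Y"], "Y": ["A", "B", "X"]}
        )
        assert ndcg_for_indication(lists, {"A", "B"}, 2) == 0.0

    def test_consensus_ndcg_hand_value(self):
        # approved {A,B}; consensus ordering [X, A, Y]: only A (rank 2) is approved
        lists = make_lists(
            {"A": ["X", "Y", "B"], "B": ["X", "A", "Y"],
             "X": ["A", "B", "Y"], "Y": ["A", "B", "X"]}
        )
        cl = build_consensus_list(lists, {"A", "B"}, 2)
        assert cl.compound_ids()[:2] == ["X", "A"]
        expected = (1 / math.log2(3)) / (1 / math.log2(2) + 1 / math.log2(3))
        assert n_ndcg_for_indication(cl, {"A", "B"}, 10) == pytest.approx(expected)

    def test_consensus_ndcg_ideal_and_zero(self, toy_lists):
        cl = build_consensus_list(toy_lists, {"D", "E"}, 1)
        assert n_ndcg_for_indication(cl, {"D", "E"}, 10) == pytest.approx(1.0)
        assert new_indication_accuracy(cl, {"D", "E"}, 10) == 100.0


class TestHypergeometricControl:
    def test_hand_binomials(self):
        assert hypergeometric_control_ia(10, 3, 3) == pytest.approx(1 - 35 / 84)
        assert hypergeometric_control_ia(3, 2, 1) == pytest.approx(0.5)

    def test_exhaustive_draw(self):
        assert hypergeometric_control_ia(20, 4, 19) == 1.0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            hypergeometric_control_ia(3, 4, 1)
        with pytest.raises(ValueError):
            hypergeometric_control_ia(10, 3, 0)

    @pytest.mark.parametrize("M,K,N", [(6, 2, 1), (8, 3, 2), (10, 4, 3), (12, 5, 4)])
    def test_matches_exhaustive_enumeration(self, M, K, N):
        assert hypergeometric_control_ia(M, K, N) == pytest.approx(
            oracle_hypergeom_ia(M, K, N), abs=1e-12
        )


class TestOracleEquivalenceOnRandomInstances:
    """Package metrics vs independent loop-based implementations on random
    small instances (M ≤ 12)."""

    def test_all_metrics_match(self):
        rng = np.random.default_rng(42)
        for trial in range(120):
            M = int(rng.integers(5, 13))
            lists = generate_null_lists(M, seed=int(rng.integers(0, 2**31)))
            ids = sorted(lists.universe)
            K = int(rng.integers(2, min(5, M) + 1))
            approved = set(
                ids[i] for i in rng.choice(M, size=K, replace=False)
            )
            cutoff = int(rng.integers(1, M))
            orders = orders_of(lists)
            assert indication_accuracy(lists, approved, cutoff) == pytest.approx(
                oracle_ia(orders, approved, cutoff), abs=1e-9
            )
            assert ndcg_for_indication(lists, approved, cutoff) == pytest.approx(
                oracle_ndcg(orders, approved, cutoff), abs=1e-9
            )
            cl = build_consensus_list(lists, approved, cutoff)
            expected = oracle_consensus(orders, approved, cutoff)
            assert [(e.compound_id, e.consensus_score) for e in cl] == [
                (cid, v) for cid, v, _ in expected
            ]
            for e, (_, _, avg) in zip(cl, expected):
                assert e.average_score == pytest.approx(avg, abs=1e-9)
            assert new_indication_accuracy(cl, approved, cutoff) == pytest.approx(
                oracle_nia(orders, approved, cutoff), abs=1e-9
            )
            assert n_ndcg_for_indication(cl, approved, cutoff) == pytest.approx(
                oracle_n_ndcg(orders, approved, cutoff), abs=1e-9
            )


class TestRunBenchmark:
    def test_null_lists_match_closed_form_control(self):
        # shuffled lists: AIA should sit near the hypergeometric chance level
        M, K = 40, 3
        reps = 150
        rng = np.random.default_rng(11)
        ids = [f"C{i:05d}" for i in range(M)]
        vals = []
        for rep in range(reps):
            lists = generate_null_lists(M, seed=int(rng.integers(0, 2**31)))
            approved = set(ids[i] for i in rng.choice(M, size=K, replace=False))
            vals.append(indication_accuracy(lists, approved, 5))
        expected = 100 * hypergeometric_control_ia(M, K, 5)
        se = np.std(vals, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(vals) - expected) < 3 * se + 1e-9

    def test_metric_set_structure_and_monotonicity(self, small_study):
        from drugsig.ranking import build_proteomic_lists

        lists = build_proteomic_lists(small_study.matrix)
        ms = run_benchmark(lists, small_study.mapping, cutoffs=(5, 10, 20), seed=0)
        for metric in ("AIA", "nAIA"):
            vals = [ms.aggregate[metric][c] for c in (5, 10, 20)]
            assert vals == sorted(vals)  # accuracy non-decreasing in cutoff
            assert all(0 <= v <= 100 for v in vals)
        for metric in ("NDCG", "nNDCG"):
            assert all(0 <= ms.aggregate[metric][c] <= 1 for c in (5, 10, 20))
        assert set(ms.per_indication) == set(small_study.mapping.associations)
        assert "AIA" in ms.control and "NDCG" in ms.control

    def test_monte_carlo_control_close_to_closed_form_ia_analogue(self):
        # nIA MC control is finite and within [0, 100]; determinism by seed
        mc1 = monte_carlo_consensus_control(
            30, 3, (5, 10), np.random.default_rng(5), reps=40
        )
        mc2 = monte_carlo_consensus_control(
            30, 3, (5, 10), np.random.default_rng(5), reps=40
        )
        assert mc1 == mc2
        assert 0 <= mc1[5]["nIA"] <= 100 and 0 <= mc1[5]["nNDCG"] <= 1

    def test_json_and_tsv_export(self, tmp_path, small_study):
        from drugsig.ranking import build_proteomic_lists

        lists = build_proteomic_lists(small_study.matrix)
        ms = run_benchmark(lists, small_study.mapping, cutoffs=(5, 10), seed=0)
        ms.to_json(tmp_path / "r.json")
        ms.to_tsv(tmp_path / "r.tsv")
        lines = (tmp_path / "r.tsv").read_text().splitlines()
        assert lines[0] == "pipeline\tmetric\tcutoff\tvalue"
        assert len(lines) == 1 + 4 * 2  # 4 aggregate metrics × 2 cutoffs
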