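import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugsig.ranking import (
    PipelineLists,
    apply_uniqueness_filter,
    build_proteomic_lists,
    build_tanimoto_lists,
    cosine_distance,
    fuse_ranks,
    fuse_score_product,
    load_pipeline_lists,
    save_pipeline_lists,
)
from drugsig.synthetic import generate_null_lists
from drugsig.types import CompoundRecord, InteractionMatrix, as_fingerprint
from conftest import make_lists


def assert_list_invariants(lists: PipelineLists):
    """The SimilarityList contract: self excluded, distances in [0,1]
    non-decreasing with rank, ranks 1..L gapless, ties in id order."""
    for qid, sl in lists.lists.items():
        ids = [n.compound_id for n in sl.neighbors]
        assert qid not in ids
        assert [n.rank for n in sl.neighbors] == list(range(1, len(sl) + 1))
        for a, b in zip(sl.neighbors, sl.neighbors[1:]):
            assert 0.0 <= a.distance <= 1.0
            assert a.distance <= b.distance
            if a.distance == b.distance:
                assert a.compound_id < b.compound_id


class TestCosineDistance:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 0), (0, 1), 1.0),
            ((2, 1), (2, 1), 0.0),
            ((1, 1), (1, 0), 1 - 1 / math.sqrt(2)),
            ((0, 0), (1, 0), 1.0),
            ((0, 0), (0, 0), 0.0),
        ],
    )
    def test_values(self, x, y, expected):
        assert cosine_distance(x, y) == pytest.approx(expected, abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            cosine_distance([1, 0], [1, 0, 0])


class TestBuildProteomicLists:
    def test_hand_example_on_unit_vectors(self):
        m = InteractionMatrix(["A", "B", "C"], ["p", "q"], [[1, 0], [1, 0], [0, 1]])
        lists = build_proteomic_lists(m)
        a = lists["A"].neighbors
        assert [(n.compound_id, n.rank) for n in a] == [("B", 1), ("C", 2)]
        assert a[0].distance == pytest.approx(0.0)
        assert a[1].distance == pytest.approx(1.0)

    def test_identical_rows_tie_by_id(self):
        m = InteractionMatrix(
            ["Z", "A", "Q"], ["p", "q"], [[1, 1], [1, 1], [1, 1]]
        )
        lists = build_proteomic_lists(m)
        assert [n.compound_id for n in lists["Z"].neighbors] == ["A", "Q"]
        assert all(n.distance == 0.0 for n in lists["Z"].neighbors)

    def test_two_compounds(self):
        m = InteractionMatrix(["A", "B"], ["p"], [[1.0], [0.5]])
        lists = build_proteomic_lists(m)
        assert len(lists["A"]) == 1 and len(lists["B"]) == 1

    def test_single_compound_fails(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_proteomic_lists(InteractionMatrix(["A"], ["p"], [[1.0]]))

    def test_invariants_on_random_matrix(self):
        rng = np.random.default_rng(5)
        m = InteractionMatrix(
            [f"C{i:02d}" for i in range(12)],
            [f"P{j}" for j in range(6)],
            rng.random((12, 6)),
        )
        assert_list_invariants(build_proteomic_lists(m))


class TestBuildTanimotoLists:
    def _compounds(self, fps):
        return [CompoundRecord(cid, fingerprint=as_fingerprint(f)) for cid, f in fps]

    def test_hand_example(self):
        lists = build_tanimoto_lists(
            self._compounds([("A", {1, 2}), ("B", {1, 2}), ("C", {3})])
        )
        a = lists["A"].neighbors
        assert [(n.compound_id, n.distance) for n in a] == [("B", 0.0), ("C", 1.0)]

    def test_identical_library_all_zero_distance(self):
        lists = build_tanimoto_lists(
            self._compounds([("A", {1}), ("B", {1}), ("C", {1})])
        )
        assert all(
            n.distance == 0.0 for sl in lists.lists.values() for n in sl.neighbors
        )

    def test_disjoint_fingerprints_order_by_id(self):
        lists = build_tanimoto_lists(
            self._compounds([("C", {1}), ("A", {2}), ("B", {3})])
        )
        assert [n.compound_id for n in lists["C"].neighbors] == ["A", "B"]
        assert all(n.distance == 1.0 for n in lists["C"].neighbors)

    def test_missing_fingerprint_names_compound(self):
        with pytest.raises(ValueError, match="'B'"):
            build_tanimoto_lists(
                [CompoundRecord("A", fingerprint=frozenset()), CompoundRecord("B")]
            )


class TestUniquenessFilter:
    def test_exact_count_zeroed(self):
        lists = generate_null_lists(101, seed=0)  # L = 100 per list
        filtered = apply_uniqueness_filter(lists, 0.02)
        assert filtered.name == "null_filtered"
        for qid in lists.lists:
            before = {n.compound_id for n in lists[qid].top(2)}
            after = {n.compound_id: n.distance for n in filtered[qid].neighbors}
            assert all(after[c] == 1.0 for c in before)
            # exactly k=2 entries moved to distance 1 (none were there before)
            assert sum(1 for d in after.values() if d == 1.0) == 2

    def test_ceil_on_short_lists(self):
        lists = generate_null_lists(50, seed=1)  # L = 49 → ceil(0.98) = 1
        filtered = apply_uniqueness_filter(lists, 0.02)
        for qid in lists.lists:
            top1 = lists[qid].neighbors[0].compound_id
            assert filtered[qid].distance_of(top1) == 1.0
            assert sum(1 for n in filtered[qid].neighbors if n.distance == 1.0) == 1

    def test_zero_distance_neighbor_moves_to_tail_tie_block(self):
        lists = make_lists({"A": ["B", "C", "D"], "B": ["A", "C", "D"],
                            "C": ["A", "B", "D"], "D": ["A", "B", "C"]})
        filtered = apply_uniqueness_filter(lists, 0.02)  # k = ceil(0.06) = 1
        assert filtered["A"].distance_of("B") == 1.0
        assert filtered["A"].rank_of("B") == 3  # last: only distance-1 entry
        assert_list_invariants(filtered)

    def test_invalid_fraction(self):
        lists = generate_null_lists(5, seed=0)
        with pytest.raises(ValueError):
            apply_uniqueness_filter(lists, 0.0)


class TestFusion:
    def _pair(self):
        a = make_lists({"A": ["B", "C"], "B": ["A", "C"], "C": ["A", "B"]}, "p1")
        b = make_lists({"A": ["C", "B"], "B": ["C", "A"], "C": ["B", "A"]}, "p2")
        return a, b

    def test_score_product_identity(self):
        a, b = self._pair()
        fused = fuse_score_product(a, b)
        for qid in a.lists:
            for n in fused[qid].neighbors:
                da = a[qid].distance_of(n.compound_id)
                db = b[qid].distance_of(n.compound_id)
                assert n.distance == pytest.approx(1 - (1 - da) * (1 - db))

    def test_score_product_commutative(self):
        a, b = self._pair()
        f1, f2 = fuse_score_product(a, b), fuse_score_product(b, a)
        for qid in a.lists:
            assert [(n.compound_id, n.distance) for n in f1[qid].neighbors] == [
                (n.compound_id, n.distance) for n in f2[qid].neighbors
            ]

    def test_fusing_with_all_zero_similarity_gives_distance_one(self):
        a, _ = self._pair()
        dead = make_lists({"A": ["B", "C"], "B": ["A", "C"], "C": ["A", "B"]}, "dead")
        for sl in dead.lists.values():
            sl.neighbors = [n.__class__(n.compound_id, 1.0, n.rank) for n in sl.neighbors]
        fused = fuse_score_product(a, dead)
        assert all(
            n.distance == 1.0 for sl in fused.lists.values() for n in sl.neighbors
        )

    def test_rank_fusion_idempotent_on_identical_pipelines(self):
        a, _ = self._pair()
        for op in ("min", "max", "mean", "sum", "product", "distance_product"):
            fused = fuse_ranks(a, a, operator=op)
            for qid in a.lists:
                assert [n.compound_id for n in fused[qid].neighbors] == [
                    n.compound_id for n in a[qid].neighbors
                ]

    def test_rank_sum_ordering(self):
        # query X: neighbor P has ranks (2,5) → key 7; Q has ranks (3,3) → key 6,
        # so Q precedes P after sum fusion
        rest = ["P", "Q", "V", "W", "X"]
        a = make_lists({"X": ["Z", "P", "Q", "W", "V"],
                        **{c: ["Z"] + [o for o in rest if o != c] for c in rest[:-1]},
                        "Z": rest}, "a")
        b = make_lists({"X": ["Z", "W", "Q", "V", "P"],
                        **{c: ["Z"] + [o for o in rest if o != c] for c in rest[:-1]},
                        "Z": rest}, "b")
        fused = fuse_ranks(a, b, operator="sum")
        assert fused["X"].rank_of("Q") < fused["X"].rank_of("P")
        # min operator: P key min(2,5)=2, Q key min(3,3)=3 → P precedes Q
        fused_min = fuse_ranks(a, b, operator="min")
        assert fused_min["X"].rank_of("P") < fused_min["X"].rank_of("Q")

    def test_universe_mismatch_fails(self):
        a, _ = self._pair()
        other = make_lists({"A": ["B"], "B": ["A"]}, "small")
        with pytest.raises(ValueError, match="universe"):
            fuse_score_product(a, other)

    def test_unknown_operator(self):
        a, b = self._pair()
        with pytest.raises(ValueError, match="operator"):
            fuse_ranks(a, b, operator="median")


@settings(max_examples=30, derandomize=True)
@given(seed=st.integers(0, 10_000), m=st.integers(3, 12))
def test_invariants_preserved_by_all_operations(seed, m):
    lists = generate_null_lists(m, seed)
    assert_list_invariants(lists)
    filtered = apply_uniqueness_filter(lists, 0.1)
    assert_list_invariants(filtered)
    assert_list_invariants(fuse_score_product(lists, filtered))
    assert_list_invariants(fuse_ranks(lists, filtered, operator="sum"))


def test_pipeline_lists_tsv_round_trip(tmp_path, toy_lists):
    p = tmp_path / "lists.tsv"
    save_pipeline_lists(toy_lists, p)
    loaded = load_pipeline_lists(p)
    for qid in toy_lists.lists:
        assert [(n.compound_id, n.distance, n.rank) for n in loaded[qid].neighbors] == [
            (n.compound_id, n.distance, n.rank) for n in toy_lists[qid].neighbors
        ]
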