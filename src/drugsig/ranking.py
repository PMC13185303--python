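"""Ranked compound similarity lists, the uniqueness filter, and fusion.

Each compound gets a similarity list: every other compound in the library
sorted by ascending distance in [0, 1]. Two list families are supported:

* proteomic — cosine distance between interaction-signature rows, and
* fingerprint (Tanimoto) — distance = 1 − Tanimoto on ECFP feature sets.

Ties are broken by lexicographic compound id everywhere, so every ordering is
a deterministic total order. The per-query uniqueness filter zeroes the
similarity of the top fraction (default 2%) of each list, pushing
near-duplicate "me too" analogs to the back; fusion operators combine two
pipelines' lists by rank or score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Sequence, Tuple, Union

import numpy as np

from .chem import tanimoto_coefficient
from .types import CompoundRecord, InteractionMatrix

PathLike = Union[str, Path]

RANK_OPERATORS = ("min", "max", "mean", "sum", "product", "distance_product")


@dataclass(frozen=True)
class Neighbor:
    compound_id: str
    distance: float
    rank: int


@dataclass
class SimilarityList:
    """One query compound's ranked neighbors (distances ascending, ranks 1..L)."""

    query_id: str
    neighbors: List[Neighbor] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.neighbors)

    def top(self, n: int) -> List[Neighbor]:
        return self.neighbors[:n]

    def distance_of(self, compound_id: str) -> float:
        for n in self.neighbors:
            if n.compound_id == compound_id:
                return n.distance
        raise KeyError(compound_id)

    def rank_of(self, compound_id: str) -> int:
        for n in self.neighbors:
            if n.compound_id == compound_id:
                return n.rank
        raise KeyError(compound_id)


@dataclass
class PipelineLists:
    """A full pipeline: one SimilarityList per compound over a shared universe."""

    name: str
    lists: Dict[str, SimilarityList] = field(default_factory=dict)

    @property
    def universe(self) -> frozenset:
        return frozenset(self.lists)

    @property
    def n_compounds(self) -> int:
        return len(self.lists)

    def __getitem__(self, query_id: str) -> SimilarityList:
        return self.lists[query_id]

    def __iter__(self):
        return iter(self.lists)


def _make_list(query_id: str, pairs: Iterable[Tuple[str, float]]) -> SimilarityList:
    """Sort (neighbor, distance) pairs by (distance, id) and assign ranks 1..L."""
    ordered = sorted(pairs, key=lambda p: (p[1], p[0]))
    return SimilarityList(
        query_id,
        [Neighbor(cid, float(d), r) for r, (cid, d) in enumerate(ordered, start=1)],
    )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def cosine_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """1 − cos(x, y) for non-negative vectors, so the result lies in [0, 1].

    An all-zero signature is maximally distant from any non-zero one (1.0)
    and identical to another all-zero one (0.0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"vector length mismatch: {x.shape} vs {y.shape}")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 and ny == 0.0:
        return 0.0
    if nx == 0.0 or ny == 0.0:
        return 1.0
    d = float(np.clip(1.0 - float(x @ y) / (nx * ny), 0.0, 1.0))
    return 0.0 if d < _ZERO_SNAP else d


#: distances below this are rounding residue of exactly-parallel vectors
_ZERO_SNAP = 1e-12


def _cosine_distance_matrix(values: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(values, axis=1)
    zero = norms == 0.0
    safe = np.where(zero, 1.0, norms)
    unit = values / safe[:, None]
    dist = np.clip(1.0 - unit @ unit.T, 0.0, 1.0)
    dist[dist < _ZERO_SNAP] = 0.0
    # all-zero rows: distance 1 to non-zero rows, 0 to other all-zero rows
    dist[zero, :] = 1.0
    dist[:, zero] = 1.0
    both = np.ix_(zero, zero)
    dist[both] = 0.0
    return dist


def build_proteomic_lists(
    matrix: InteractionMatrix, name: str = "proteomic"
) -> PipelineLists:
    """All-against-all cosine distances between interaction-signature rows."""
    ids = matrix.compound_ids
    if len(ids) < 2:
        raise ValueError("need at least 2 compounds to build similarity lists")
    dist = _cosine_distance_matrix(matrix.values)
    # lexicographic id rank used as the deterministic tie-break inside lexsort
    id_order = np.argsort(np.argsort(np.array(ids, dtype=object)))
    lists = {}
    for i, qid in enumerate(ids):
        others = np.array([j for j in range(len(ids)) if j != i])
        row = dist[i, others]
        order = np.lexsort((id_order[others], row))
        neighbors = [
            Neighbor(ids[others[k]], float(row[k]), r)
            for r, k in enumerate(order, start=1)
        ]
        lists[qid] = SimilarityList(qid, neighbors)
    return PipelineLists(name=name, lists=lists)


def build_tanimoto_lists(
    compounds: Sequence[CompoundRecord], name: str = "tanimoto"
) -> PipelineLists:
    """Distance = 1 − Tanimoto between ECFP feature sets, same tie contract."""
    if len(compounds) < 2:
        raise ValueError("need at least 2 compounds to build similarity lists")
    for c in compounds:
        if c.fingerprint is None:
            raise ValueError(f"compound {c.id!r} has no fingerprint")
    ids = [c.id for c in compounds]
    fps = {c.id: c.fingerprint for c in compounds}
    n = len(ids)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = tanimoto_coefficient(fps[ids[i]], fps[ids[j]])
            sim[i, j] = sim[j, i] = s
    lists = {}
    for i, qid in enumerate(ids):
        pairs = [(ids[j], 1.0 - sim[i, j]) for j in range(n) if j != i]
        lists[qid] = _make_list(qid, pairs)
    return PipelineLists(name=name, lists=lists)


# ---------------------------------------------------------------------------
# Uniqueness ("me too") filter
# ---------------------------------------------------------------------------

def apply_uniqueness_filter(
    lists: PipelineLists,
    top_fraction: float = 0.02,
    name: str = None,
) -> PipelineLists:
    """Zero the similarity of each query's most similar neighbors.

    Per list of length L, the k = ceil(top_fraction × L) nearest neighbors
    have their similarity set to 0 (distance set to 1), then the list is
    re-sorted. Filtered pairs stay in the list so lengths and cutoff math are
    unchanged; at distance 1 they cannot contribute to top-N recovery.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must be in (0, 1)")
    if name is None:
        name = f"{lists.name}_filtered"
    out = {}
    for qid, sl in lists.lists.items():
        k = math.ceil(top_fraction * len(sl))
        pairs = [
            (n.compound_id, 1.0 if n.rank <= k else n.distance)
            for n in sl.neighbors
        ]
        out[qid] = _make_list(qid, pairs)
    return PipelineLists(name=name, lists=out)


def apply_absolute_similarity_filter(
    lists: PipelineLists, min_similarity: float, name: str = None
) -> PipelineLists:
    """Sensitivity-check variant: zero all similarities ≥ ``min_similarity``."""
    if name is None:
        name = f"{lists.name}_absfiltered"
    out = {}
    for qid, sl in lists.lists.items():
        pairs = [
            (n.compound_id, 1.0 if (1.0 - n.distance) >= min_similarity else n.distance)
            for n in sl.neighbors
        ]
        out[qid] = _make_list(qid, pairs)
    return PipelineLists(name=name, lists=out)


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

def _check_same_universe(a: PipelineLists, b: PipelineLists) -> None:
    if a.universe != b.universe:
        raise ValueError(
            f"pipelines cover different compound universes "
            f"({len(a.universe)} vs {len(b.universe)} compounds)"
        )


def fuse_score_product(
    a: PipelineLists, b: PipelineLists, name: str = "fusion_score_product"
) -> PipelineLists:
    """Product-of-similarities fusion.

    Distances are converted to similarities (1 − d), multiplied, and converted
    back: d_f = 1 − (1 − d_a)(1 − d_b). Commutative; any pair at distance 1 in
    either pipeline stays at distance 1.
    """
    _check_same_universe(a, b)
    out = {}
    for qid in a.lists:
        db = {n.compound_id: n.distance for n in b[qid].neighbors}
        pairs = [
            (n.compound_id, 1.0 - (1.0 - n.distance) * (1.0 - db[n.compound_id]))
            for n in a[qid].neighbors
        ]
        out[qid] = _make_list(qid, pairs)
    return PipelineLists(name=name, lists=out)


_RANK_KEYS: Dict[str, Callable[[int, int], float]] = {
    "min": lambda ra, rb: float(min(ra, rb)),
    "max": lambda ra, rb: float(max(ra, rb)),
    "mean": lambda ra, rb: (ra + rb) / 2.0,
    "sum": lambda ra, rb: float(ra + rb),
    "product": lambda ra, rb: float(ra * rb),
}


def fuse_ranks(
    a: PipelineLists,
    b: PipelineLists,
    operator: str = "min",
    name: str = None,
) -> PipelineLists:
    """Rank-combination fusion (min/max/mean/sum/product of ranks) or the
    product of distances (``operator="distance_product"``).

    Neighbors are re-sorted by ascending fused key (ties by id). The stored
    distance is the fused key normalised by its operator-specific ceiling so
    it remains a distance-like value in [0, 1].
    """
    if operator not in RANK_OPERATORS:
        raise ValueError(f"unknown fusion operator {operator!r}")
    _check_same_universe(a, b)
    if name is None:
        name = f"fusion_rank_{operator}"
    out = {}
    for qid in a.lists:
        bn = {n.compound_id: n for n in b[qid].neighbors}
        L = len(a[qid])
        if operator == "distance_product":
            ceiling = 1.0
            keys = {
                n.compound_id: n.distance * bn[n.compound_id].distance
                for n in a[qid].neighbors
            }
        else:
            fn = _RANK_KEYS[operator]
            ceiling = {"min": L, "max": L, "mean": L, "sum": 2 * L, "product": L * L}[
                operator
            ]
            keys = {
                n.compound_id: fn(n.rank, bn[n.compound_id].rank)
                for n in a[qid].neighbors
            }
        pairs = [(cid, k / ceiling) for cid, k in keys.items()]
        out[qid] = _make_list(qid, pairs)
    return PipelineLists(name=name, lists=out)


# ---------------------------------------------------------------------------
# Serialization: query_id, neighbor_id, distance, rank
# ---------------------------------------------------------------------------

def save_pipeline_lists(lists: PipelineLists, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("query_id\tneighbor_id\tdistance\trank\n")
        for qid in sorted(lists.lists):
            for n in lists[qid].neighbors:
                fh.write(f"{qid}\t{n.compound_id}\t{repr(n.distance)}\t{n.rank}\n")


def load_pipeline_lists(path: PathLike, name: str = "loaded") -> PipelineLists:
    lists: Dict[str, List[Neighbor]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["query_id", "neighbor_id", "distance", "rank"]:
            raise ValueError(f"{path}: unexpected header {header}")
        for line in fh:
            if not line.strip():
                continue
            qid, nid, d, r = line.rstrip("\n").split("\t")
            lists.setdefault(qid, []).append(Neighbor(nid, float(d), int(r)))
    return PipelineLists(
        name=name,
        lists={
            qid: SimilarityList(qid, sorted(ns, key=lambda n: n.rank))
            for qid, ns in lists.items()
        },
    )
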