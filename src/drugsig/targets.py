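"""Top-target extraction and gold-standard overlap analyses.

For each candidate compound, its strongest predicted protein interactions are
ranked from its interaction-signature row. Overlap between candidate groups'
pooled top targets and curated gold-standard protein sets is quantified three
ways: (A) frequency of gold proteins' best predicted ranks across rank bins,
(B) cumulative percentage overlap as a function of rank cutoff, and (C) the
Jaccard coefficient J(A, B) = |A ∩ B| / |A ∪ B| between the pooled rank ≤ k
target set and the gold standard. "Best rank" pooling takes, for each gold
protein, the minimum rank over the group's candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .types import GoldStandardSet, InteractionMatrix


@dataclass
class TargetRanking:
    """One compound's proteins ranked by descending interaction score."""

    compound_id: str
    targets: List[Tuple[str, float, int]] = field(default_factory=list)
    # (protein_id, interaction_score, target_rank starting at 1)

    def rank_of(self, protein_id: str) -> Optional[int]:
        for pid, _, rank in self.targets:
            if pid == protein_id:
                return rank
        return None

    def proteins_within(self, rank_cutoff: int) -> frozenset:
        return frozenset(pid for pid, _, r in self.targets if r <= rank_cutoff)


@dataclass
class OverlapReport:
    """Bin frequencies, cumulative overlap and Jaccard for one group × gold."""

    bin_edges: List[Tuple[int, int]]
    bin_counts: List[int]
    bin_proportions: List[float]
    cumulative_percent: Dict[int, float]
    jaccard: float


def top_targets(matrix: InteractionMatrix, compound_id: str, k: int) -> TargetRanking:
    """The k proteins with the highest interaction score for a compound,
    ranked by descending score with ties broken by ascending protein id."""
    row = matrix.row(compound_id)
    order = sorted(
        range(len(matrix.protein_ids)),
        key=lambda j: (-row[j], matrix.protein_ids[j]),
    )[:k]
    return TargetRanking(
        compound_id,
        [
            (matrix.protein_ids[j], float(row[j]), rank)
            for rank, j in enumerate(order, start=1)
        ],
    )


def jaccard(a: Set[str], b: Set[str]) -> float:
    """|a∩b| / |a∪b|; 0 when both sets are empty."""
    union = set(a) | set(b)
    if not union:
        return 0.0
    return len(set(a) & set(b)) / len(union)


def _best_ranks(rankings: Sequence[TargetRanking], gold: GoldStandardSet) -> Dict[str, int]:
    """Minimum predicted rank per gold protein across a candidate group."""
    best: Dict[str, int] = {}
    for tr in rankings:
        for pid, _, rank in tr.targets:
            if pid in gold.proteins and (pid not in best or rank < best[pid]):
                best[pid] = rank
    return best


def rank_bin_frequencies(
    rankings: Sequence[TargetRanking],
    gold: GoldStandardSet,
    bin_width: int = 20,
    max_rank: int = 100,
) -> Tuple[List[Tuple[int, int]], List[int], List[float]]:
    """Counts of gold proteins whose best predicted rank falls in each bin
    ([1..w], [w+1..2w], ...); proportions normalised by the total number of
    overlapping gold proteins within ``max_rank``."""
    if max_rank % bin_width != 0:
        raise ValueError("max_rank must be divisible by bin_width")
    edges = [(lo + 1, lo + bin_width) for lo in range(0, max_rank, bin_width)]
    counts = [0] * len(edges)
    for rank in _best_ranks(rankings, gold).values():
        if rank <= max_rank:
            counts[(rank - 1) // bin_width] += 1
    total = sum(counts)
    props = [c / total if total else 0.0 for c in counts]
    return edges, counts, props


def cumulative_overlap(
    rankings: Sequence[TargetRanking],
    gold: GoldStandardSet,
    cutoffs: Sequence[int] = tuple(range(10, 101, 10)),
) -> Dict[int, float]:
    """Per cutoff c: 100 × |gold proteins with best predicted rank ≤ c| / |gold|."""
    if not gold.proteins:
        raise ValueError(f"gold standard {gold.name!r} is empty")
    best = _best_ranks(rankings, gold)
    return {
        c: 100.0 * sum(1 for r in best.values() if r <= c) / len(gold.proteins)
        for c in cutoffs
    }


def candidate_set_jaccard(
    rankings: Sequence[TargetRanking],
    gold: GoldStandardSet,
    rank_cutoff: int = 10,
) -> float:
    """Jaccard between the union of the group's rank ≤ cutoff targets and the gold set."""
    pooled: Set[str] = set()
    for tr in rankings:
        pooled |= tr.proteins_within(rank_cutoff)
    return jaccard(pooled, set(gold.proteins))


def random_candidate_group(
    universe: Sequence[str],
    n: int,
    seed: int,
    exclude: Optional[Set[str]] = None,
) -> List[str]:
    """A seeded uniform draw of ``n`` candidate ids (without replacement)."""
    pool = sorted(set(universe) - (exclude or set()))
    if n > len(pool):
        raise ValueError(f"group size {n} exceeds available universe {len(pool)}")
    rng = np.random.default_rng(seed)
    return [pool[i] for i in rng.choice(len(pool), size=n, replace=False)]


def compare_candidate_groups(
    matrix: InteractionMatrix,
    candidate_groups: Dict[str, List[str]],
    gold_standards: Sequence[GoldStandardSet],
    rank_cutoff: int = 10,
    bin_width: int = 20,
    max_rank: int = 100,
) -> Dict[str, Dict[str, OverlapReport]]:
    """Full overlap report per candidate group × gold standard.

    ``candidate_groups`` typically holds "top", "random" and "bottom" groups;
    the random group should be drawn with :func:`random_candidate_group` under
    a recorded seed, and the bottom group pre-filtered for ≥5 heavy atoms.
    """
    M = len(matrix.compound_ids)
    for gname, group in candidate_groups.items():
        if len(group) > M:
            raise ValueError(f"group {gname!r} larger than compound universe")
    report: Dict[str, Dict[str, OverlapReport]] = {}
    for gname, group in candidate_groups.items():
        rankings = [top_targets(matrix, cid, max_rank) for cid in group]
        report[gname] = {}
        for gold in gold_standards:
            edges, counts, props = rank_bin_frequencies(
                rankings, gold, bin_width=bin_width, max_rank=max_rank
            )
            report[gname][gold.name] = OverlapReport(
                bin_edges=edges,
                bin_counts=counts,
                bin_proportions=props,
                cumulative_percent=cumulative_overlap(rankings, gold),
                jaccard=candidate_set_jaccard(rankings, gold, rank_cutoff),
            )
    return report
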