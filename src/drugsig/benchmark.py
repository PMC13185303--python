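"""Leave-one-out benchmarking of similarity-list pipelines.

Given a pipeline's similarity lists and an indication → approved-drug mapping
(restricted to indications with at least two approved drugs), four metric
families quantify how well approved drugs recover each other:

* IA / AIA — indication accuracy: the percentage of approved drugs whose
  top-N neighbors contain at least one *other* approved drug for the same
  indication, averaged (unweighted) across indications for AIA.
* nIA / nAIA — the consensus-list analogs: the percentage of approved drugs
  appearing within the top N of the indication's consensus list.
* NDCG — normalized discounted cumulative gain of approved-drug positions in
  the similarity lists (binary relevance, log2(j+1) discount, ideal DCG
  truncated at min(#relevant, cutoff)), averaged over approved queries.
* nNDCG — the same construction applied once to the consensus ordering.

The chance baseline for IA is a closed-form hypergeometric: the probability
that a uniformly random draw of N of the other M−1 compounds contains at
least one of the K−1 other approved drugs. For the consensus metrics no
closed form is used; a seeded Monte-Carlo control permutes every voter's
list instead.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence, Set, Union

import numpy as np
from scipy.stats import hypergeom

from .ranking import PipelineLists
from .types import ConsensusEntry, ConsensusList, IndicationMapping

PathLike = Union[str, Path]

DEFAULT_CUTOFFS = (10, 25, 50, 100)


def _check_cutoffs(cutoffs: Sequence[int]) -> list:
    cutoffs = list(cutoffs)
    if not cutoffs or any(c <= 0 for c in cutoffs):
        raise ValueError("cutoffs must be positive integers")
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be strictly increasing")
    return cutoffs


def _check_approved(lists: PipelineLists, approved: Set[str], minimum: int) -> None:
    if len(approved) < minimum:
        raise ValueError(f"need at least {minimum} approved drugs, got {len(approved)}")
    missing = set(approved) - lists.universe
    if missing:
        raise ValueError(f"approved drugs not in compound universe: {sorted(missing)}")


# ---------------------------------------------------------------------------
# Similarity-list metrics
# ---------------------------------------------------------------------------

def indication_accuracy(
    lists: PipelineLists, approved: Set[str], cutoff: int
) -> float:
    """Percentage of approved drugs whose top-``cutoff`` neighbors contain at
    least one other approved drug for the same indication (leave-one-out)."""
    _check_approved(lists, approved, 2)
    hits = 0
    for drug in approved:
        top = {n.compound_id for n in lists[drug].top(cutoff)}
        if top & (set(approved) - {drug}):
            hits += 1
    return 100.0 * hits / len(approved)


def average_indication_accuracy(
    lists: PipelineLists, mapping: IndicationMapping, cutoff: int
) -> float:
    """Unweighted mean IA across all (benchmarkable) indications."""
    if mapping.n_indications == 0:
        raise ValueError("empty indication mapping")
    return float(
        np.mean(
            [indication_accuracy(lists, appr, cutoff) for _, appr in mapping.items()]
        )
    )


def ndcg_for_indication(
    lists: PipelineLists, approved: Set[str], cutoff: int
) -> float:
    """Mean NDCG@cutoff over approved query drugs (binary relevance)."""
    _check_approved(lists, approved, 2)
    approved = set(approved)
    idcg = sum(
        1.0 / math.log2(j + 1) for j in range(1, min(len(approved) - 1, cutoff) + 1)
    )
    scores = []
    for drug in approved:
        relevant = approved - {drug}
        dcg = sum(
            1.0 / math.log2(n.rank + 1)
            for n in lists[drug].top(cutoff)
            if n.compound_id in relevant
        )
        scores.append(dcg / idcg)
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Consensus lists and their metrics
# ---------------------------------------------------------------------------

def build_consensus_list(
    lists: PipelineLists, approved: Set[str], per_list_cutoff: int
) -> ConsensusList:
    """Vote-count consensus over the approved drugs' similarity lists.

    Each approved drug's list casts one vote for every compound in its top
    ``per_list_cutoff`` positions that has positive similarity (distance < 1;
    a zero-similarity neighbor does not contribute). Entries with at least
    one vote are ordered by descending consensus score, then ascending mean
    rank over the lists in which they appeared, then ascending id.
    """
    if not approved:
        raise ValueError("need at least one approved drug to build a consensus list")
    if per_list_cutoff < 1:
        raise ValueError("per_list_cutoff must be >= 1")
    _check_approved(lists, set(approved), 1)
    votes: Dict[str, list] = {}
    for drug in approved:
        for n in lists[drug].top(per_list_cutoff):
            if n.distance < 1.0:
                votes.setdefault(n.compound_id, []).append(n.rank)
    entries = [
        ConsensusEntry(
            compound_id=cid,
            consensus_score=len(ranks),
            average_score=float(np.mean(ranks)),
            approved=cid in approved,
        )
        for cid, ranks in votes.items()
    ]
    entries.sort(key=lambda e: (-e.consensus_score, e.average_score, e.compound_id))
    return ConsensusList(entries)


def new_indication_accuracy(
    consensus: ConsensusList, approved: Set[str], cutoff: int
) -> float:
    """Percentage of approved drugs within the top ``cutoff`` of the consensus list."""
    if not approved:
        raise ValueError("empty approved set")
    top = {e.compound_id for e in consensus.top(cutoff)}
    return 100.0 * len(top & set(approved)) / len(approved)


def n_ndcg_for_indication(
    consensus: ConsensusList, approved: Set[str], cutoff: int
) -> float:
    """NDCG@cutoff of approved-drug positions in the consensus ordering."""
    if not approved:
        raise ValueError("empty approved set")
    idcg = sum(
        1.0 / math.log2(j + 1) for j in range(1, min(len(approved), cutoff) + 1)
    )
    dcg = sum(
        1.0 / math.log2(pos + 1)
        for pos, e in enumerate(consensus.top(cutoff), start=1)
        if e.compound_id in approved
    )
    return dcg / idcg


# ---------------------------------------------------------------------------
# Random controls
# ---------------------------------------------------------------------------

def hypergeometric_control_ia(M: int, K: int, N: int) -> float:
    """Chance probability of an IA hit for one query drug.

    The probability that a uniformly random size-``N`` subset of the ``M−1``
    non-query compounds contains at least one of the ``K−1`` other approved
    drugs: 1 − C(M−K, N)/C(M−1, N), and 1 when N > M − K.
    """
    if not (M >= K >= 2):
        raise ValueError("require M >= K >= 2")
    if N < 1:
        raise ValueError("require N >= 1")
    if N > M - K:
        return 1.0
    return float(hypergeom.sf(0, M - 1, K - 1, N))


def expected_ndcg_random(M: int, K: int, cutoff: int) -> float:
    """Exact expected NDCG@cutoff under a uniformly random neighbor order.

    Position exchangeability gives E[rel_j] = (K−1)/(M−1) at every position,
    and the ideal DCG is a constant, so the expectation passes through the
    ratio exactly.
    """
    if not (M >= K >= 2):
        raise ValueError("require M >= K >= 2")
    c = min(cutoff, M - 1)
    e_dcg = (K - 1) / (M - 1) * sum(1.0 / math.log2(j + 1) for j in range(1, c + 1))
    idcg = sum(1.0 / math.log2(j + 1) for j in range(1, min(K - 1, cutoff) + 1))
    return e_dcg / idcg


def _null_rank_matrix(M: int, n_voters: int, rng: np.random.Generator) -> np.ndarray:
    """Ranks (1..M−1) each voter assigns to every compound under random
    ranking; a voter's own rank is set beyond any cutoff."""
    ranks = np.empty((n_voters, M), dtype=int)
    for v in range(n_voters):
        perm = rng.permutation(M - 1) + 1  # ranks of the other M-1 compounds
        row = np.empty(M, dtype=int)
        row[:v] = perm[:v]
        row[v] = M  # self: never within a cutoff
        row[v + 1 :] = perm[v:]
        ranks[v] = row
    return ranks


def monte_carlo_consensus_control(
    M: int,
    K: int,
    cutoffs: Sequence[int],
    rng: np.random.Generator,
    reps: int = 100,
) -> Dict[int, Dict[str, float]]:
    """Monte-Carlo nIA / nNDCG under random ranking.

    Simulates ``reps`` studies where each of K voters ranks the other M−1
    compounds uniformly at random (voters double as the approved drugs,
    occupying the first K universe slots). Returns per-cutoff means.
    """
    cutoffs = _check_cutoffs(cutoffs)
    acc = {c: {"nIA": [], "nNDCG": []} for c in cutoffs}
    for _ in range(reps):
        ranks = _null_rank_matrix(M, K, rng)
        for c in cutoffs:
            voted = ranks <= c
            scores = voted.sum(axis=0)
            with np.errstate(invalid="ignore"):
                avg = np.where(
                    scores > 0, (ranks * voted).sum(axis=0) / np.maximum(scores, 1), 0.0
                )
            idx = np.arange(M)
            has_vote = scores > 0
            order = np.lexsort((idx, avg, -scores))
            order = order[has_vote[order]]
            top = order[:c]
            approved_mask = top < K
            nia = 100.0 * approved_mask.sum() / K
            idcg = sum(
                1.0 / math.log2(j + 1) for j in range(1, min(K, c) + 1)
            )
            dcg = sum(
                1.0 / math.log2(pos + 1)
                for pos, a in enumerate(approved_mask, start=1)
                if a
            )
            acc[c]["nIA"].append(nia)
            acc[c]["nNDCG"].append(dcg / idcg)
    return {
        c: {m: float(np.mean(v)) for m, v in d.items()} for c, d in acc.items()
    }


# ---------------------------------------------------------------------------
# Full benchmark run
# ---------------------------------------------------------------------------

@dataclass
class MetricSet:
    """Benchmark results: per-indication and aggregate metrics with controls.

    ``per_indication[ind][metric][cutoff]`` and ``aggregate[metric][cutoff]``;
    metrics are "IA"/"nIA" (percent), "NDCG"/"nNDCG" (in [0, 1]). Controls use
    the same shape under ``control``.
    """

    pipeline: str
    cutoffs: list
    per_indication: dict = field(default_factory=dict)
    aggregate: dict = field(default_factory=dict)
    control: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pipeline": self.pipeline,
            "cutoffs": self.cutoffs,
            "per_indication": self.per_indication,
            "aggregate": self.aggregate,
            "control": self.control,
        }

    def to_json(self, path: PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_tsv(self, path: PathLike) -> None:
        """Flat export: pipeline, metric, cutoff, value (aggregates only)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("pipeline\tmetric\tcutoff\tvalue\n")
            for metric in sorted(self.aggregate):
                for cutoff in self.cutoffs:
                    fh.write(
                        f"{self.pipeline}\t{metric}\t{cutoff}\t"
                        f"{self.aggregate[metric][cutoff]}\n"
                    )


_AGGREGATE_NAMES = {"IA": "AIA", "nIA": "nAIA", "NDCG": "NDCG", "nNDCG": "nNDCG"}


def run_benchmark(
    lists: PipelineLists,
    mapping: IndicationMapping,
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
    voting_cutoff: Optional[int] = None,
    control: str = "closed_form",
    seed: Optional[int] = None,
    mc_reps: int = 100,
) -> MetricSet:
    """Benchmark one pipeline against a drug–indication mapping.

    Per indication and cutoff N: IA and NDCG on the similarity lists, nIA and
    nNDCG on the consensus list built with per-list voting cutoff
    ``voting_cutoff`` (default: N itself). ``control="closed_form"`` reports
    the hypergeometric IA baseline and exact expected NDCG; ``"monte_carlo"``
    additionally estimates nIA/nNDCG baselines from seeded permutation nulls.
    """
    cutoffs = _check_cutoffs(cutoffs)
    if control not in ("closed_form", "monte_carlo"):
        raise ValueError(f"unknown control mode {control!r}")
    if mapping.n_indications == 0:
        raise ValueError("empty indication mapping")
    M = len(lists.universe)
    rng = np.random.default_rng(seed)
    per_ind: dict = {}
    for ind, approved in mapping.items():
        approved = set(approved)
        metrics = {m: {} for m in ("IA", "nIA", "NDCG", "nNDCG")}
        for N in cutoffs:
            vc = voting_cutoff if voting_cutoff is not None else N
            consensus = build_consensus_list(lists, approved, vc)
            metrics["IA"][N] = indication_accuracy(lists, approved, N)
            metrics["NDCG"][N] = ndcg_for_indication(lists, approved, N)
            metrics["nIA"][N] = new_indication_accuracy(consensus, approved, N)
            metrics["nNDCG"][N] = n_ndcg_for_indication(consensus, approved, N)
        per_ind[ind] = metrics

    aggregate = {
        _AGGREGATE_NAMES[m]: {
            N: float(np.mean([per_ind[ind][m][N] for ind in per_ind])) for N in cutoffs
        }
        for m in ("IA", "nIA", "NDCG", "nNDCG")
    }

    ctrl: dict = {"AIA": {}, "NDCG": {}}
    for N in cutoffs:
        ctrl["AIA"][N] = 100.0 * float(
            np.mean(
                [
                    hypergeometric_control_ia(M, len(appr), N)
                    for _, appr in mapping.items()
                ]
            )
        )
        ctrl["NDCG"][N] = float(
            np.mean(
                [expected_ndcg_random(M, len(appr), N) for _, appr in mapping.items()]
            )
        )
    if control == "monte_carlo":
        nctrl = {"nAIA": {N: [] for N in cutoffs}, "nNDCG": {N: [] for N in cutoffs}}
        for _, approved in mapping.items():
            mc = monte_carlo_consensus_control(
                M, len(approved), cutoffs, rng, reps=mc_reps
            )
            for N in cutoffs:
                nctrl["nAIA"][N].append(mc[N]["nIA"])
                nctrl["nNDCG"][N].append(mc[N]["nNDCG"])
        ctrl["nAIA"] = {N: float(np.mean(v)) for N, v in nctrl["nAIA"].items()}
        ctrl["nNDCG"] = {N: float(np.mean(v)) for N, v in nctrl["nNDCG"].items()}

    return MetricSet(
        pipeline=lists.name,
        cutoffs=cutoffs,
        per_indication=per_ind,
        aggregate=aggregate,
        control=ctrl,
    )
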