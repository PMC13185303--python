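"""Ranked candidate generation for an indication.

Candidates are ranked by consensus: the number of approved drugs for the
indication in whose top-N similarity lists the candidate appears, then by its
average rank over those lists. Each entry carries a binomial tail probability
— the chance of collecting at least that many votes if every voter ranked the
other compounds uniformly at random, with per-list success probability
p = N/(M−1) for a universe of M compounds. Approved drugs themselves are
retained in the output and flagged rather than removed; "novel-only"
filtering is a presentation choice left to the caller.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Set, Union

from scipy.stats import binom

from .benchmark import build_consensus_list
from .ranking import PipelineLists
from .types import ConsensusEntry, ConsensusList

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def binomial_tail_probability(c: int, n: int, p: float) -> float:
    """P(X ≥ c) for X ~ Binomial(n, p)."""
    if not 0 <= c <= n:
        raise ValueError(f"require 0 <= c <= n, got c={c}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"require 0 <= p <= 1, got p={p}")
    if c == 0:
        return 1.0
    return float(binom.sf(c - 1, n, p))


def predict_candidates(
    lists: PipelineLists,
    approved: Set[str],
    per_list_cutoff: int = 100,
    top_k: int = 100,
    exclude_approved: bool = False,
) -> ConsensusList:
    """Consensus-ranked candidate list for one indication.

    ``per_list_cutoff`` is the voting depth in each approved drug's similarity
    list; ``top_k`` truncates the output. The binomial null uses
    n = number of voters and p = per_list_cutoff/(M−1).
    """
    approved = set(approved)
    if not approved:
        raise ValueError("need at least one approved drug")
    consensus = build_consensus_list(lists, approved, per_list_cutoff)
    M = len(lists.universe)
    n_voters = len(approved)
    p = per_list_cutoff / (M - 1)
    logger.info(
        "binomial null for candidate probabilities: n=%d voters, p=%d/(%d-1)=%.6g",
        n_voters, per_list_cutoff, M, p,
    )
    entries = []
    for e in consensus:
        if exclude_approved and e.approved:
            continue
        entries.append(
            ConsensusEntry(
                compound_id=e.compound_id,
                consensus_score=e.consensus_score,
                average_score=e.average_score,
                probability=binomial_tail_probability(e.consensus_score, n_voters, p),
                approved=e.approved,
            )
        )
    return ConsensusList(entries[:top_k])


def export_prediction_table(consensus: ConsensusList, path: PathLike) -> None:
    """Write a prediction table: drug_rank, consensus_score, average_score,
    probability, drug_name, plus an approved-for-indication flag."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "drug_rank\tconsensus_score\taverage_score\tprobability\tdrug_name\tapproved\n"
        )
        for rank, e in enumerate(consensus, start=1):
            prob = "" if e.probability is None else repr(float(e.probability))
            fh.write(
                f"{rank}\t{e.consensus_score}\t{repr(float(e.average_score))}\t"
                f"{prob}\t{e.compound_id}\t{int(e.approved)}\n"
            )


def load_prediction_table(path: PathLike) -> ConsensusList:
    entries = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = [
            "drug_rank", "consensus_score", "average_score",
            "probability", "drug_name", "approved",
        ]
        if header != expected:
            raise ValueError(f"{path}: unexpected header {header}")
        for line in fh:
            if not line.strip():
                continue
            _, cs, avg, prob, name, appr = line.rstrip("\n").split("\t")
            entries.append(
                ConsensusEntry(
                    compound_id=name,
                    consensus_score=int(cs),
                    average_score=float(avg),
                    probability=float(prob) if prob != "" else None,
                    approved=bool(int(appr)),
                )
            )
    return ConsensusList(entries)
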