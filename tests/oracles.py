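"""Independent brute-force reference implementations.

Everything here is written from the metric definitions with plain loops,
exhaustive enumeration and direct summation, deliberately sharing no code
with the package. Used to cross-check the package on small instances.
"""

import itertools
import math
from typing import Dict, List, Set


def oracle_ia(orders: Dict[str, List[str]], approved: Set[str], cutoff: int) -> float:
    hits = 0
    for drug in approved:
        top = orders[drug][:cutoff]
        if any(n in approved and n != drug for n in top):
            hits += 1
    return 100.0 * hits / len(approved)


def oracle_ndcg(orders: Dict[str, List[str]], approved: Set[str], cutoff: int) -> float:
    idcg = 0.0
    for j in range(1, min(len(approved) - 1, cutoff) + 1):
        idcg += 1.0 / math.log2(j + 1)
    total = 0.0
    for drug in approved:
        dcg = 0.0
        for pos, n in enumerate(orders[drug][:cutoff], start=1):
            if n in approved and n != drug:
                dcg += 1.0 / math.log2(pos + 1)
        total += dcg / idcg
    return total / len(approved)


def oracle_consensus(
    orders: Dict[str, List[str]], approved: Set[str], cutoff: int
) -> List[tuple]:
    """[(compound_id, votes, mean_rank)] ordered by (-votes, mean_rank, id)."""
    tally: Dict[str, List[int]] = {}
    for drug in approved:
        for pos, n in enumerate(orders[drug][:cutoff], start=1):
            tally.setdefault(n, []).append(pos)
    rows = [(cid, len(r), sum(r) / len(r)) for cid, r in tally.items()]
    rows.sort(key=lambda t: (-t[1], t[2], t[0]))
    return rows


def oracle_nia(orders: Dict[str, List[str]], approved: Set[str], cutoff: int) -> float:
    cons = oracle_consensus(orders, approved, cutoff)
    top = {cid for cid, _, _ in cons[:cutoff]}
    return 100.0 * len(top & approved) / len(approved)


def oracle_n_ndcg(
    orders: Dict[str, List[str]], approved: Set[str], cutoff: int
) -> float:
    cons = oracle_consensus(orders, approved, cutoff)
    idcg = sum(
        1.0 / math.log2(j + 1) for j in range(1, min(len(approved), cutoff) + 1)
    )
    dcg = sum(
        1.0 / math.log2(pos + 1)
        for pos, (cid, _, _) in enumerate(cons[:cutoff], start=1)
        if cid in approved
    )
    return dcg / idcg


def oracle_hypergeom_ia(M: int, K: int, N: int) -> float:
    """Exhaustive enumeration: draw N of the M−1 non-query compounds, count
    draws containing at least one of the K−1 other approved drugs."""
    others = list(range(M - 1))
    approved_others = set(range(K - 1))
    if N > len(others):
        N = len(others)
    hits = total = 0
    for draw in itertools.combinations(others, N):
        total += 1
        if approved_others & set(draw):
            hits += 1
    return hits / total


def oracle_binomial_tail(c: int, n: int, p: float) -> float:
    return sum(
        math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(c, n + 1)
    )


def oracle_score(query: frozenset, sites) -> float:
    """Brute force over all sites: best Dice, ties to higher confidence."""
    if not sites:
        return 0.0
    def dice(a, b):
        return 0.0 if not a and not b else 2 * len(a & b) / (len(a) + len(b))
    best_d = max(dice(query, s.template_ligand) for s in sites)
    best_conf = max(
        s.confidence for s in sites if dice(query, s.template_ligand) == best_d
    )
    return best_d * best_conf
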