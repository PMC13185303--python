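from typing import Dict, List

import pytest

from drugsig.ranking import Neighbor, PipelineLists, SimilarityList
from drugsig.synthetic import SyntheticConfig, generate_study


def make_lists(orders: Dict[str, List[str]], name: str = "toy") -> PipelineLists:
    """Build a pipeline from explicit neighbor orders.

    Neighbor j of a list of length L gets synthetic distance j/(L+1), so
    distances are strictly increasing and every neighbor has positive
    similarity (distance < 1).
    """
    lists = {}
    for q, order in orders.items():
        L = len(order)
        lists[q] = SimilarityList(
            q, [Neighbor(nid, r / (L + 1), r) for r, nid in enumerate(order, start=1)]
        )
    return PipelineLists(name=name, lists=lists)


@pytest.fixture
def toy_lists() -> PipelineLists:
    """5-compound universe; approved {A,B,C}: A and B have an approved hit in
    their top 2, C does not → IA@2 = 66.667. Approved {D,E} recover each
    other at rank 1 → IA = 100 at any cutoff."""
    return make_lists(
        {
            "A": ["B", "D", "C", "E"],
            "B": ["D", "A", "C", "E"],
            "C": ["D", "E", "A", "B"],
            "D": ["E", "A", "B", "C"],
            "E": ["D", "A", "B", "C"],
        }
    )


@pytest.fixture
def consensus_toy_lists() -> PipelineLists:
    """Voting toy: approved {A,B,C} with top-2 prefixes A:[D,B], B:[D,A],
    C:[E,D] → D gets consensus 3 with mean rank 4/3."""
    return make_lists(
        {
            "A": ["D", "B", "C", "E"],
            "B": ["D", "A", "C", "E"],
            "C": ["E", "D", "A", "B"],
            "D": ["A", "B", "C", "E"],
            "E": ["A", "B", "C", "D"],
        }
    )


@pytest.fixture(scope="session")
def small_study():
    """A small planted-signal study reused across tests."""
    return generate_study(
        SyntheticConfig(
            seed=7,
            n_compounds=60,
            n_proteins=40,
            n_indications=6,
            drugs_per_indication=3,
            drivers_per_indication=4,
            signal=0.8,
            noise_sd=0.02,
            background_density=0.2,
            n_analog_pairs=3,
        )
    )
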