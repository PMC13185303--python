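"""Compound–protein interaction scoring from binding-site predictions.

A protein is represented by its predicted binding sites, each carrying a
confidence in [0, 1] and the fingerprint of the template ligand bound in the
structure the site was inferred from. The interaction score between a query
compound and a protein is a docking surrogate:

    score = Dice(query, best template) × confidence of that site

where "best template" is the site whose template ligand has the highest Dice
similarity to the query (ties broken by higher confidence, then site id).
A protein with no predicted sites scores 0 against every compound. Applying
the rule between every compound and every protein yields the compound-proteome
interaction signature matrix.

The selection rule is configurable: ``mode="argmax_dice"`` (default) picks the
most chemically similar template first and then multiplies by its confidence;
``mode="max_product"`` maximises the product Dice × confidence directly.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Sequence

import numpy as np

from .chem import dice_coefficient
from .types import (
    BindingSitePrediction,
    CompoundRecord,
    Fingerprint,
    InteractionMatrix,
    ProteinRecord,
)

logger = logging.getLogger(__name__)

#: protein_id -> list of BindingSitePrediction
SiteLibrary = Dict[str, List[BindingSitePrediction]]


def score_compound_protein(
    query: Fingerprint,
    sites: Sequence[BindingSitePrediction],
    mode: str = "argmax_dice",
) -> float:
    """Interaction score between a query fingerprint and one protein's sites.

    Returns 0.0 when the protein has no predicted sites. Invariant to the
    order of ``sites``.
    """
    if mode not in ("argmax_dice", "max_product"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    if not sites:
        return 0.0
    best = 0.0
    if mode == "argmax_dice":
        # (dice, confidence) lexicographic max; site id as a final determinism tie-break
        key = (-1.0, -1.0, "")
        for s in sites:
            d = dice_coefficient(query, s.template_ligand)
            k = (d, s.confidence, s.site_id)
            if k > key:
                key = k
                best = d * s.confidence
    else:
        for s in sites:
            best = max(best, dice_coefficient(query, s.template_ligand) * s.confidence)
    return best


def build_signature_matrix(
    compounds: Sequence[CompoundRecord],
    sites: SiteLibrary,
    proteins: Sequence[ProteinRecord],
    mode: str = "argmax_dice",
) -> InteractionMatrix:
    """Score every compound against every protein.

    Every compound must carry a fingerprint; proteins absent from the site
    library score 0 (logged once per protein).
    """
    for c in compounds:
        if c.fingerprint is None:
            raise ValueError(f"compound {c.id!r} has no fingerprint; cannot score")
    for p in proteins:
        if p.id not in sites or not sites[p.id]:
            logger.info("protein %s has no predicted sites; scores 0", p.id)
    values = np.zeros((len(compounds), len(proteins)))
    for j, p in enumerate(proteins):
        psites = sites.get(p.id, [])
        if not psites:
            continue
        for i, c in enumerate(compounds):
            values[i, j] = score_compound_protein(c.fingerprint, psites, mode=mode)
    return InteractionMatrix(
        [c.id for c in compounds], [p.id for p in proteins], values
    )
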