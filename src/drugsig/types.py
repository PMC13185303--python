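"""Core domain types shared across the pipeline.

The central object is the :class:`InteractionMatrix`, a compounds-by-proteins
matrix of predicted interaction scores in [0, 1] ("interaction signatures":
each row describes one compound's predicted behaviour across a proteome).
Everything downstream — similarity lists, benchmarking, consensus predictions,
target analysis — consumes these types.

Fingerprints are represented as sparse sets of non-negative integer feature
identifiers (the ECFP4 convention: hashed circular substructures of radius 2).
Equality is set equality; the empty set is a valid fingerprint for a molecule
with no perceived features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

#: Sparse fingerprint: a (frozen) set of non-negative integer feature ids.
Fingerprint = frozenset

CompoundStatus = Literal["approved", "other"]


def as_fingerprint(features: Iterable[int]) -> Fingerprint:
    """Normalise an iterable of feature ids into a Fingerprint.

    Raises ``ValueError`` on negative or non-integer ids.
    """
    fp = frozenset(int(f) for f in features)
    if any(f < 0 for f in fp):
        raise ValueError("fingerprint feature ids must be non-negative")
    return fp


@dataclass
class CompoundRecord:
    """A small molecule in the compound library."""

    id: str
    name: str = ""
    fingerprint: Optional[Fingerprint] = None
    heavy_atom_count: Optional[int] = None
    status: CompoundStatus = "other"

    def __post_init__(self) -> None:
        if self.heavy_atom_count is not None and self.heavy_atom_count < 0:
            raise ValueError(f"compound {self.id}: negative heavy_atom_count")
        if self.status not in ("approved", "other"):
            raise ValueError(f"compound {self.id}: invalid status {self.status!r}")


@dataclass
class ProteinRecord:
    """A protein in the proteome library (UniProt-style accession)."""

    id: str
    name: Optional[str] = None


@dataclass
class BindingSitePrediction:
    """One predicted binding site on a protein.

    ``confidence`` is the binding-site prediction confidence in [0, 1] and
    ``template_ligand`` is the fingerprint of the ligand bound in the template
    structure the site was inferred from.
    """

    protein_id: str
    site_id: str
    confidence: float
    template_ligand: Fingerprint

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(
                f"site {self.protein_id}/{self.site_id}: confidence "
                f"{self.confidence} outside [0, 1]"
            )


class InteractionMatrix:
    """Compounds × proteins matrix of interaction scores in [0, 1].

    Row/column order is authoritative and preserved through IO round-trips.
    """

    def __init__(
        self,
        compound_ids: Sequence[str],
        protein_ids: Sequence[str],
        values,
    ) -> None:
        self.compound_ids = list(compound_ids)
        self.protein_ids = list(protein_ids)
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self.compound_ids), len(self.protein_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match id lists "
                f"({len(self.compound_ids)} compounds × {len(self.protein_ids)} proteins)"
            )
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("duplicate compound ids in matrix")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("duplicate protein ids in matrix")
        bad = ~np.isfinite(values) | (values < 0.0) | (values > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"interaction score out of [0, 1] at compound "
                f"{self.compound_ids[i]!r}, protein {self.protein_ids[j]!r}: "
                f"{values[i, j]}"
            )
        self.values = values
        self._row_index = {c: i for i, c in enumerate(self.compound_ids)}

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def row(self, compound_id: str) -> np.ndarray:
        try:
            return self.values[self._row_index[compound_id]]
        except KeyError:
            raise KeyError(f"unknown compound id {compound_id!r}") from None

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionMatrix):
            return NotImplemented
        return (
            self.compound_ids == other.compound_ids
            and self.protein_ids == other.protein_ids
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        m, p = self.values.shape
        return f"InteractionMatrix({m} compounds × {p} proteins)"


@dataclass
class IndicationMapping:
    """Indication id → set of approved compound ids."""

    associations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.associations = {
            ind: frozenset(comps) for ind, comps in self.associations.items()
        }

    @property
    def n_indications(self) -> int:
        return len(self.associations)

    @property
    def n_associations(self) -> int:
        return sum(len(c) for c in self.associations.values())

    def __getitem__(self, indication_id: str) -> frozenset:
        return self.associations[indication_id]

    def __iter__(self):
        return iter(self.associations)

    def items(self):
        return self.associations.items()

    def __eq__(self, other) -> bool:
        if not isinstance(other, IndicationMapping):
            return NotImplemented
        return self.associations == other.associations


@dataclass(frozen=True)
class GoldStandardSet:
    """A named reference set of protein ids used in overlap analyses."""

    name: str
    proteins: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "proteins", frozenset(self.proteins))


@dataclass
class ConsensusEntry:
    """One candidate in a consensus list.

    ``consensus_score`` is the number of voting (approved-drug) similarity
    lists whose head contains this compound; ``average_score`` is its mean
    rank over those lists; ``probability`` is the binomial tail probability of
    observing at least that many votes under random ranking (filled by the
    prediction layer).
    """

    compound_id: str
    consensus_score: int
    average_score: float
    probability: Optional[float] = None
    approved: bool = False


@dataclass
class ConsensusList:
    """Candidates ordered by (desc consensus, asc average score, asc id)."""

    entries: list = field(default_factory=list)

    def top(self, n: int) -> list:
        return self.entries[:n]

    def compound_ids(self) -> list:
        return [e.compound_id for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)
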