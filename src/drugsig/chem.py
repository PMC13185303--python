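"""Fingerprint similarity coefficients and structure-derived compound filters.

Fingerprints are sparse sets of integer feature ids (ECFP4 convention:
circular substructures of radius 2 hashed to integers). The two coefficients
used throughout the pipeline are set-overlap measures:

    Dice(A, B)     = 2|A ∩ B| / (|A| + |B|)
    Tanimoto(A, B) = |A ∩ B| / |A ∪ B|

which are related by D = 2T / (1 + T). Two empty fingerprints score 0, not 1:
a featureless parse should never look like a perfect match.

ECFP4 hashing itself is delegated to RDKit; this module only defines the
fingerprint contract, the coefficients, and filters.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

from .types import CompoundRecord, Fingerprint, as_fingerprint

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: ECFP radius (radius 2 == diameter 4).
ECFP_RADIUS = 2


def dice_coefficient(a: Fingerprint, b: Fingerprint) -> float:
    """Sorenson-Dice coefficient 2|a∩b| / (|a|+|b|); 0 when both sets empty."""
    denom = len(a) + len(b)
    if denom == 0:
        return 0.0
    return 2.0 * len(a & b) / denom


def tanimoto_coefficient(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) coefficient |a∩b| / |a∪b|; 0 when both sets empty."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def heavy_atom_filter(
    compounds: Sequence[CompoundRecord], min_heavy: int
) -> List[CompoundRecord]:
    """Keep compounds with at least ``min_heavy`` heavy (non-hydrogen) atoms.

    Input order is preserved. A compound without a heavy-atom count cannot be
    filtered and raises rather than being silently imputed.
    """
    for c in compounds:
        if c.heavy_atom_count is None:
            raise ValueError(
                f"compound {c.id!r} has no heavy_atom_count; cannot apply heavy-atom filter"
            )
    return [c for c in compounds if c.heavy_atom_count >= min_heavy]


# ---------------------------------------------------------------------------
# Fingerprint computation via RDKit (ECFP4 = Morgan radius 2)
# ---------------------------------------------------------------------------

def fingerprint_from_mol(mol, radius: int = ECFP_RADIUS) -> Fingerprint:
    """Unfolded sparse ECFP fingerprint of an RDKit molecule."""
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    sfp = gen.GetSparseCountFingerprint(mol)
    return as_fingerprint(sfp.GetNonzeroElements().keys())


def compound_from_smiles(
    smiles: str, compound_id: str, name: str = "", status: str = "other"
) -> Optional[CompoundRecord]:
    """Parse a SMILES string into a CompoundRecord with fingerprint and
    heavy-atom count. Returns None (with a warning) on parse failure."""
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        warnings.warn(f"could not parse SMILES for compound {compound_id!r}; skipping")
        return None
    return CompoundRecord(
        id=compound_id,
        name=name or compound_id,
        fingerprint=fingerprint_from_mol(mol),
        heavy_atom_count=mol.GetNumHeavyAtoms(),
        status=status,  # type: ignore[arg-type]
    )


def load_compounds_from_smiles(path: PathLike) -> List[CompoundRecord]:
    """Load 'SMILES<TAB>id' lines; unparseable structures are skipped with a warning."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 'SMILES<TAB>id'")
            rec = compound_from_smiles(parts[0], parts[1])
            if rec is not None:
                records.append(rec)
    return records


def load_compounds_from_sdf(path: PathLike) -> List[CompoundRecord]:
    """Load an SDF file; molecule titles are used as compound ids."""
    from rdkit import Chem

    records = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            warnings.warn(f"{path}: could not parse SDF record {i}; skipping")
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"SDF{i}"
        records.append(
            CompoundRecord(
                id=cid,
                name=cid,
                fingerprint=fingerprint_from_mol(mol),
                heavy_atom_count=mol.GetNumHeavyAtoms(),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Fingerprint files: "id<TAB>comma-separated feature ids"
# ---------------------------------------------------------------------------

def load_fingerprints(path: PathLike) -> dict:
    fps: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 'id<TAB>features'"
                )
            cid, feats = parts
            if cid in fps:
                raise ValueError(f"{path}: duplicate compound id {cid!r}")
            fps[cid] = as_fingerprint(
                int(f) for f in feats.split(",") if f.strip() != ""
            )
    return fps


def save_fingerprints(fps: dict, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cid in sorted(fps):
            fh.write(f"{cid}\t{','.join(str(f) for f in sorted(fps[cid]))}\n")


def bitvector_to_fingerprint(bits: Iterable[int]) -> Fingerprint:
    """Convert a folded 0/1 bit vector to the set of set-bit indices."""
    return as_fingerprint(i for i, b in enumerate(bits) if b)
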