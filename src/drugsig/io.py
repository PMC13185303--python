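"""Readers and writers for every file format the pipeline touches.

All tabular formats are tab-separated UTF-8 with '.' as the decimal separator
and no quoting, so files interchange bit-exactly with command-line tooling.
Loading is strict: malformed cells, duplicate ids and out-of-range scores
raise :class:`DataFormatError` naming the offending location instead of being
silently coerced.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, List, Union

import numpy as np
import pandas as pd

from .types import (
    BindingSitePrediction,
    CompoundRecord,
    GoldStandardSet,
    IndicationMapping,
    InteractionMatrix,
    as_fingerprint,
)

PathLike = Union[str, Path]


class DataFormatError(ValueError):
    """A file failed validation; the message names the offending cell."""


# ---------------------------------------------------------------------------
# Interaction matrices
# ---------------------------------------------------------------------------

def load_interaction_matrix(path: PathLike) -> InteractionMatrix:
    """Load a compounds × proteins score matrix from TSV.

    Layout: header row = protein ids (first cell is an ignored corner label),
    first column = compound ids, remaining cells decimals in [0, 1].
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    compound_ids = [str(c) for c in df.index]
    protein_ids = [str(p) for p in df.columns]
    if len(set(compound_ids)) != len(compound_ids):
        raise DataFormatError(f"{path}: duplicate compound id in first column")
    if len(set(protein_ids)) != len(protein_ids):
        raise DataFormatError(f"{path}: duplicate protein id in header")
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            try:
                v = float(cell)
            except (TypeError, ValueError):
                raise DataFormatError(
                    f"{path}: malformed value {cell!r} at compound "
                    f"{compound_ids[i]!r}, protein {protein_ids[j]!r}"
                ) from None
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise DataFormatError(
                    f"{path}: score {v} outside [0, 1] at compound "
                    f"{compound_ids[i]!r}, protein {protein_ids[j]!r}"
                )
            values[i, j] = v
    return InteractionMatrix(compound_ids, protein_ids, values)


def save_interaction_matrix(matrix: InteractionMatrix, path: PathLike) -> None:
    df = pd.DataFrame(
        matrix.values, index=matrix.compound_ids, columns=matrix.protein_ids
    )
    df.index.name = "compound_id"
    # repr() keeps full float precision so load(save(x)) == x bit-exactly
    df.to_csv(path, sep="\t", float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# Indication mappings
# ---------------------------------------------------------------------------

def load_indication_mapping(path: PathLike) -> IndicationMapping:
    """Load a two-column TSV (indication_id, compound_id), no header.

    Duplicate associations collapse under set semantics.
    """
    associations: dict = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise DataFormatError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, got {len(row)}"
                )
            ind, comp = row[0].strip(), row[1].strip()
            associations.setdefault(ind, set()).add(comp)
    return IndicationMapping(associations)


def save_indication_mapping(mapping: IndicationMapping, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ind in sorted(mapping.associations):
            for comp in sorted(mapping.associations[ind]):
                fh.write(f"{ind}\t{comp}\n")


def restrict_to_benchmarkable(
    mapping: IndicationMapping, min_drugs: int = 2
) -> IndicationMapping:
    """Keep only indications with at least ``min_drugs`` approved drugs.

    Leave-one-out benchmarking needs at least two approved drugs per
    indication (each query must have another approved drug to recover).
    """
    return IndicationMapping(
        {
            ind: comps
            for ind, comps in mapping.associations.items()
            if len(comps) >= min_drugs
        }
    )


# ---------------------------------------------------------------------------
# Gold-standard protein sets
# ---------------------------------------------------------------------------

def load_gold_standard(path: PathLike) -> GoldStandardSet:
    """Load a gold standard: first line ``# <name>``, then one protein id per line."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or not lines[0].startswith("#"):
        raise DataFormatError(f"{path}: missing '# <name>' header line")
    name = lines[0].lstrip("#").strip()
    proteins = frozenset(ln.strip() for ln in lines[1:] if ln.strip())
    return GoldStandardSet(name=name, proteins=proteins)


def save_gold_standard(gold: GoldStandardSet, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {gold.name}\n")
        for pid in sorted(gold.proteins):
            fh.write(f"{pid}\n")


# ---------------------------------------------------------------------------
# Compound tables and site libraries
# ---------------------------------------------------------------------------

_COMPOUND_COLUMNS = ["id", "name", "status", "heavy_atom_count"]


def save_compound_table(compounds: Iterable[CompoundRecord], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_COMPOUND_COLUMNS) + "\n")
        for c in compounds:
            hac = "" if c.heavy_atom_count is None else str(c.heavy_atom_count)
            fh.write(f"{c.id}\t{c.name}\t{c.status}\t{hac}\n")


def load_compound_table(path: PathLike) -> List[CompoundRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _COMPOUND_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing columns {missing}")
    records = []
    seen = set()
    for _, row in df.iterrows():
        cid = row["id"]
        if cid in seen:
            raise DataFormatError(f"{path}: duplicate compound id {cid!r}")
        seen.add(cid)
        hac = int(row["heavy_atom_count"]) if row["heavy_atom_count"] != "" else None
        records.append(
            CompoundRecord(
                id=cid,
                name=row["name"],
                status=row["status"],  # type: ignore[arg-type]
                heavy_atom_count=hac,
            )
        )
    return records


def load_site_library(path: PathLike) -> dict:
    """Load a binding-site prediction table.

    TSV columns: protein_id, site_id, confidence, template feature ids
    (comma-separated; empty = featureless template). Returns a dict
    protein_id → list of :class:`BindingSitePrediction`.
    """
    sites: dict = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["protein_id", "site_id", "confidence", "template_features"]
        if header != expected:
            raise DataFormatError(f"{path}: expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise DataFormatError(f"{path}: line {lineno}: expected 4 columns")
            pid, sid, conf_s, feats = parts
            try:
                conf = float(conf_s)
            except ValueError:
                raise DataFormatError(
                    f"{path}: line {lineno}: malformed confidence {conf_s!r}"
                ) from None
            if not 0.0 <= conf <= 1.0:
                raise DataFormatError(
                    f"{path}: line {lineno}: confidence {conf} outside [0, 1]"
                )
            fp = as_fingerprint(
                int(f) for f in feats.split(",") if f.strip() != ""
            )
            sites.setdefault(pid, []).append(
                BindingSitePrediction(pid, sid, conf, fp)
            )
    return sites


def save_site_library(sites: dict, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\tsite_id\tconfidence\ttemplate_features\n")
        for pid in sorted(sites):
            for s in sites[pid]:
                feats = ",".join(str(f) for f in sorted(s.template_ligand))
                fh.write(f"{pid}\t{s.site_id}\t{repr(float(s.confidence))}\t{feats}\n")
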