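"""Synthetic studies with planted structure.

The generator emulates the statistical shape the analysis assumes, at desk
scale: an interaction matrix in [0, 1] where drugs approved for the same
indication share elevated scores on dedicated "driver" proteins on top of a
right-skewed background (interaction scores behave like products of a
similarity and a confidence, hence the Beta-shaped background); fingerprints
as random sparse feature sets with planted near-duplicate "me too" analog
pairs at a target Tanimoto; a multi-indication drug mapping; and per-indication
gold-standard protein sets equal to the planted driver sets.

Planted driver scores are an additive elevation: entry = clip(background +
signal + Normal(0, noise_sd), 0, 1). With signal = 0 and noise_sd = 0 the
study is an exact null (no indication structure); with background 0, noise 0
and signal > 0, co-indicated drugs have identical signatures (the
perfect-duplicate limit).

Everything is deterministic given the master seed, which is split into named
substreams so each component is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Dict, List, Tuple, Union

import numpy as np

from . import io as dio
from .chem import save_fingerprints, tanimoto_coefficient
from .ranking import Neighbor, PipelineLists, SimilarityList
from .types import (
    BindingSitePrediction,
    CompoundRecord,
    GoldStandardSet,
    IndicationMapping,
    InteractionMatrix,
    ProteinRecord,
    as_fingerprint,
)

PathLike = Union[str, Path]

_SUBSTREAMS = ("background", "signal", "fingerprints", "analogs", "sites", "atoms")


@dataclass
class SyntheticConfig:
    """Study-generation parameters.

    ``signal`` is the additive elevation of an approved drug's scores on its
    indication's driver proteins; ``background_density`` is the fraction of
    non-zero background entries; ``analog_overlap`` is the target Tanimoto of
    planted analog pairs.
    """

    seed: int = 0
    n_compounds: int = 500
    n_proteins: int = 300
    n_indications: int = 50
    drugs_per_indication: int = 4
    drivers_per_indication: int = 5
    signal: float = 0.75
    noise_sd: float = 0.05
    background_density: float = 0.2
    background_dist: str = "beta"  # "beta" (Beta(2,5)) or "uniform"
    n_analog_pairs: int = 10
    analog_overlap: float = 0.9
    fingerprint_features_per_compound: int = 48
    feature_universe: int = 2**20

    def __post_init__(self) -> None:
        if self.n_indications * self.drugs_per_indication > self.n_compounds:
            raise ValueError(
                "infeasible config: n_indications × drugs_per_indication exceeds n_compounds"
            )
        if self.n_indications * self.drivers_per_indication > self.n_proteins:
            raise ValueError(
                "infeasible config: n_indications × drivers_per_indication exceeds n_proteins"
            )
        if self.signal < 0 or self.noise_sd < 0:
            raise ValueError("signal and noise_sd must be non-negative")
        if not 0.0 <= self.background_density <= 1.0:
            raise ValueError("background_density must be in [0, 1]")
        if not 0.0 < self.analog_overlap <= 1.0:
            raise ValueError("analog_overlap must be in (0, 1]")
        if self.background_dist not in ("beta", "uniform"):
            raise ValueError(f"unknown background_dist {self.background_dist!r}")
        if self.n_analog_pairs > 0 and 2 * self.n_analog_pairs > self.n_indications:
            raise ValueError(
                "need n_indications >= 2 × n_analog_pairs to plant analog pairs "
                "across distinct indications"
            )


@dataclass
class StudyBundle:
    """Everything one synthetic study produces."""

    config: SyntheticConfig
    compounds: List[CompoundRecord]
    proteins: List[ProteinRecord]
    site_library: Dict[str, List[BindingSitePrediction]]
    matrix: InteractionMatrix
    mapping: IndicationMapping
    gold_standards: Dict[str, GoldStandardSet]
    analog_pairs: List[Tuple[str, str]] = field(default_factory=list)

    @property
    def fingerprints(self) -> Dict[str, frozenset]:
        return {c.id: c.fingerprint for c in self.compounds}


def _substreams(seed: int) -> Dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_SUBSTREAMS, children)}


def _random_fingerprint(rng: np.random.Generator, size: int, universe: int) -> frozenset:
    feats: set = set()
    while len(feats) < size:
        feats.update(int(f) for f in rng.integers(0, universe, size=size - len(feats)))
    return as_fingerprint(feats)


def generate_study(config: SyntheticConfig) -> StudyBundle:
    """Generate one complete synthetic study, deterministic given the seed."""
    rngs = _substreams(config.seed)
    M, P = config.n_compounds, config.n_proteins
    I, K, G = (
        config.n_indications,
        config.drugs_per_indication,
        config.drivers_per_indication,
    )
    compound_ids = [f"C{i:05d}" for i in range(M)]
    protein_ids = [f"P{i:05d}" for i in range(P)]
    indication_ids = [f"D{i:04d}" for i in range(I)]

    # --- interaction matrix: skewed background + planted driver blocks ---
    rng = rngs["background"]
    if config.background_dist == "beta":
        bg = rng.beta(2.0, 5.0, size=(M, P))
    else:
        bg = rng.random(size=(M, P))
    mask = rng.random(size=(M, P)) < config.background_density
    values = bg * mask
    rng = rngs["signal"]
    for i in range(I):
        rows = slice(i * K, (i + 1) * K)
        cols = slice(i * G, (i + 1) * G)
        noise = rng.normal(0.0, config.noise_sd, size=(K, G)) if config.noise_sd else 0.0
        values[rows, cols] = values[rows, cols] + config.signal + noise
    values = np.clip(values, 0.0, 1.0)
    matrix = InteractionMatrix(compound_ids, protein_ids, values)

    # --- mapping and gold standards ---
    mapping = IndicationMapping(
        {
            ind: frozenset(compound_ids[i * K : (i + 1) * K])
            for i, ind in enumerate(indication_ids)
        }
    )
    gold = {
        ind: GoldStandardSet(ind, frozenset(protein_ids[i * G : (i + 1) * G]))
        for i, ind in enumerate(indication_ids)
    }

    # --- fingerprints with planted analog pairs ---
    rng = rngs["fingerprints"]
    F = config.fingerprint_features_per_compound
    fps = {
        cid: _random_fingerprint(rng, F, config.feature_universe)
        for cid in compound_ids
    }
    rng = rngs["analogs"]
    analog_pairs: List[Tuple[str, str]] = []
    # analog pairs link the first approved drug of consecutive indications, so
    # each "me too" twin belongs to a *different* indication than its partner
    t = config.analog_overlap
    shared = ceil(2 * F * t / (1 + t))
    for pair_idx in range(config.n_analog_pairs):
        a = compound_ids[(2 * pair_idx) * K]
        b = compound_ids[(2 * pair_idx + 1) * K]
        a_feats = sorted(fps[a])
        keep = [a_feats[i] for i in rng.choice(F, size=shared, replace=False)]
        fresh: set = set()
        while len(fresh) < F - shared:
            cand = int(rng.integers(0, config.feature_universe))
            if cand not in fps[a] and cand not in fresh:
                fresh.add(cand)
        fps[b] = as_fingerprint(set(keep) | fresh)
        assert tanimoto_coefficient(fps[a], fps[b]) >= t
        analog_pairs.append((a, b))

    # --- compound and protein records ---
    rng = rngs["atoms"]
    heavy = rng.integers(1, 41, size=M)
    approved = {cid for comps in mapping.associations.values() for cid in comps}
    compounds = [
        CompoundRecord(
            id=cid,
            name=cid,
            fingerprint=fps[cid],
            heavy_atom_count=int(heavy[i]),
            status="approved" if cid in approved else "other",
        )
        for i, cid in enumerate(compound_ids)
    ]
    proteins = [ProteinRecord(id=pid) for pid in protein_ids]

    # --- binding-site library (exercises the scoring stage; the planted matrix
    # above is generated directly and is not derived from these sites) ---
    rng = rngs["sites"]
    site_library: Dict[str, List[BindingSitePrediction]] = {}
    for pid in protein_ids:
        n_sites = int(rng.integers(0, 4))
        sites = []
        for s in range(n_sites):
            template = fps[compound_ids[int(rng.integers(0, M))]]
            sites.append(
                BindingSitePrediction(
                    protein_id=pid,
                    site_id=f"{pid}_S{s}",
                    confidence=float(rng.beta(5.0, 2.0)),
                    template_ligand=template,
                )
            )
        if sites:
            site_library[pid] = sites

    return StudyBundle(
        config=config,
        compounds=compounds,
        proteins=proteins,
        site_library=site_library,
        matrix=matrix,
        mapping=mapping,
        gold_standards=gold,
        analog_pairs=analog_pairs,
    )


def generate_null_lists(M: int, seed: int, name: str = "null") -> PipelineLists:
    """Similarity lists under random ranking: each compound's neighbor order is
    an independent uniform permutation with strictly increasing distances."""
    if M < 2:
        raise ValueError("need at least 2 compounds")
    rng = np.random.default_rng(seed)
    ids = [f"C{i:05d}" for i in range(M)]
    lists = {}
    for i, qid in enumerate(ids):
        others = [ids[j] for j in range(M) if j != i]
        perm = rng.permutation(len(others))
        lists[qid] = SimilarityList(
            qid,
            [
                Neighbor(others[int(j)], rank / M, rank)
                for rank, j in enumerate(perm, start=1)
            ],
        )
    return PipelineLists(name=name, lists=lists)


def write_study(bundle: StudyBundle, outdir: PathLike) -> Dict[str, str]:
    """Write every artifact of a study in the pipeline's file formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "compounds": outdir / "compounds.tsv",
        "fingerprints": outdir / "fingerprints.tsv",
        "sites": outdir / "sites.tsv",
        "matrix": outdir / "matrix.tsv",
        "mapping": outdir / "mapping.tsv",
    }
    dio.save_compound_table(bundle.compounds, paths["compounds"])
    save_fingerprints(bundle.fingerprints, paths["fingerprints"])
    dio.save_site_library(bundle.site_library, paths["sites"])
    dio.save_interaction_matrix(bundle.matrix, paths["matrix"])
    dio.save_indication_mapping(bundle.mapping, paths["mapping"])
    golddir = outdir / "gold_standards"
    golddir.mkdir(exist_ok=True)
    for ind, gs in bundle.gold_standards.items():
        p = golddir / f"{ind}.txt"
        dio.save_gold_standard(gs, p)
        paths[f"gold:{ind}"] = p
    return {k: str(v) for k, v in paths.items()}
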