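"""End-to-end orchestration of the four-pipeline comparison.

A run builds the proteomic, fingerprint (Tanimoto), filtered-Tanimoto and
fusion similarity-list pipelines from one study (synthetic or loaded),
benchmarks each against the indication mapping, writes per-indication
prediction tables, and runs the gold-standard overlap comparison of top /
random / bottom candidate groups. Every run writes a manifest recording the
package version, seeds and parameters, from which it is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

from . import __version__
from .benchmark import DEFAULT_CUTOFFS, MetricSet, run_benchmark
from .chem import heavy_atom_filter
from .io import restrict_to_benchmarkable
from .prediction import export_prediction_table, predict_candidates
from .ranking import (
    PipelineLists,
    apply_uniqueness_filter,
    build_proteomic_lists,
    build_tanimoto_lists,
    fuse_ranks,
    fuse_score_product,
)
from .synthetic import StudyBundle, SyntheticConfig, generate_study, write_study
from .targets import compare_candidate_groups, random_candidate_group

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

KNOWN_PIPELINES = (
    "proteomic",
    "tanimoto",
    "tanimoto_filtered",
    "fusion_score_product",
    "fusion_rank_min",
    "fusion_rank_max",
    "fusion_rank_mean",
    "fusion_rank_sum",
    "fusion_rank_product",
    "fusion_distance_product",
)


@dataclass
class RunConfig:
    """Configuration of one full study run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    pipelines: List[str] = field(
        default_factory=lambda: [
            "proteomic",
            "tanimoto",
            "tanimoto_filtered",
            "fusion_score_product",
        ]
    )
    cutoffs: List[int] = field(default_factory=lambda: list(DEFAULT_CUTOFFS))
    voting_cutoff: Optional[int] = None
    filter_fraction: float = 0.02
    prediction_cutoff: int = 100
    prediction_top_k: int = 100
    overlap_group_size: int = 24
    overlap_rank_cutoff: int = 10
    min_heavy_atoms: int = 5
    control: str = "closed_form"
    seed: int = 0
    out_dir: str = "drugsig_run"

    def __post_init__(self) -> None:
        if not self.pipelines:
            raise ValueError("at least one pipeline required")
        unknown = set(self.pipelines) - set(KNOWN_PIPELINES)
        if unknown:
            raise ValueError(f"unknown pipelines: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        return cls(**d)


def build_pipelines(
    bundle: StudyBundle, names: List[str], filter_fraction: float = 0.02
) -> Dict[str, PipelineLists]:
    """Construct the requested similarity-list pipelines from one study."""
    out: Dict[str, PipelineLists] = {}
    need_proteomic = {"proteomic", "fusion_score_product"} | {
        n for n in names if n.startswith("fusion_")
    }
    need_tanimoto = {"tanimoto", "tanimoto_filtered"} | {
        n for n in names if n.startswith("fusion_")
    }
    proteomic = (
        build_proteomic_lists(bundle.matrix)
        if set(names) & need_proteomic
        else None
    )
    tanimoto = (
        build_tanimoto_lists(bundle.compounds) if set(names) & need_tanimoto else None
    )
    for name in names:
        logger.info("building pipeline %s", name)
        if name == "proteomic":
            out[name] = proteomic
        elif name == "tanimoto":
            out[name] = tanimoto
        elif name == "tanimoto_filtered":
            out[name] = apply_uniqueness_filter(
                tanimoto, top_fraction=filter_fraction, name="tanimoto_filtered"
            )
        elif name == "fusion_score_product":
            out[name] = fuse_score_product(proteomic, tanimoto)
        elif name == "fusion_distance_product":
            out[name] = fuse_ranks(proteomic, tanimoto, operator="distance_product",
                                   name=name)
        elif name.startswith("fusion_rank_"):
            out[name] = fuse_ranks(
                proteomic, tanimoto, operator=name.removeprefix("fusion_rank_")
            )
    return out


def _sha256_of_matrix(bundle: StudyBundle) -> str:
    h = hashlib.sha256()
    h.update("\n".join(bundle.matrix.compound_ids).encode())
    h.update("\n".join(bundle.matrix.protein_ids).encode())
    h.update(bundle.matrix.values.tobytes())
    return h.hexdigest()


def run_full_study(config: RunConfig, bundle: Optional[StudyBundle] = None) -> dict:
    """Run the full comparison and write a report bundle to ``config.out_dir``.

    Returns a dict with the manifest, per-pipeline MetricSets, prediction
    tables and overlap reports (also serialized to disk).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle is None:
        logger.info("generating synthetic study (seed=%d)", config.synthetic.seed)
        bundle = generate_study(config.synthetic)
        write_study(bundle, out / "study")
    logger.info("matrix sha256=%s", _sha256_of_matrix(bundle))

    mapping = restrict_to_benchmarkable(bundle.mapping)
    pipelines = build_pipelines(bundle, config.pipelines, config.filter_fraction)

    metric_sets: Dict[str, MetricSet] = {}
    for name, lists in pipelines.items():
        logger.info("benchmarking pipeline %s", name)
        ms = run_benchmark(
            lists,
            mapping,
            cutoffs=config.cutoffs,
            voting_cutoff=config.voting_cutoff,
            control=config.control,
            seed=config.seed,
        )
        metric_sets[name] = ms
        ms.to_json(out / f"benchmark_{name}.json")
        ms.to_tsv(out / f"benchmark_{name}.tsv")

    # predictions per indication, primary pipeline = first configured
    primary = pipelines[config.pipelines[0]]
    preddir = out / "predictions"
    preddir.mkdir(exist_ok=True)
    predictions = {}
    for ind, approved in mapping.items():
        cl = predict_candidates(
            primary,
            set(approved),
            per_list_cutoff=config.prediction_cutoff,
            top_k=config.prediction_top_k,
        )
        predictions[ind] = cl
        export_prediction_table(cl, preddir / f"{ind}.tsv")

    # overlap analysis: top vs random vs bottom candidate groups per indication
    overlap_reports = {}
    n = config.overlap_group_size
    by_id = {c.id: c for c in bundle.compounds}
    for ind, cl in predictions.items():
        ids = cl.compound_ids()
        if len(ids) < n:
            continue
        top_group = ids[:n]
        bottom_pool = heavy_atom_filter(
            [by_id[cid] for cid in ids], config.min_heavy_atoms
        )
        bottom_group = [c.id for c in bottom_pool][-n:]
        rand_group = random_candidate_group(
            bundle.matrix.compound_ids, n, seed=config.seed, exclude=set(top_group)
        )
        report = compare_candidate_groups(
            bundle.matrix,
            {"top": top_group, "random": rand_group, "bottom": bottom_group},
            [bundle.gold_standards[ind]],
            rank_cutoff=config.overlap_rank_cutoff,
        )
        overlap_reports[ind] = report
    with open(out / "overlap.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                ind: {
                    g: {
                        gold: dataclasses.asdict(rep)
                        for gold, rep in golds.items()
                    }
                    for g, golds in groups.items()
                }
                for ind, groups in overlap_reports.items()
            },
            fh,
            indent=2,
            sort_keys=True,
        )

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "matrix_sha256": _sha256_of_matrix(bundle),
        "n_compounds": len(bundle.matrix.compound_ids),
        "n_proteins": len(bundle.matrix.protein_ids),
        "n_benchmarkable_indications": mapping.n_indications,
        "pipelines": list(pipelines),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "manifest": manifest,
        "metrics": metric_sets,
        "predictions": predictions,
        "overlap": overlap_reports,
    }
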