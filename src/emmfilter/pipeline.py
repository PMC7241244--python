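"""End-to-end workflow: mine → build EMM → mass-filter → assemble → summarize.

Each stage writes its artifact to the output directory so any stage can be
re-run or audited in isolation; ``run_pipeline`` composes them in memory
and returns the summary statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

from . import candidate_assembly as ca
from . import io as eio
from .emm_builder import build_emm
from .mass_filter import MassIndex, filter_features
from .operator_miner import build_operator_library

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths and knobs for one workflow run."""

    model_path: str
    features_path: str
    out_dir: str
    reactions_path: Optional[str] = None
    xref_paths: Dict[str, str] = field(default_factory=dict)  # {"kegg": path, ...}
    tolerance_ppm: float = 10.0
    adduct: str = "none"
    min_heavy_atoms: int = 4
    depth: int = 1
    both_directions: bool = True
    model_only: bool = False  # skip the EMM stage (reference-model workflow)
    seed: int = 17

    def __post_init__(self):
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance must be > 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write all artifacts.

    Returns the summary statistics dict (also written as summary.json).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    model = eio.read_model(config.model_path, config.reactions_path)
    logger.info(
        "model: %d metabolites, %d reactions",
        len(model.metabolites), len(model.reactions),
    )
    features = eio.read_feature_table(config.features_path)
    logger.info("features: %d", len(features))

    model_index = MassIndex.from_model(model)
    model_matches = filter_features(
        features, model_index, config.tolerance_ppm, config.adduct
    )
    eio.write_matches(model_matches, out / "model_matches.tsv")

    emm_matches = []
    provenance = {}
    if not config.model_only:
        if not model.reactions:
            raise ValueError("EMM workflow requires a reaction table")
        library = build_operator_library(
            model.reactions,
            min_heavy_atoms=config.min_heavy_atoms,
            both_directions=config.both_directions,
        )
        logger.info("mined %d unique operators", len(library))
        eio.write_library(library, out / "library.json")
        emm = build_emm(model, library, depth=config.depth)
        logger.info("EMM: %d unique derivatives", len(emm.derivatives))
        eio.write_derivatives(emm, out / "derivatives.tsv")
        eio.write_json(emm.statistics(), out / "emm_stats.json")
        emm_index = MassIndex.from_extended_model(emm)
        emm_matches = filter_features(
            features, emm_index, config.tolerance_ppm, config.adduct
        )
        eio.write_matches(emm_matches, out / "emm_matches.tsv")
        provenance = {
            d.key: (d.n_reactions, d.n_ecs) for d in emm.derivatives.values()
        }

    candidates = ca.assemble(model_matches, emm_matches, provenance)
    tables = {
        name: eio.read_xref_table(path) for name, path in config.xref_paths.items()
    }
    for record in candidates:
        ca.xref_lookup(record, tables)
    if candidates:
        ca.export_candidates(candidates, out)
    summary = ca.summarize(len(features), model_matches, emm_matches, candidates)
    summary["config"] = {
        "tolerance_ppm": config.tolerance_ppm,
        "adduct": config.adduct,
        "depth": config.depth,
        "model_only": config.model_only,
        "schema_version": 1,
    }
    eio.write_json(summary, out / "summary.json")
    logger.info(
        "matched %d/%d features via the model, %d via the EMM",
        summary["model"]["matched_masses"],
        len(features),
        summary["emm"]["matched_masses"],
    )
    return summary
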