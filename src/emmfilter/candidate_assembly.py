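"""Assemble the biologically relevant candidate set.

The candidate set for annotation is the union, per feature, of model
metabolites and EMM derivatives whose masses matched the feature. Local
cross-reference tables (canonical structure key → KEGG / PubChem id) tag
candidates with known identities; candidates absent from every table are
flagged novel. Summary statistics mirror the matched-count, percentage and
lower-bound-discovery arithmetic used to compare workflows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

from .mass_filter import MatchResult

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateRecord",
    "assemble",
    "xref_lookup",
    "xref_buckets",
    "summarize",
    "percent",
    "fold_ratio",
    "export_candidates",
]


@dataclass
class CandidateRecord:
    """One candidate identity for one feature."""

    feature_id: str
    key: str  # canonical structure key
    mass: float
    ppm_error: float
    source: str  # "model" | "derivative"
    identity: Optional[str] = None  # metabolite id (model candidates)
    kegg_id: Optional[str] = None
    pubchem_id: Optional[str] = None
    novel: bool = False
    n_reactions: Optional[int] = None  # derivative provenance
    n_ecs: Optional[int] = None


def assemble(
    model_matches: Sequence[MatchResult],
    emm_matches: Sequence[MatchResult],
    derivative_provenance: Optional[Mapping[str, tuple]] = None,
) -> List[CandidateRecord]:
    """Union of model and derivative matches keyed on (feature, structure).

    A structure matched both as a model metabolite and as a derivative is
    reported once with source="model". ``derivative_provenance`` maps a
    derivative key to (n_reactions, n_ecs).
    """
    provenance = derivative_provenance or {}
    records: Dict[tuple, CandidateRecord] = {}
    for result_set in (model_matches, emm_matches):
        for result in result_set:
            for match in result.matches:
                entry = match.entry
                slot = (result.feature.feature_id, entry.key)
                prior = records.get(slot)
                if prior is not None and (
                    prior.source == "model" or entry.source == prior.source
                ):
                    continue
                if prior is not None and entry.source == "derivative":
                    continue  # keep the model-sourced record
                rec = CandidateRecord(
                    feature_id=result.feature.feature_id,
                    key=entry.key,
                    mass=entry.mass,
                    ppm_error=match.ppm_error,
                    source=entry.source,
                    identity=entry.record_id if entry.source == "model" else None,
                )
                if entry.source == "derivative" and entry.key in provenance:
                    rec.n_reactions, rec.n_ecs = provenance[entry.key]
                records[slot] = rec
    return sorted(records.values(), key=lambda r: (r.feature_id, r.key))


def xref_lookup(
    record: CandidateRecord, tables: Mapping[str, Mapping[str, str]]
) -> CandidateRecord:
    """Fill cross-references from local tables keyed by structure key.

    Tables are named maps, e.g. ``{"kegg": {...}, "pubchem": {...}}``.
    Records found in no table are flagged novel and retained.
    """
    record.kegg_id = tables.get("kegg", {}).get(record.key)
    record.pubchem_id = tables.get("pubchem", {}).get(record.key)
    record.novel = record.kegg_id is None and record.pubchem_id is None
    return record


def xref_buckets(candidates: Sequence[CandidateRecord]) -> Dict[str, List[CandidateRecord]]:
    """Partition candidates: in KEGG ⊔ in PubChem only ⊔ novel."""
    buckets: Dict[str, List[CandidateRecord]] = {
        "kegg": [],
        "pubchem_not_kegg": [],
        "novel": [],
    }
    for rec in candidates:
        if rec.kegg_id is not None:
            buckets["kegg"].append(rec)
        elif rec.pubchem_id is not None:
            buckets["pubchem_not_kegg"].append(rec)
        else:
            buckets["novel"].append(rec)
    return buckets


def percent(matched: int, measured: int) -> float:
    """Percentage of measured masses matched, two-decimal reporting."""
    if measured == 0:
        return 0.0
    return round(100.0 * matched / measured, 2)


def fold_ratio(numerator: int, denominator: int) -> Optional[float]:
    """Two-decimal ratio; undefined (None) on a zero denominator."""
    if denominator == 0:
        return None
    return round(numerator / denominator, 2)


def summarize(
    n_features: int,
    model_matches: Sequence[MatchResult],
    emm_matches: Sequence[MatchResult],
    candidates: Sequence[CandidateRecord],
) -> dict:
    """Comparison statistics for the model-only and EMM workflows.

    Chemical-identity counts are global distinct structure keys over all
    features; per-feature totals (counting a key once per feature it
    matches) are emitted alongside.
    """
    model_matched = len(model_matches)
    emm_matched = len({r.feature.feature_id for r in emm_matches} |
                      {r.feature.feature_id for r in model_matches})
    buckets = xref_buckets(candidates)
    kegg_mass = {r.feature_id for r in buckets["kegg"]}
    pnk_mass = {r.feature_id for r in buckets["pubchem_not_kegg"]}
    kegg_ids = {r.key for r in buckets["kegg"]}
    pnk_ids = {r.key for r in buckets["pubchem_not_kegg"]}
    return {
        "measured_masses": n_features,
        "model": {
            "matched_masses": model_matched,
            "percent_matched": percent(model_matched, n_features),
            "chemical_ids": len({m.entry.key for r in model_matches for m in r.matches}),
        },
        "emm": {
            "matched_masses": emm_matched,
            "percent_matched": percent(emm_matched, n_features),
            "chemical_ids": len({r.key for r in candidates}),
            "chemical_ids_per_feature_total": len(
                {(r.feature_id, r.key) for r in candidates}
            ),
        },
        "candidates": {
            "total": len(candidates),
            "novel": len(buckets["novel"]),
            "in_kegg": len(kegg_ids),
            "in_pubchem_not_kegg": len(pnk_ids),
        },
        "lower_bound_discovery": {
            "matched_masses_kegg": len(kegg_mass),
            "matched_masses_pubchem_not_kegg": len(pnk_mass),
            "chemical_ids_kegg": len(kegg_ids),
            "chemical_ids_pubchem_not_kegg": len(pnk_ids),
            "fold_masses": fold_ratio(len(pnk_mass), len(kegg_mass)),
            "fold_ids": fold_ratio(len(pnk_ids), len(kegg_ids)),
        },
    }


_EXPORT_FORMATS = ("tsv", "smiles")


def export_candidates(
    candidates: Sequence[CandidateRecord], out_dir, formats: Sequence[str] = _EXPORT_FORMATS
) -> List[Path]:
    """Write the candidate set for downstream annotation tools.

    ``tsv`` carries full provenance; ``smiles`` is a plain structure list
    (one canonical SMILES per line, deduplicated). Row order is (feature
    id, structure key), so re-export of the same set is byte-identical.
    """
    if not candidates:
        raise ValueError("candidate set is empty")
    unknown = set(formats) - set(_EXPORT_FORMATS)
    if unknown:
        raise ValueError(
            f"unknown export format(s) {sorted(unknown)}; supported: {_EXPORT_FORMATS}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ordered = sorted(candidates, key=lambda r: (r.feature_id, r.key))
    written = []
    if "tsv" in formats:
        path = out_dir / "candidates.tsv"
        cols = [
            "feature_id", "structure_key", "mass", "ppm_error", "source",
            "identity", "kegg_id", "pubchem_id", "novel", "n_reactions", "n_ecs",
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in ordered:
                fh.write(
                    "\t".join(
                        [
                            r.feature_id,
                            r.key,
                            f"{r.mass:.6f}",
                            f"{r.ppm_error:.4f}",
                            r.source,
                            r.identity or "",
                            r.kegg_id or "",
                            r.pubchem_id or "",
                            "1" if r.novel else "0",
                            "" if r.n_reactions is None else str(r.n_reactions),
                            "" if r.n_ecs is None else str(r.n_ecs),
                        ]
                    )
                    + "\n"
                )
        written.append(path)
    if "smiles" in formats:
        path = out_dir / "candidates.smi"
        seen = []
        for r in ordered:
            if r.key not in seen:
                seen.append(r.key)
        with open(path, "w") as fh:
            for key in seen:
                fh.write(key + "\n")
        written.append(path)
    return written
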