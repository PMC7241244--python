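"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats
-------
- metabolite TSV: ``metabolite_id  name  smiles``
- reaction TSV:   ``reaction_id  reaction_smiles  ec_numbers`` where
  ``reaction_smiles`` is ``reactant>>product`` (atom-mapped accepted;
  unmapped pairs get a maximum-common-substructure alignment) and
  ``ec_numbers`` is semicolon-separated
- feature CSV:    ``feature_id,mz,rt_min,polarity``
- xref TSV:       ``structure_key  external_id``
- operator library JSON, matches TSV, statistics JSON
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import pandas as pd
from rdkit import Chem

from .chem_core import StructureParseError, parse_structure
from .emm_builder import ExtendedModel, MetabolicModel, Metabolite
from .mass_filter import Feature, MatchResult
from .operator_miner import (
    MappedReactionPair,
    OperatorLibrary,
    infer_atom_map,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_metabolite_table",
    "write_metabolite_table",
    "read_reaction_table",
    "write_reaction_table",
    "read_model",
    "read_feature_table",
    "write_feature_table",
    "read_xref_table",
    "write_xref_table",
    "read_library",
    "write_library",
    "write_matches",
    "write_derivatives",
    "write_json",
    "parse_reaction_smiles",
    "mapped_reaction_smiles",
]


class FormatError(ValueError):
    """A table violates the documented column layout."""


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


# ---------------------------------------------------------------------------
# reaction line notation


def _relax_explicit_hs(mol):
    """Return hydrogen bookkeeping to the implicit-valence model.

    Atom-mapped SMILES put every atom in brackets, freezing its hydrogen
    count; downstream edits rely on hydrogens refilling from valence.
    Aromatic N/P (where the H placement is structural, e.g. pyrrole-type
    nitrogen) and charged atoms keep their explicit counts.
    """
    work = Chem.Mol(mol)
    for atom in work.GetAtoms():
        if atom.GetFormalCharge() != 0:
            continue
        if atom.GetIsAromatic() and atom.GetSymbol() in ("N", "P"):
            continue
        atom.SetNoImplicit(False)
        atom.SetNumExplicitHs(0)
    Chem.SanitizeMol(work)
    return work


def parse_reaction_smiles(text: str):
    """Split ``reactant>>product`` and build the atom correspondence.

    When both sides carry atom-map numbers, the map is read from them;
    otherwise it is inferred by maximum-common-substructure alignment.
    Returns (reactant, product, atom_map) with map numbers cleared.
    """
    parts = text.split(">")
    if len(parts) == 3:
        left, _, right = parts  # reactant>agents>product dialect
    elif len(parts) == 2:
        left, right = parts
    else:
        raise FormatError(f"bad reaction notation {text!r}; expected 'reactant>>product'")
    reactant = parse_structure(left)
    product = parse_structure(right)
    r_maps = {a.GetAtomMapNum(): a.GetIdx() for a in reactant.GetAtoms() if a.GetAtomMapNum()}
    p_maps = {a.GetAtomMapNum(): a.GetIdx() for a in product.GetAtoms() if a.GetAtomMapNum()}
    shared = set(r_maps) & set(p_maps)
    if shared:
        atom_map = {r_maps[n]: p_maps[n] for n in shared}
        for mol in (reactant, product):
            for atom in mol.GetAtoms():
                atom.SetAtomMapNum(0)
        reactant = _relax_explicit_hs(reactant)
        product = _relax_explicit_hs(product)
    else:
        atom_map = infer_atom_map(reactant, product)
    return reactant, product, atom_map


def mapped_reaction_smiles(pair: MappedReactionPair) -> str:
    """Serialize a pair as atom-mapped ``reactant>>product`` notation."""
    reactant = Chem.Mol(pair.reactant)
    product = Chem.Mol(pair.product)
    for n, (r_idx, p_idx) in enumerate(sorted(pair.atom_map.items()), start=1):
        reactant.GetAtomWithIdx(r_idx).SetAtomMapNum(n)
        product.GetAtomWithIdx(p_idx).SetAtomMapNum(n)
    return f"{Chem.MolToSmiles(reactant)}>>{Chem.MolToSmiles(product)}"


# ---------------------------------------------------------------------------
# tables


def read_metabolite_table(path) -> List[Metabolite]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["metabolite_id", "name", "smiles"], path)
    metabolites = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        try:
            metabolites.append(
                Metabolite.from_smiles(row.metabolite_id, row.name, row.smiles)
            )
        except StructureParseError as exc:
            raise FormatError(f"{path}:{line}: {exc}") from exc
    return metabolites


def write_metabolite_table(metabolites: Sequence[Metabolite], path) -> None:
    pd.DataFrame(
        {
            "metabolite_id": [m.metabolite_id for m in metabolites],
            "name": [m.name for m in metabolites],
            "smiles": [Chem.MolToSmiles(m.structure) for m in metabolites],
        }
    ).to_csv(path, sep="\t", index=False)


def read_reaction_table(path) -> List[MappedReactionPair]:
    """Read reactions, skipping unparsable rows with a logged count."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require_columns(df, ["reaction_id", "reaction_smiles", "ec_numbers"], path)
    pairs, skipped = [], 0
    for line, row in enumerate(df.itertuples(index=False), start=2):
        try:
            reactant, product, atom_map = parse_reaction_smiles(row.reaction_smiles)
            ecs = tuple(e.strip() for e in row.ec_numbers.split(";") if e.strip())
            pairs.append(
                MappedReactionPair(
                    reaction_id=row.reaction_id,
                    reactant=reactant,
                    product=product,
                    atom_map=atom_map,
                    ec_numbers=ecs,
                )
            )
        except (StructureParseError, FormatError, ValueError) as exc:
            logger.warning("%s:%d: skipping reaction: %s", path, line, exc)
            skipped += 1
    if skipped:
        logger.info("%s: skipped %d unusable reaction row(s)", path, skipped)
    return pairs


def write_reaction_table(pairs: Sequence[MappedReactionPair], path) -> None:
    pd.DataFrame(
        {
            "reaction_id": [p.reaction_id for p in pairs],
            "reaction_smiles": [mapped_reaction_smiles(p) for p in pairs],
            "ec_numbers": [";".join(p.ec_numbers) for p in pairs],
        }
    ).to_csv(path, sep="\t", index=False)


def read_model(metabolite_path, reaction_path=None, organism: str = "") -> MetabolicModel:
    metabolites = read_metabolite_table(metabolite_path)
    reactions = read_reaction_table(reaction_path) if reaction_path else []
    return MetabolicModel(metabolites=metabolites, reactions=reactions, organism=organism)


def read_feature_table(path) -> List[Feature]:
    df = pd.read_csv(path, dtype={"feature_id": str})
    _require_columns(df, ["feature_id", "mz", "rt_min", "polarity"], path)
    features = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        try:
            features.append(
                Feature(
                    feature_id=row.feature_id,
                    mass=float(row.mz),
                    rt_min=float(row.rt_min),
                    polarity=str(row.polarity),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{line}: {exc}") from exc
    return features


def write_feature_table(features: Sequence[Feature], path) -> None:
    pd.DataFrame(
        {
            "feature_id": [f.feature_id for f in features],
            "mz": [f"{f.mass:.6f}" for f in features],
            "rt_min": [f"{f.rt_min:.3f}" for f in features],
            "polarity": [f.polarity for f in features],
        }
    ).to_csv(path, index=False)


def read_xref_table(path) -> Dict[str, str]:
    """structure key → external id; malformed rows skipped with a warning."""
    table: Dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                logger.warning("%s:%d: malformed xref row skipped", path, line_no)
                continue
            table[parts[0].strip()] = parts[1].strip()
    return table


def write_xref_table(table: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("structure_key\texternal_id\n")
        for key in sorted(table):
            fh.write(f"{key}\t{table[key]}\n")


def read_library(path) -> OperatorLibrary:
    with open(path) as fh:
        return OperatorLibrary.from_json(json.load(fh))


def write_library(library: OperatorLibrary, path) -> None:
    with open(path, "w") as fh:
        json.dump(library.to_json(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_matches(results: Sequence[MatchResult], path) -> None:
    """Matches TSV: feature_id, record_id, record mass, ppm error, source."""
    rows = []
    for result in results:
        for match in result.matches:
            rows.append(
                (
                    result.feature.feature_id,
                    match.entry.record_id,
                    f"{match.entry.mass:.6f}",
                    f"{match.ppm_error:.4f}",
                    match.entry.source,
                )
            )
    rows.sort()
    with open(path, "w") as fh:
        fh.write("feature_id\trecord_id\trecord_mass\tppm_error\tsource\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def write_derivatives(emm: ExtendedModel, path) -> None:
    """Derivative TSV with provenance counts, ordered by canonical key."""
    with open(path, "w") as fh:
        fh.write(
            "structure_key\tmass\tparent_ids\toperator_ids\tn_reactions\tn_ecs\tdepth\n"
        )
        for key in sorted(emm.derivatives):
            d = emm.derivatives[key]
            fh.write(
                "\t".join(
                    [
                        d.key,
                        repr(d.mass),  # shortest round-trip float, so staged
                        # re-reads reproduce in-memory ppm errors exactly
                        ";".join(sorted(d.parent_ids)),
                        ";".join(sorted(d.operator_ids)),
                        str(d.n_reactions),
                        str(d.n_ecs),
                        str(d.depth),
                    ]
                )
                + "\n"
            )


def write_json(data, path) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
        fh.write("\n")
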