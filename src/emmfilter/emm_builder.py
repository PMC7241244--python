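"""Build the extended metabolic model (EMM).

Every operator in the mined library is applied to every model metabolite
whose local atom environment matches the operator's pattern. Each
successful application yields a derivative metabolite; derivatives whose
structure is already in the model are discarded, the rest are deduplicated
by canonical key with provenance merged, and summary statistics (unique
derivatives, unique derivative masses, fold changes over the model) are
computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

from rdkit import Chem
from rdkit.Chem import Mol

from .chem_core import (
    canonical_key,
    monoisotopic_mass,
    neutralize_charges,
    parse_structure,
)
from .operator_miner import (
    BiotransformationOperator,
    MappedReactionPair,
    OperatorLibrary,
    _ORDER_BOND,
    _bond_order,
    _branch_atoms,
    _fragment_smiles,
    extract_signature,
)

logger = logging.getLogger(__name__)

__all__ = [
    "InvalidDerivativeError",
    "Metabolite",
    "MetabolicModel",
    "DerivativeRecord",
    "ExtendedModel",
    "match_sites",
    "apply_operator",
    "build_emm",
    "merge_models",
    "count_unique_masses",
]

#: Masses closer than this (Da) are counted as one "unique mass" — below
#: instrument precision, far above float noise.
MASS_GROUP_TOLERANCE = 1e-4


class InvalidDerivativeError(ValueError):
    """Replaying an edit script produced a chemically invalid structure."""


@dataclass(frozen=True)
class Metabolite:
    metabolite_id: str
    name: str
    structure: Mol
    key: str
    mass: float

    @classmethod
    def from_smiles(cls, metabolite_id: str, name: str, smiles: str) -> "Metabolite":
        """Parse and protonation-normalize a metabolite structure.

        Model inputs are sometimes drawn as salts/zwitterions; masses and
        matching patterns are defined on the neutral species.
        """
        mol = neutralize_charges(parse_structure(smiles))
        return cls(
            metabolite_id=metabolite_id,
            name=name,
            structure=mol,
            key=canonical_key(mol),
            mass=monoisotopic_mass(mol),
        )


@dataclass
class MetabolicModel:
    """Reference metabolic model: metabolites + reactions for one system."""

    metabolites: List[Metabolite]
    reactions: List[MappedReactionPair] = field(default_factory=list)
    organism: str = ""

    def __post_init__(self):
        ids = [m.metabolite_id for m in self.metabolites]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate metabolite ids: {dupes}")

    @property
    def keys(self) -> Set[str]:
        return {m.key for m in self.metabolites}

    @property
    def unique_mass_count(self) -> int:
        return count_unique_masses([m.mass for m in self.metabolites])


@dataclass
class DerivativeRecord:
    """One unique derivative structure with merged provenance."""

    structure: Mol
    key: str
    mass: float
    parent_ids: FrozenSet[str]
    operator_ids: FrozenSet[str]
    provenance: FrozenSet[Tuple[str, Tuple[str, ...]]]  # (reaction id, ECs)
    depth: int = 1

    @property
    def n_reactions(self) -> int:
        return len({rid for rid, _ in self.provenance})

    @property
    def n_ecs(self) -> int:
        return len({ec for _, ecs in self.provenance for ec in ecs})


@dataclass
class ExtendedModel:
    """A reference model plus its deduplicated derivative records."""

    model: MetabolicModel
    library: OperatorLibrary
    derivatives: Dict[str, DerivativeRecord]
    depth: int = 1

    def statistics(self) -> dict:
        """Counts and fold changes describing the expansion."""
        n_model = len(self.model.metabolites)
        n_model_masses = self.model.unique_mass_count
        n_deriv = len(self.derivatives)
        n_deriv_masses = count_unique_masses(
            [d.mass for d in self.derivatives.values()]
        )
        return {
            "model_reactions": len(self.model.reactions),
            "model_metabolites": n_model,
            "model_unique_masses": n_model_masses,
            "unique_operators": len(self.library),
            "unique_derivatives": n_deriv,
            "unique_derivative_masses": n_deriv_masses,
            "metabolite_fold_change": round(n_deriv / n_model, 2) if n_model else None,
            "mass_fold_change": (
                round(n_deriv_masses / n_model_masses, 2) if n_model_masses else None
            ),
        }


def count_unique_masses(masses: Sequence[float], tol: float = MASS_GROUP_TOLERANCE) -> int:
    """Number of mass values distinct beyond ``tol``, by adjacent-gap
    clustering of the sorted list."""
    if not masses:
        return 0
    ordered = sorted(masses)
    count = 1
    anchor = ordered[0]
    for m in ordered[1:]:
        if m - anchor > tol:
            count += 1
            anchor = m
    return count


# ---------------------------------------------------------------------------
# operator application


def _candidate_neighbors(mol: Mol, site: int, descriptor: Sequence) -> List[int]:
    """Site neighbors matching a (bond order, element, aromatic) descriptor,
    ordered by canonical atom rank for determinism."""
    order, elem, aromatic = descriptor
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    site_atom = mol.GetAtomWithIdx(site)
    found = []
    for bond in site_atom.GetBonds():
        nbr = bond.GetOtherAtom(site_atom)
        if (
            _bond_order(bond) == order
            and nbr.GetSymbol() == elem
            and nbr.GetIsAromatic() == bool(aromatic)
        ):
            found.append(nbr.GetIdx())
    return sorted(found, key=lambda i: ranks[i])


def _replay_edits(
    substrate: Mol, edits: Sequence[dict], site: int
) -> Tuple[Mol, Dict[int, int]]:
    """Replay an edit script at ``site`` on a copy of ``substrate``.

    Returns the sanitized product and a map from surviving substrate atom
    indices to product atom indices. Hydrogen counts are not edited
    directly: they are refilled from valence during sanitization, which is
    what makes e.g. a C=O → C–O bond edit add one hydrogen to each atom.

    Raises :class:`InvalidDerivativeError` when an edit cannot be placed or
    the result fails valence/aromaticity sanitization.
    """
    work = Chem.RWMol(substrate)
    for atom in work.GetAtoms():
        atom.SetIntProp("_src", atom.GetIdx())
    n_src = substrate.GetNumAtoms()
    next_src = n_src  # pseudo-ids for atoms introduced by attachments
    site_src = site
    consumed: Set[int] = set()  # _src ids of neighbors already used

    def locate(src: int) -> int:
        for atom in work.GetAtoms():
            if atom.GetIntProp("_src") == src:
                return atom.GetIdx()
        raise InvalidDerivativeError("edit site removed by an earlier edit")

    for edit in edits:
        cur_site = locate(site_src)
        kind = edit["op"]
        if kind == "change_bond":
            for nbr in _candidate_neighbors(work, cur_site, edit["neighbor"]):
                nbr_src = work.GetAtomWithIdx(nbr).GetIntProp("_src")
                if nbr_src in consumed:
                    continue
                bond = work.GetBondBetweenAtoms(cur_site, nbr)
                bond.SetBondType(_ORDER_BOND[edit["new_order"]])
                if edit["new_order"] != "ar":
                    bond.SetIsAromatic(False)
                consumed.add(nbr_src)
                break
            else:
                raise InvalidDerivativeError(
                    f"no free neighbor matches descriptor {edit['neighbor']}"
                )
        elif kind == "delete_fragment":
            for nbr in _candidate_neighbors(work, cur_site, edit["neighbor"]):
                nbr_src = work.GetAtomWithIdx(nbr).GetIntProp("_src")
                if nbr_src in consumed:
                    continue
                if work.GetBondBetweenAtoms(cur_site, nbr).IsInRing():
                    continue  # branch loops back to the site: not deletable
                branch = _branch_atoms(work, nbr, blocked=cur_site)
                if _fragment_smiles(work, branch) != edit["fragment"]:
                    continue  # site carries a different substituent here
                for idx in sorted(branch, reverse=True):
                    work.RemoveAtom(idx)
                break
            else:
                raise InvalidDerivativeError(
                    f"no branch at the site matches fragment {edit['fragment']!r}"
                )
        elif kind == "attach_fragment":
            frag = Chem.MolFromSmiles(edit["fragment"], sanitize=False)
            if frag is None:
                raise InvalidDerivativeError(
                    f"unparsable fragment {edit['fragment']!r}"
                )
            offset = work.GetNumAtoms()
            combo = Chem.RWMol(Chem.CombineMols(work.GetMol(), frag))
            attach_idx = None
            for i in range(offset, combo.GetNumAtoms()):
                atom = combo.GetAtomWithIdx(i)
                atom.SetIntProp("_src", next_src)
                next_src += 1
                if atom.GetAtomMapNum() == 1:
                    attach_idx = i
                    atom.SetAtomMapNum(0)
            if attach_idx is None:
                raise InvalidDerivativeError(
                    f"fragment {edit['fragment']!r} has no attachment atom"
                )
            combo.AddBond(cur_site, attach_idx, _ORDER_BOND[edit["order"]])
            work = combo
        else:
            raise InvalidDerivativeError(f"unknown edit kind {kind!r}")

    product = work.GetMol()
    try:
        Chem.SanitizeMol(product)
    except Exception as exc:  # valence, kekulization, ...
        raise InvalidDerivativeError(f"invalid derivative: {exc}") from exc
    index_map: Dict[int, int] = {}
    for atom in product.GetAtoms():
        src = atom.GetIntProp("_src")
        if src < n_src:
            index_map[src] = atom.GetIdx()
        atom.ClearProp("_src")
    return product, index_map


def match_sites(substrate: Mol, op: BiotransformationOperator) -> List[int]:
    """All substrate atoms whose neighborhood signature equals the
    operator's pattern, in ascending canonical-rank order."""
    ranks = list(Chem.CanonicalRankAtoms(substrate, breakTies=True))
    sites = [
        atom.GetIdx()
        for atom in substrate.GetAtoms()
        if extract_signature(substrate, atom.GetIdx()) == op.pattern
    ]
    return sorted(sites, key=lambda i: (ranks[i], i))


def apply_operator(substrate: Mol, op: BiotransformationOperator, site: int) -> Mol:
    """Apply an operator at a matched site, returning the derivative.

    Raises :class:`InvalidDerivativeError` when the edit script does not
    fit the site's actual substituents or yields an invalid structure; the
    caller is expected to skip such sites.
    """
    product, _ = _replay_edits(substrate, op.edits, site)
    return product


# ---------------------------------------------------------------------------
# EMM assembly


def build_emm(
    model: MetabolicModel,
    library: OperatorLibrary,
    depth: int = 1,
) -> ExtendedModel:
    """Generate all derivatives of the model under the operator library.

    Every (metabolite, operator, matched site) product is collected;
    products whose canonical key already belongs to the model are
    discarded; the rest are deduplicated by key with provenance unioned.
    With ``depth`` > 1 the operators are re-applied to the derivatives of
    the previous round (off by default).
    """
    if not model.metabolites:
        raise ValueError("model has no metabolites")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    model_keys = model.keys
    derivatives: Dict[str, DerivativeRecord] = {}
    # substrates for the current round: (parent id, structure)
    frontier: List[Tuple[str, Mol]] = [
        (m.metabolite_id, m.structure) for m in model.metabolites
    ]
    for level in range(1, depth + 1):
        produced: List[Tuple[str, Mol]] = []
        for parent_id, structure in frontier:
            for op in library:
                for site in match_sites(structure, op):
                    try:
                        product = apply_operator(structure, op, site)
                    except InvalidDerivativeError as exc:
                        logger.debug(
                            "skipping %s @ %s on %s: %s",
                            op.operator_id, site, parent_id, exc,
                        )
                        continue
                    key = canonical_key(product)
                    if key in model_keys:
                        continue
                    if key in derivatives:
                        rec = derivatives[key]
                        derivatives[key] = DerivativeRecord(
                            structure=rec.structure,
                            key=key,
                            mass=rec.mass,
                            parent_ids=rec.parent_ids | {parent_id},
                            operator_ids=rec.operator_ids | {op.operator_id},
                            provenance=rec.provenance | op.provenance,
                            depth=min(rec.depth, level),
                        )
                    else:
                        derivatives[key] = DerivativeRecord(
                            structure=product,
                            key=key,
                            mass=monoisotopic_mass(product),
                            parent_ids=frozenset({parent_id}),
                            operator_ids=frozenset({op.operator_id}),
                            provenance=op.provenance,
                            depth=level,
                        )
                        produced.append((parent_id, product))
        frontier = produced
        if not frontier:
            break
    if not derivatives:
        logger.info("EMM construction produced no derivatives")
    return ExtendedModel(model=model, library=library, derivatives=derivatives, depth=depth)


def merge_models(models: Sequence[MetabolicModel]) -> MetabolicModel:
    """Mechanical union of models: metabolites by canonical key, reactions
    by reaction id.

    The same structure under two ids keeps the first id; the other ids are
    recorded as synonyms in the name field. A reaction id appearing twice
    with different chemistry is an error.
    """
    if not models:
        raise ValueError("no models to merge")
    by_key: Dict[str, Metabolite] = {}
    synonyms: Dict[str, List[str]] = {}
    reactions: Dict[str, MappedReactionPair] = {}
    organisms = []
    for model in models:
        if model.organism:
            organisms.append(model.organism)
        for met in model.metabolites:
            if met.key not in by_key:
                by_key[met.key] = met
            elif met.metabolite_id != by_key[met.key].metabolite_id:
                synonyms.setdefault(met.key, []).append(met.metabolite_id)
        for rxn in model.reactions:
            if rxn.reaction_id in reactions:
                prior = reactions[rxn.reaction_id]
                if (
                    canonical_key(prior.reactant) != canonical_key(rxn.reactant)
                    or canonical_key(prior.product) != canonical_key(rxn.product)
                ):
                    raise ValueError(
                        f"reaction id {rxn.reaction_id!r} appears with "
                        "conflicting chemistry"
                    )
            else:
                reactions[rxn.reaction_id] = rxn
    merged = []
    for key, met in by_key.items():
        extra = sorted(set(synonyms.get(key, [])))
        if extra:
            met = Metabolite(
                metabolite_id=met.metabolite_id,
                name=f"{met.name} (syn: {', '.join(extra)})",
                structure=met.structure,
                key=met.key,
                mass=met.mass,
            )
        merged.append(met)
    return MetabolicModel(
        metabolites=merged,
        reactions=list(reactions.values()),
        organism="+".join(organisms),
    )
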