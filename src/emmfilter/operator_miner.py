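"""Mining biotransformation operators from enzymatic reactant→product pairs.

An operator is a reusable local edit rule: it records (a) a matching
pattern — the reaction center atom together with its first- and
second-level neighborhood — and (b) an edit script that rewrites the
center's bonds and attached fragments, plus the mass change the edit
implies and the reactions/EC numbers it was mined from. Applying the
operator to a new substrate that presents the same local environment
predicts a promiscuous enzyme product.

The neighborhood signature used here is a declared approximation of
KEGG-style atom typing: element, aromaticity, ring membership and degree at
the center; (bond order, element, aromaticity) triples one bond out; and
(two-bond-order path, terminal element) pairs two bonds out.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from rdkit import Chem
from rdkit.Chem import Mol, rdFMCS

from .chem_core import canonical_key, heavy_atom_count, monoisotopic_mass

logger = logging.getLogger(__name__)

__all__ = [
    "UnalignablePairError",
    "NoTransformationError",
    "OperatorMiningError",
    "MappedReactionPair",
    "NeighborhoodSignature",
    "BiotransformationOperator",
    "OperatorLibrary",
    "infer_atom_map",
    "detect_reaction_center",
    "extract_signature",
    "mine_operator",
    "build_operator_library",
]


class UnalignablePairError(ValueError):
    """No common heavy-atom substructure exists between the two sides."""


class NoTransformationError(ValueError):
    """Reactant and product describe the same structure."""


class OperatorMiningError(ValueError):
    """The structural change cannot be expressed as a local edit script."""


_BOND_ORDER = {
    Chem.BondType.SINGLE: "1",
    Chem.BondType.DOUBLE: "2",
    Chem.BondType.TRIPLE: "3",
    Chem.BondType.AROMATIC: "ar",
}
_ORDER_BOND = {v: k for k, v in _BOND_ORDER.items()}


def _bond_order(bond) -> str:
    try:
        return _BOND_ORDER[bond.GetBondType()]
    except KeyError:
        raise OperatorMiningError(
            f"unsupported bond type {bond.GetBondType()}"
        ) from None


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class MappedReactionPair:
    """One reactant→product pair of an enzymatic reaction with atom map.

    ``atom_map`` is a partial bijection from reactant atom indices to
    product atom indices; mapped atoms must agree in element.
    """

    reaction_id: str
    reactant: Mol
    product: Mol
    atom_map: Dict[int, int]
    ec_numbers: Tuple[str, ...] = ()

    def __post_init__(self):
        if not self.atom_map:
            raise ValueError(f"{self.reaction_id}: atom map is empty")
        for r_idx, p_idx in self.atom_map.items():
            r_sym = self.reactant.GetAtomWithIdx(r_idx).GetSymbol()
            p_sym = self.product.GetAtomWithIdx(p_idx).GetSymbol()
            if r_sym != p_sym:
                raise ValueError(
                    f"{self.reaction_id}: mapped atoms {r_idx}->{p_idx} "
                    f"have different elements ({r_sym} vs {p_sym})"
                )

    def reversed(self) -> "MappedReactionPair":
        """The same reaction read product→reactant."""
        return MappedReactionPair(
            reaction_id=self.reaction_id,
            reactant=self.product,
            product=self.reactant,
            atom_map={p: r for r, p in self.atom_map.items()},
            ec_numbers=self.ec_numbers,
        )


@dataclass(frozen=True)
class NeighborhoodSignature:
    """Local environment of one atom: the center plus two shells out.

    center: (element, aromatic, in_ring, heavy-atom degree)
    level1: sorted tuple of (bond order, neighbor element, neighbor aromatic)
    level2: sorted tuple of ((first bond order, second bond order), terminal
            element) over all two-bond paths leaving the center
    """

    center: Tuple[str, bool, bool, int]
    level1: Tuple[Tuple[str, str, bool], ...]
    level2: Tuple[Tuple[Tuple[str, str], str], ...]

    def to_json(self) -> dict:
        return {
            "center": list(self.center),
            "level1": [list(t) for t in self.level1],
            "level2": [[list(t[0]), t[1]] for t in self.level2],
        }

    @classmethod
    def from_json(cls, data: dict) -> "NeighborhoodSignature":
        return cls(
            center=tuple(data["center"]),
            level1=tuple(tuple(t) for t in data["level1"]),
            level2=tuple((tuple(t[0]), t[1]) for t in data["level2"]),
        )


@dataclass(frozen=True)
class BiotransformationOperator:
    """A mined edit rule with pattern, edit script, mass delta, provenance.

    The edit script is an ordered list of primitive edits, each a dict:

    - ``{"op": "change_bond", "neighbor": [order, elem, aromatic],
       "new_order": order}`` — change the bond between the center and the
      neighbor matching the descriptor;
    - ``{"op": "delete_fragment", "neighbor": [order, elem, aromatic],
       "fragment": smiles}`` — delete the acyclic branch starting at that
      neighbor (the branch must equal ``fragment``);
    - ``{"op": "attach_fragment", "fragment": smiles, "order": order}`` —
      attach a new fragment to the center; the fragment's attachment atom
      carries atom-map number 1.

    Hydrogen bookkeeping is implicit: hydrogen counts are recomputed from
    valence after the heavy-atom edits are replayed.
    """

    operator_id: str
    pattern: NeighborhoodSignature
    edits: Tuple[dict, ...]
    mass_delta: float
    provenance: FrozenSet[Tuple[str, Tuple[str, ...]]]  # (reaction id, ECs)

    @property
    def n_reactions(self) -> int:
        """Number of distinct reactions used to derive this operator."""
        return len({rid for rid, _ in self.provenance})

    @property
    def n_ecs(self) -> int:
        """Number of distinct EC numbers associated with those reactions."""
        return len({ec for _, ecs in self.provenance for ec in ecs})

    def to_json(self) -> dict:
        return {
            "operator_id": self.operator_id,
            "pattern": self.pattern.to_json(),
            "edits": [dict(e) for e in self.edits],
            "mass_delta": self.mass_delta,
            "provenance": sorted(
                [rid, sorted(ecs)] for rid, ecs in self.provenance
            ),
        }

    @classmethod
    def from_json(cls, data: dict) -> "BiotransformationOperator":
        return cls(
            operator_id=data["operator_id"],
            pattern=NeighborhoodSignature.from_json(data["pattern"]),
            edits=tuple(data["edits"]),
            mass_delta=float(data["mass_delta"]),
            provenance=frozenset(
                (rid, tuple(ecs)) for rid, ecs in data["provenance"]
            ),
        )


def _edits_key(edits: Sequence[dict]) -> str:
    return json.dumps(list(edits), sort_keys=True)


def _operator_id(pattern: NeighborhoodSignature, edits: Sequence[dict]) -> str:
    payload = json.dumps(
        {"pattern": pattern.to_json(), "edits": list(edits)}, sort_keys=True
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class OperatorLibrary:
    """Deduplicated collection of operators with a pattern index."""

    operators: Dict[str, BiotransformationOperator] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.operators)

    def __iter__(self):
        return iter(self.operators.values())

    def add(self, op: BiotransformationOperator) -> None:
        """Insert an operator, merging provenance on (pattern, edit) dupes."""
        existing = self.operators.get(op.operator_id)
        if existing is None:
            self.operators[op.operator_id] = op
            return
        if abs(existing.mass_delta - op.mass_delta) > 1e-6:
            raise OperatorMiningError(
                f"operator {op.operator_id}: inconsistent mass delta "
                f"({existing.mass_delta} vs {op.mass_delta})"
            )
        self.operators[op.operator_id] = BiotransformationOperator(
            operator_id=existing.operator_id,
            pattern=existing.pattern,
            edits=existing.edits,
            mass_delta=existing.mass_delta,
            provenance=existing.provenance | op.provenance,
        )

    def by_pattern(self) -> Dict[NeighborhoodSignature, List[BiotransformationOperator]]:
        index: Dict[NeighborhoodSignature, List[BiotransformationOperator]] = {}
        for op in self:
            index.setdefault(op.pattern, []).append(op)
        return index

    def to_json(self) -> list:
        return [self.operators[k].to_json() for k in sorted(self.operators)]

    @classmethod
    def from_json(cls, data: list) -> "OperatorLibrary":
        lib = cls()
        for entry in data:
            lib.add(BiotransformationOperator.from_json(entry))
        return lib


# ---------------------------------------------------------------------------
# atom correspondence


def infer_atom_map(reactant: Mol, product: Mol) -> Dict[int, int]:
    """Maximum-common-substructure atom correspondence between two sides.

    Elements must match atom-to-atom; bond orders are allowed to differ so
    that e.g. a ketone carbon still maps onto the carbinol carbon of its
    reduced product. Among the possible embeddings the one whose canonical
    atom-rank tuple is lexicographically smallest is chosen on each side,
    making the result deterministic.
    """
    result = rdFMCS.FindMCS(
        [reactant, product],
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareAny,
        ringMatchesRingOnly=False,
        timeout=10,
    )
    if result.numAtoms < 1 or not result.smartsString:
        raise UnalignablePairError(
            "no common heavy-atom substructure between reactant and product"
        )
    query = Chem.MolFromSmarts(result.smartsString)

    def best_match(mol: Mol) -> Tuple[int, ...]:
        ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
        matches = mol.GetSubstructMatches(query, uniquify=False, maxMatches=5000)
        if not matches:
            raise UnalignablePairError("common substructure failed to embed")
        return min(matches, key=lambda m: tuple(ranks[i] for i in m))

    r_match = best_match(reactant)
    p_match = best_match(product)
    return {r: p for r, p in zip(r_match, p_match)}


# ---------------------------------------------------------------------------
# reaction center and signature


def _mapped_bond_profile(mol: Mol, idx: int, mapped: Dict[int, int]):
    """Multiset of (bond order, mapped partner on the other side)."""
    profile = []
    for bond in mol.GetAtomWithIdx(idx).GetBonds():
        other = bond.GetOtherAtomIdx(idx)
        if other in mapped:
            profile.append((_bond_order(bond), mapped[other]))
    return sorted(profile)


def detect_reaction_center(pair: MappedReactionPair) -> FrozenSet[int]:
    """Reactant atom indices whose environment changes in the reaction.

    An atom belongs to the center when its hydrogen count, formal charge,
    aromaticity or bond multiset differs between the two sides, or when it
    is adjacent to an unmapped (lost or gained) atom on either side.
    """
    if canonical_key(pair.reactant) == canonical_key(pair.product):
        raise NoTransformationError(
            f"{pair.reaction_id}: reactant and product are identical"
        )
    fwd = pair.atom_map
    rev = {p: r for r, p in fwd.items()}
    center = set()
    for r_idx, p_idx in fwd.items():
        ra = pair.reactant.GetAtomWithIdx(r_idx)
        pa = pair.product.GetAtomWithIdx(p_idx)
        if (
            ra.GetTotalNumHs() != pa.GetTotalNumHs()
            or ra.GetFormalCharge() != pa.GetFormalCharge()
            or ra.GetIsAromatic() != pa.GetIsAromatic()
        ):
            center.add(r_idx)
            continue
        r_profile = _mapped_bond_profile(pair.reactant, r_idx, fwd)
        p_profile = _mapped_bond_profile(pair.product, p_idx, {p: p for p in rev})
        # compare against product bonds translated into product indices
        p_profile = sorted(
            (o, partner) for o, partner in p_profile
        )
        r_profile_as_p = sorted((o, partner) for o, partner in r_profile)
        if r_profile_as_p != p_profile:
            center.add(r_idx)
            continue
        if any(
            bond.GetOtherAtomIdx(r_idx) not in fwd
            for bond in ra.GetBonds()
        ) or any(
            bond.GetOtherAtomIdx(p_idx) not in rev
            for bond in pa.GetBonds()
        ):
            center.add(r_idx)
    if not center:
        raise NoTransformationError(
            f"{pair.reaction_id}: no transformation detected at mapped atoms"
        )
    return frozenset(center)


def extract_signature(mol: Mol, center: int) -> NeighborhoodSignature:
    """Neighborhood signature of ``center``: the atom plus two shells out."""
    atom = mol.GetAtomWithIdx(center)
    level1 = []
    level2 = []
    for bond in atom.GetBonds():
        nbr = bond.GetOtherAtom(atom)
        o1 = _bond_order(bond)
        level1.append((o1, nbr.GetSymbol(), nbr.GetIsAromatic()))
        for bond2 in nbr.GetBonds():
            terminal = bond2.GetOtherAtom(nbr)
            if terminal.GetIdx() == center:
                continue
            level2.append(((o1, _bond_order(bond2)), terminal.GetSymbol()))
    return NeighborhoodSignature(
        center=(
            atom.GetSymbol(),
            atom.GetIsAromatic(),
            atom.IsInRing(),
            atom.GetDegree(),
        ),
        level1=tuple(sorted(level1)),
        level2=tuple(sorted(level2)),
    )


# ---------------------------------------------------------------------------
# edit-script extraction


def _connected_components(mol: Mol, members: FrozenSet[int]) -> List[FrozenSet[int]]:
    """Connected components of the induced subgraph on ``members``."""
    remaining = set(members)
    components = []
    while remaining:
        seed = min(remaining)
        comp = {seed}
        frontier = [seed]
        while frontier:
            idx = frontier.pop()
            for bond in mol.GetAtomWithIdx(idx).GetBonds():
                other = bond.GetOtherAtomIdx(idx)
                if other in remaining and other not in comp:
                    comp.add(other)
                    frontier.append(other)
        remaining -= comp
        components.append(frozenset(comp))
    return components


def _branch_atoms(mol: Mol, start: int, blocked: int) -> FrozenSet[int]:
    """Atoms reachable from ``start`` without passing through ``blocked``."""
    seen = {start}
    frontier = [start]
    while frontier:
        idx = frontier.pop()
        for bond in mol.GetAtomWithIdx(idx).GetBonds():
            other = bond.GetOtherAtomIdx(idx)
            if other == blocked or other in seen:
                continue
            seen.add(other)
            frontier.append(other)
    return frozenset(seen)


def _fragment_smiles(mol: Mol, atoms: FrozenSet[int], attach: Optional[int] = None) -> str:
    """Canonical SMILES of a fragment; ``attach`` gets atom-map number 1."""
    work = Chem.Mol(mol)
    for a in work.GetAtoms():
        a.SetAtomMapNum(0)
    if attach is not None:
        work.GetAtomWithIdx(attach).SetAtomMapNum(1)
    return Chem.MolFragmentToSmiles(work, atomsToUse=sorted(atoms), canonical=True)


def _neighbor_descriptor(mol: Mol, center: int, nbr: int) -> List:
    bond = mol.GetBondBetweenAtoms(center, nbr)
    atom = mol.GetAtomWithIdx(nbr)
    return [_bond_order(bond), atom.GetSymbol(), atom.GetIsAromatic()]


def _extract_edits(pair: MappedReactionPair, anchor: int) -> List[dict]:
    """Edit script rewriting the reactant's anchor environment into the
    product's, expressed relative to the anchor atom.

    Raises :class:`OperatorMiningError` when the change is not local to the
    anchor (e.g. bonds between two non-anchor atoms change, or a lost
    fragment is attached to more than one mapped atom).
    """
    fwd = pair.atom_map
    rev = {p: r for r, p in fwd.items()}
    r_mol, p_mol = pair.reactant, pair.product
    p_anchor = fwd[anchor]
    edits: List[dict] = []

    # bond-order changes between the anchor and mapped neighbors
    for bond in r_mol.GetAtomWithIdx(anchor).GetBonds():
        nbr = bond.GetOtherAtomIdx(anchor)
        if nbr not in fwd:
            continue
        p_bond = p_mol.GetBondBetweenAtoms(p_anchor, fwd[nbr])
        if p_bond is None:
            raise OperatorMiningError(
                f"{pair.reaction_id}: bond cleavage between mapped atoms is "
                "not expressible as a local edit"
            )
        old, new = _bond_order(bond), _bond_order(p_bond)
        if old != new:
            edits.append(
                {
                    "op": "change_bond",
                    "neighbor": _neighbor_descriptor(r_mol, anchor, nbr),
                    "new_order": new,
                }
            )

    # lost fragments: unmapped reactant branches hanging off the anchor
    lost = frozenset(i for i in range(r_mol.GetNumAtoms()) if i not in fwd)
    for comp in _connected_components(r_mol, lost):
        attach_bonds = [
            (i, bond.GetOtherAtomIdx(i))
            for i in comp
            for bond in r_mol.GetAtomWithIdx(i).GetBonds()
            if bond.GetOtherAtomIdx(i) not in comp
        ]
        anchors = {m for _, m in attach_bonds}
        if anchors == {anchor}:
            if len(attach_bonds) != 1:
                raise OperatorMiningError(
                    f"{pair.reaction_id}: lost fragment attached through "
                    "multiple bonds"
                )
            frag_root = attach_bonds[0][0]
            edits.append(
                {
                    "op": "delete_fragment",
                    "neighbor": _neighbor_descriptor(r_mol, anchor, frag_root),
                    "fragment": _fragment_smiles(r_mol, comp),
                }
            )
        elif anchor in anchors:
            raise OperatorMiningError(
                f"{pair.reaction_id}: lost fragment spans several center atoms"
            )

    # gained fragments: unmapped product branches hanging off the anchor
    gained = frozenset(i for i in range(p_mol.GetNumAtoms()) if i not in rev)
    for comp in _connected_components(p_mol, gained):
        attach_bonds = [
            (i, bond.GetOtherAtomIdx(i), bond)
            for i in comp
            for bond in p_mol.GetAtomWithIdx(i).GetBonds()
            if bond.GetOtherAtomIdx(i) not in comp
        ]
        anchors = {m for _, m, _ in attach_bonds}
        if anchors == {p_anchor}:
            if len(attach_bonds) != 1:
                raise OperatorMiningError(
                    f"{pair.reaction_id}: gained fragment attached through "
                    "multiple bonds"
                )
            frag_root, _, bond = attach_bonds[0]
            edits.append(
                {
                    "op": "attach_fragment",
                    "fragment": _fragment_smiles(p_mol, comp, attach=frag_root),
                    "order": _bond_order(bond),
                }
            )
        elif p_anchor in anchors:
            raise OperatorMiningError(
                f"{pair.reaction_id}: gained fragment spans several center atoms"
            )

    if not edits:
        raise OperatorMiningError(
            f"{pair.reaction_id}: change at center is hydrogen/charge-only "
            "and cannot be expressed as a heavy-atom edit"
        )
    # canonical edit ordering for stable operator identity
    edits.sort(key=lambda e: json.dumps(e, sort_keys=True))
    return edits


def _choose_anchor(mol: Mol, component: FrozenSet[int]) -> int:
    """Deterministic anchor for a center component: highest heavy-atom
    degree, ties broken by canonical atom rank."""
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    return max(component, key=lambda i: (mol.GetAtomWithIdx(i).GetDegree(), -ranks[i]))


def mine_operator(
    pair: MappedReactionPair, max_center_size: int = 6
) -> List[BiotransformationOperator]:
    """Mine one operator per connected component of the reaction center.

    Each operator is verified to round-trip on its source pair: replaying
    every component's edit script on the reactant must reproduce the
    product. Components larger than ``max_center_size`` atoms are rejected
    as over-specific.
    """
    from .emm_builder import _replay_edits  # local import to avoid a cycle

    center = detect_reaction_center(pair)
    components = _connected_components(pair.reactant, center)
    ops: List[Tuple[BiotransformationOperator, int]] = []
    for comp in components:
        if len(comp) > max_center_size:
            raise OperatorMiningError(
                f"{pair.reaction_id}: reaction-center component has "
                f"{len(comp)} atoms (bound {max_center_size}); pattern would "
                "be over-specific"
            )
        anchor = _choose_anchor(pair.reactant, comp)
        pattern = extract_signature(pair.reactant, anchor)
        edits = _extract_edits(pair, anchor)
        # per-operator mass delta measured by actually replaying the edit
        intermediate, _ = _replay_edits(pair.reactant, edits, anchor)
        delta = monoisotopic_mass(intermediate) - monoisotopic_mass(pair.reactant)
        op = BiotransformationOperator(
            operator_id=_operator_id(pattern, edits),
            pattern=pattern,
            edits=tuple(edits),
            mass_delta=delta,
            provenance=frozenset({(pair.reaction_id, tuple(pair.ec_numbers))}),
        )
        ops.append((op, anchor))

    # round-trip check: replay all component edits sequentially
    current = Chem.Mol(pair.reactant)
    index_map = {i: i for i in range(pair.reactant.GetNumAtoms())}
    for op, anchor in ops:
        site = index_map.get(anchor)
        if site is None:
            raise OperatorMiningError(
                f"{pair.reaction_id}: center atom consumed by an earlier edit"
            )
        current, step_map = _replay_edits(current, op.edits, site)
        index_map = {
            orig: step_map[cur]
            for orig, cur in index_map.items()
            if cur in step_map
        }
    if canonical_key(current) != canonical_key(pair.product):
        raise OperatorMiningError(
            f"{pair.reaction_id}: edit script does not round-trip to the "
            "source product"
        )
    return [op for op, _ in ops]


def build_operator_library(
    reactions: Sequence[MappedReactionPair],
    min_heavy_atoms: int = 4,
    both_directions: bool = True,
    max_center_size: int = 6,
) -> OperatorLibrary:
    """Mine and deduplicate operators over a set of reactions.

    Pairs where either side has fewer than ``min_heavy_atoms`` heavy atoms
    are excluded (currency-metabolite guard). With ``both_directions`` each
    pair is mined reactant→product and product→reactant. Operators sharing
    (pattern, edit script) are merged with their provenance unioned; pairs
    whose change cannot be expressed as a local edit are skipped with a
    logged warning.
    """
    if not reactions:
        raise ValueError("no reactions supplied")
    library = OperatorLibrary()
    n_skipped = 0
    for pair in reactions:
        if (
            heavy_atom_count(pair.reactant) < min_heavy_atoms
            or heavy_atom_count(pair.product) < min_heavy_atoms
        ):
            logger.info("%s: skipped (currency-size structure)", pair.reaction_id)
            n_skipped += 1
            continue
        directions = [pair, pair.reversed()] if both_directions else [pair]
        mined_any = False
        for directed in directions:
            try:
                for op in mine_operator(directed, max_center_size=max_center_size):
                    library.add(op)
                    mined_any = True
            except (OperatorMiningError, NoTransformationError, ValueError) as exc:
                logger.warning("skipping %s: %s", directed.reaction_id, exc)
        if not mined_any:
            n_skipped += 1
    if n_skipped:
        logger.info("operator mining skipped %d reaction(s)", n_skipped)
    if not library.operators:
        raise ValueError("no usable reactions: every pair was skipped")
    return library
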