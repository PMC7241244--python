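"""Self-contained toy models, reaction sets and synthetic feature tables.

Everything the pipeline consumes can be generated here with known ground
truth: a panel of small metabolites, six template chemistries that
instantiate correctly atom-mapped reactant→product pairs, and feature
tables with planted true masses (bounded uniform ppm noise) plus decoys
kept far away from every true mass. Noise is uniform on a bounded support
rather than Gaussian so that recall guarantees are exact: with noise bound
b and matching tolerance t > b, every planted feature must match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import Mol

from .chem_core import canonical_key, parse_structure
from .emm_builder import ExtendedModel, MetabolicModel, Metabolite, build_emm
from .mass_filter import Feature
from .operator_miner import MappedReactionPair, build_operator_library

logger = logging.getLogger(__name__)

__all__ = [
    "COMPOUND_PANEL",
    "VALIDATION_COMPOUNDS",
    "TEMPLATE_NAMES",
    "ToySpec",
    "GroundTruth",
    "make_toy_model",
    "make_feature_table",
    "hydroxyphenyllactate_provenance_reactions",
]

#: Hard-coded panel of small metabolite structures (name → SMILES).
COMPOUND_PANEL: Dict[str, str] = {
    # substrates used to build toy models
    "pyruvate": "CC(=O)C(=O)O",
    "4-hydroxyphenylpyruvate": "O=C(O)C(=O)Cc1ccc(O)cc1",
    "phenol": "Oc1ccccc1",
    "glutarate": "OC(=O)CCCC(=O)O",
    "phenylpyruvate": "O=C(O)C(=O)Cc1ccccc1",
    "acetoacetate": "CC(=O)CC(=O)O",
    "benzaldehyde": "O=Cc1ccccc1",
    "hydroquinone": "Oc1ccc(O)cc1",
    "benzoate": "O=C(O)c1ccccc1",
    "5-aminopentanoate": "NCCCCC(=O)O",
    "lactate": "CC(O)C(=O)O",
    "phenylacetate": "O=C(O)Cc1ccccc1",
    "3-hydroxyanthranilate": "Nc1cccc(O)c1C(=O)O",
    "4-hydroxybenzaldehyde": "O=Cc1ccc(O)cc1",
    # compounds that appear as predicted derivatives / validation standards
    "salicylaldehyde": "O=Cc1ccccc1O",
    "4-hydroxyphenyllactate": "OC(Cc1ccc(O)cc1)C(=O)O",
    "acetoacetamide": "CC(=O)CC(N)=O",
    "3-methoxyanthranilate": "COc1cccc(N)c1C(=O)O",
    "2-hydroxyphenylacetate": "O=C(O)Cc1ccccc1O",
    "4-pyridoxate": "Cc1ncc(CO)c(C(=O)O)c1O",
    "phenyllactate": "OC(Cc1ccccc1)C(=O)O",
}

#: The validation-standard compounds with an unambiguous printed mass
#: (name → expected two-decimal neutral monoisotopic mass).
VALIDATION_COMPOUNDS: Dict[str, float] = {
    "salicylaldehyde": 122.04,
    "4-hydroxyphenyllactate": 182.06,
    "acetoacetamide": 101.05,
    "glutarate": 132.04,
    "3-methoxyanthranilate": 167.06,
    "2-hydroxyphenylacetate": 152.05,
    "4-pyridoxate": 183.05,
}

#: Metabolites eligible for toy-model membership; the first four are always
#: included so the canonical worked examples are reproducible.
_MODEL_CORE = ("pyruvate", "4-hydroxyphenylpyruvate", "phenol", "glutarate")
_MODEL_EXTRA = (
    "phenylpyruvate",
    "acetoacetate",
    "benzaldehyde",
    "hydroquinone",
    "benzoate",
    "5-aminopentanoate",
    "lactate",
    "phenylacetate",
    "3-hydroxyanthranilate",
    "4-hydroxybenzaldehyde",
)

TEMPLATE_NAMES = (
    "ketone_reduction",
    "hydroxylation",
    "o_methylation",
    "o_acetylation",
    "amination",
    "decarboxylation",
)


@dataclass
class ToySpec:
    """Parameters of one synthetic study."""

    seed: int = 17
    n_metabolites: int = 12
    templates: Tuple[str, ...] = TEMPLATE_NAMES
    n_planted: int = 30
    n_decoys: int = 30
    ppm_noise_bound: float = 5.0  # planted features within ± this many ppm
    decoy_min_ppm: float = 50.0  # decoys at least this far from any true mass

    def __post_init__(self):
        unknown = set(self.templates) - set(TEMPLATE_NAMES)
        if unknown:
            raise ValueError(f"unknown template(s): {sorted(unknown)}")


@dataclass
class GroundTruth:
    """What the generator planted, for exact downstream checks."""

    planted: Dict[str, Tuple[str, float]] = field(default_factory=dict)
    # feature id → (true record key, signed ppm offset)
    decoy_ids: List[str] = field(default_factory=list)
    expected_operator_count: Optional[int] = None
    expected_derivative_keys: Optional[set] = None


# ---------------------------------------------------------------------------
# template chemistry: each generator returns (product, atom map) for one
# deterministically chosen site, or None when the template does not apply


def _tracked_edit(mol: Mol):
    work = Chem.RWMol(mol)
    for atom in work.GetAtoms():
        atom.SetIntProp("_src", atom.GetIdx())
    return work


def _finish(work, n_orig: int):
    product = work.GetMol()
    Chem.SanitizeMol(product)
    atom_map = {}
    for atom in product.GetAtoms():
        src = atom.GetIntProp("_src")
        if src < n_orig:
            atom_map[src] = atom.GetIdx()
        atom.ClearProp("_src")
    return product, atom_map


def _first_match(mol: Mol, smarts: str):
    patt = Chem.MolFromSmarts(smarts)
    matches = sorted(mol.GetSubstructMatches(patt))
    return matches[0] if matches else None


def _ketone_reduction(mol: Mol):
    m = _first_match(mol, "[#6][CX3](=[OX1])[#6]")
    if m is None:
        return None
    _, c_idx, o_idx, _ = m
    work = _tracked_edit(mol)
    work.GetBondBetweenAtoms(c_idx, o_idx).SetBondType(Chem.BondType.SINGLE)
    return _finish(work, mol.GetNumAtoms())


def _hydroxylation(mol: Mol):
    m = _first_match(mol, "[cH]")
    if m is None:
        return None
    (c_idx,) = m
    work = _tracked_edit(mol)
    o = work.AddAtom(Chem.Atom(8))
    work.GetAtomWithIdx(o).SetIntProp("_src", o)
    work.AddBond(c_idx, o, Chem.BondType.SINGLE)
    return _finish(work, mol.GetNumAtoms())


def _o_methylation(mol: Mol):
    m = _first_match(mol, "[OX2H;!$([OX2H]C=O)]")
    if m is None:
        return None
    (o_idx,) = m
    work = _tracked_edit(mol)
    c = work.AddAtom(Chem.Atom(6))
    work.GetAtomWithIdx(c).SetIntProp("_src", c)
    work.AddBond(o_idx, c, Chem.BondType.SINGLE)
    return _finish(work, mol.GetNumAtoms())


def _o_acetylation(mol: Mol):
    m = _first_match(mol, "[OX2H;!$([OX2H]C=O)]")
    if m is None:
        return None
    (o_idx,) = m
    work = _tracked_edit(mol)
    c1 = work.AddAtom(Chem.Atom(6))
    c2 = work.AddAtom(Chem.Atom(6))
    o2 = work.AddAtom(Chem.Atom(8))
    for idx in (c1, c2, o2):
        work.GetAtomWithIdx(idx).SetIntProp("_src", idx)
    work.AddBond(o_idx, c1, Chem.BondType.SINGLE)
    work.AddBond(c1, c2, Chem.BondType.SINGLE)
    work.AddBond(c1, o2, Chem.BondType.DOUBLE)
    return _finish(work, mol.GetNumAtoms())


def _amination(mol: Mol):
    # carboxylic acid → primary amide
    m = _first_match(mol, "[CX3](=[OX1])[OX2H]")
    if m is None:
        return None
    c_idx, _, oh_idx = m
    work = _tracked_edit(mol)
    n = work.AddAtom(Chem.Atom(7))
    work.GetAtomWithIdx(n).SetIntProp("_src", n)
    work.AddBond(c_idx, n, Chem.BondType.SINGLE)
    work.RemoveAtom(oh_idx)
    return _finish(work, mol.GetNumAtoms())


def _decarboxylation(mol: Mol):
    m = _first_match(mol, "[#6;!$([CX3]=[OX1])][CX3](=[OX1])[OX2H]")
    if m is None:
        return None
    _, c_idx, o1_idx, o2_idx = m
    if mol.GetNumHeavyAtoms() - 3 < 4:
        return None  # product would be currency-sized
    work = _tracked_edit(mol)
    for idx in sorted((c_idx, o1_idx, o2_idx), reverse=True):
        work.RemoveAtom(idx)
    return _finish(work, mol.GetNumAtoms())


_TEMPLATES = {
    "ketone_reduction": (_ketone_reduction, "1.1.1"),
    "hydroxylation": (_hydroxylation, "1.14.13"),
    "o_methylation": (_o_methylation, "2.1.1"),
    "o_acetylation": (_o_acetylation, "2.3.1"),
    "amination": (_amination, "6.3.1"),
    "decarboxylation": (_decarboxylation, "4.1.1"),
}


# ---------------------------------------------------------------------------
# generators


def make_toy_model(
    spec: ToySpec, compute_expectations: bool = True
) -> Tuple[MetabolicModel, GroundTruth]:
    """Toy metabolic model: panel metabolites + template-derived reactions.

    The first four core compounds are always present; the remainder are
    drawn without replacement under the seed. Each requested template is
    instantiated on every selected metabolite it applies to, with a correct
    atom map. Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_extra = max(0, min(spec.n_metabolites - len(_MODEL_CORE), len(_MODEL_EXTRA)))
    extra = list(rng.choice(_MODEL_EXTRA, size=n_extra, replace=False))
    names = list(_MODEL_CORE[: spec.n_metabolites]) + extra
    metabolites = [
        Metabolite.from_smiles(f"M{idx:03d}", name, COMPOUND_PANEL[name])
        for idx, name in enumerate(names, start=1)
    ]

    reactions: List[MappedReactionPair] = []
    rxn_no = 0
    for template in spec.templates:
        generator, ec_base = _TEMPLATES[template]
        applied = False
        for met in metabolites:
            result = generator(met.structure)
            if result is None:
                continue
            product, atom_map = result
            if canonical_key(product) == met.key:
                continue
            rxn_no += 1
            reactions.append(
                MappedReactionPair(
                    reaction_id=f"RX{rxn_no:03d}",
                    reactant=met.structure,
                    product=product,
                    atom_map=atom_map,
                    ec_numbers=(f"{ec_base}.{rxn_no}",),
                )
            )
            applied = True
        if not applied:
            logger.warning(
                "template %r not applicable to any selected metabolite", template
            )

    truth = GroundTruth()
    if reactions and compute_expectations:
        library = build_operator_library(reactions)
        emm = build_emm(MetabolicModel(metabolites=metabolites, reactions=reactions), library)
        truth.expected_operator_count = len(library)
        truth.expected_derivative_keys = set(emm.derivatives)
    elif not reactions:
        logger.warning("toy model has an empty reaction set")
    model = MetabolicModel(
        metabolites=metabolites, reactions=reactions, organism="toy"
    )
    return model, truth


def make_feature_table(
    emm: ExtendedModel, spec: ToySpec
) -> Tuple[List[Feature], GroundTruth]:
    """Synthetic feature table: planted features at true EMM masses with
    bounded uniform ppm noise, plus decoys far from every true mass."""
    if not emm.derivatives and not emm.model.metabolites:
        raise ValueError("extended model is empty")
    rng = np.random.default_rng(spec.seed + 1)
    records: List[Tuple[str, float]] = [
        (m.key, m.mass) for m in emm.model.metabolites
    ] + sorted((d.key, d.mass) for d in emm.derivatives.values())
    true_masses = np.array([mass for _, mass in records])

    truth = GroundTruth()
    features: List[Feature] = []
    chosen = rng.integers(0, len(records), size=spec.n_planted)
    for i, rec_idx in enumerate(chosen):
        key, mass = records[int(rec_idx)]
        offset = float(rng.uniform(-spec.ppm_noise_bound, spec.ppm_noise_bound))
        fid = f"F{i + 1:04d}"
        features.append(
            Feature(
                feature_id=fid,
                mass=mass * (1.0 + offset * 1e-6),
                rt_min=float(rng.uniform(0.5, 20.0)),
                polarity="neutralized",
            )
        )
        truth.planted[fid] = (key, offset)

    lo, hi = float(true_masses.min()) * 0.8, float(true_masses.max()) * 1.2
    made = 0
    for attempt in range(spec.n_decoys * 200):
        if made == spec.n_decoys:
            break
        candidate = float(rng.uniform(lo, hi))
        ppm_gap = np.abs(candidate - true_masses) / true_masses * 1e6
        if ppm_gap.min() < spec.decoy_min_ppm:
            continue
        made += 1
        fid = f"D{made:04d}"
        features.append(
            Feature(
                feature_id=fid,
                mass=candidate,
                rt_min=float(rng.uniform(0.5, 20.0)),
                polarity="neutralized",
            )
        )
        truth.decoy_ids.append(fid)
    if made < spec.n_decoys:
        raise ValueError(
            f"could not place {spec.n_decoys} decoys at >= {spec.decoy_min_ppm} "
            "ppm from every true mass"
        )
    return features, truth


def hydroxyphenyllactate_provenance_reactions() -> List[MappedReactionPair]:
    """Twelve aryl-pyruvate reduction reactions carrying fifteen distinct EC
    numbers in total, all expressing the same keto→carbinol edit.

    Emulates a curated reaction set in which one biotransformation pattern
    recurs across many cataloged reactions (NAD/NADP variants, paralogous
    enzymes), so the single mined operator should report 12 source
    reactions and 15 associated ECs.
    """
    substrates = {
        "phenylpyruvate": COMPOUND_PANEL["phenylpyruvate"],
        "4-hydroxyphenylpyruvate": COMPOUND_PANEL["4-hydroxyphenylpyruvate"],
    }
    ec_pool = [
        ("1.1.1.110",),
        ("1.1.1.222", "1.1.1.237"),
        ("1.1.1.28",),
        ("1.1.1.27", "1.1.1.2"),
        ("1.1.1.103",),
        ("1.1.1.4",),
        ("1.1.1.6", "1.1.1.14"),
        ("1.1.1.21",),
        ("1.1.1.37",),
        ("1.1.1.38",),
        ("1.1.1.39",),
        ("1.1.1.40",),
    ]
    assert len({ec for ecs in ec_pool for ec in ecs}) == 15
    pairs = []
    for i, ecs in enumerate(ec_pool):
        name = "phenylpyruvate" if i % 2 == 0 else "4-hydroxyphenylpyruvate"
        mol = parse_structure(substrates[name])
        product, atom_map = _ketone_reduction(mol)
        pairs.append(
            MappedReactionPair(
                reaction_id=f"R{3300 + i}",
                reactant=mol,
                product=product,
                atom_map=atom_map,
                ec_numbers=ecs,
            )
        )
    return pairs
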