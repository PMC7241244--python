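"""Operator mining: atom maps, reaction centers, signatures, libraries."""

import numpy as np
import pytest

from emmfilter.chem_core import canonical_key, monoisotopic_mass, parse_structure
from emmfilter.fixtures import (
    COMPOUND_PANEL,
    hydroxyphenyllactate_provenance_reactions,
)
from emmfilter.operator_miner import (
    MappedReactionPair,
    NoTransformationError,
    UnalignablePairError,
    build_operator_library,
    detect_reaction_center,
    extract_signature,
    infer_atom_map,
    mine_operator,
)

PYRUVATE = "CC(=O)C(=O)O"
LACTATE = "CC(O)C(=O)O"


def make_pair(reactant, product, rid="R1", ecs=("1.1.1.1",)):
    r = parse_structure(reactant)
    p = parse_structure(product)
    return MappedReactionPair(
        reaction_id=rid, reactant=r, product=p,
        atom_map=infer_atom_map(r, p), ec_numbers=ecs,
    )


class TestInferAtomMap:
    def test_pyruvate_lactate_full_mapping(self):
        r, p = parse_structure(PYRUVATE), parse_structure(LACTATE)
        amap = infer_atom_map(r, p)
        assert len(amap) == 6
        # keto carbon (bonded to CH3 and carboxyl C) maps to carbinol carbon
        keto = next(
            a.GetIdx() for a in r.GetAtoms()
            if a.GetSymbol() == "C"
            and any(b.GetBondTypeAsDouble() == 2 for b in a.GetBonds())
            and sum(n.GetSymbol() == "C" for n in a.GetNeighbors()) == 2
        )
        carbinol = amap[keto]
        pa = p.GetAtomWithIdx(carbinol)
        assert pa.GetSymbol() == "C"
        assert any(
            n.GetSymbol() == "O" and p.GetBondBetweenAtoms(carbinol, n.GetIdx()).GetBondTypeAsDouble() == 1
            for n in pa.GetNeighbors()
        )

    def test_identity_molecules_identity_sized_map(self):
        r = parse_structure(PYRUVATE)
        p = parse_structure(PYRUVATE)
        amap = infer_atom_map(r, p)
        assert len(amap) == r.GetNumAtoms()
        assert all(
            r.GetAtomWithIdx(i).GetSymbol() == p.GetAtomWithIdx(j).GetSymbol()
            for i, j in amap.items()
        )

    def test_elementwise_disjoint_pair_rejected(self):
        with pytest.raises(UnalignablePairError):
            infer_atom_map(parse_structure("C"), parse_structure("N"))


class TestReactionCenter:
    def test_ketone_reduction_center_is_the_carbonyl(self):
        pair = make_pair(PYRUVATE, LACTATE)
        center = detect_reaction_center(pair)
        keto_c = next(
            a.GetIdx() for a in pair.reactant.GetAtoms()
            if a.GetSymbol() == "C"
            and sum(n.GetSymbol() == "C" for n in a.GetNeighbors()) == 2
            and any(n.GetSymbol() == "O" for n in a.GetNeighbors())
        )
        assert keto_c in center
        # the changed carbonyl (C and its O) and nothing else
        assert len(center) <= 2
        symbols = {pair.reactant.GetAtomWithIdx(i).GetSymbol() for i in center}
        assert symbols <= {"C", "O"}

    def test_o_acetylation_center_is_the_phenolic_oxygen(self):
        pair = make_pair("Oc1ccccc1", "CC(=O)Oc1ccccc1")
        center = detect_reaction_center(pair)
        assert len(center) == 1
        (idx,) = center
        atom = pair.reactant.GetAtomWithIdx(idx)
        assert atom.GetSymbol() == "O"
        assert not atom.GetIsAromatic()

    def test_identical_sides_rejected(self):
        with pytest.raises(NoTransformationError):
            detect_reaction_center(make_pair("c1ccccc1", "c1ccccc1"))


class TestSignature:
    def test_pyruvate_keto_carbon(self):
        mol = parse_structure(PYRUVATE)
        keto_c = 1  # CC(=O)... atom order from this notation
        sig = extract_signature(mol, keto_c)
        assert sig.center == ("C", False, False, 3)
        assert sorted(sig.level1) == sorted(
            [("2", "O", False), ("1", "C", False), ("1", "C", False)]
        )
        # carboxyl oxygens sit two bonds out
        assert (("1", "2"), "O") in sig.level2
        assert (("1", "1"), "O") in sig.level2

    def test_isolated_carbon_has_empty_shells(self):
        sig = extract_signature(parse_structure("C"), 0)
        assert sig.center == ("C", False, False, 0)
        assert sig.level1 == ()
        assert sig.level2 == ()

    def test_phenolic_oxygen(self):
        mol = parse_structure("Oc1ccccc1")
        sig = extract_signature(mol, 0)
        assert sig.center == ("O", False, False, 1)
        assert sig.level1 == (("1", "C", True),)
        assert len(sig.level2) == 2
        assert all(elem == "C" for _, elem in sig.level2)

    def test_serialization_round_trip(self):
        from emmfilter.operator_miner import NeighborhoodSignature

        sig = extract_signature(parse_structure(PYRUVATE), 1)
        assert NeighborhoodSignature.from_json(sig.to_json()) == sig


class TestMineOperator:
    def test_ketone_reduction_mass_delta(self):
        ops = mine_operator(make_pair(PYRUVATE, LACTATE))
        assert len(ops) == 1
        assert ops[0].mass_delta == pytest.approx(2.0157, abs=1e-4)

    def test_o_methylation_mass_delta(self):
        ops = mine_operator(make_pair("Oc1ccccc1", "COc1ccccc1"))
        assert len(ops) == 1
        assert ops[0].mass_delta == pytest.approx(14.0157, abs=1e-4)

    def test_identity_pair_propagates_error(self):
        with pytest.raises(NoTransformationError):
            mine_operator(make_pair("CC(=O)C(=O)O", "CC(=O)C(=O)O"))

    def test_mass_delta_equals_product_minus_reactant(self, toy_model):
        model, _ = toy_model
        for pair in model.reactions:
            for directed in (pair, pair.reversed()):
                try:
                    ops = mine_operator(directed)
                except Exception:
                    continue
                total = monoisotopic_mass(directed.product) - monoisotopic_mass(
                    directed.reactant
                )
                assert sum(op.mass_delta for op in ops) == pytest.approx(
                    total, abs=1e-6
                )


class TestOperatorLibrary:
    def test_identical_environments_merge_provenance(self):
        # two different reactions expressing the same keto -> carbinol edit
        pairs = [
            make_pair(
                COMPOUND_PANEL["phenylpyruvate"],
                COMPOUND_PANEL["phenyllactate"],
                rid="RA", ecs=("1.1.1.110",),
            ),
            make_pair(
                COMPOUND_PANEL["4-hydroxyphenylpyruvate"],
                COMPOUND_PANEL["4-hydroxyphenyllactate"],
                rid="RB", ecs=("1.1.1.237",),
            ),
        ]
        library = build_operator_library(pairs, both_directions=False)
        assert len(library) == 1
        (op,) = list(library)
        assert op.n_reactions == 2
        assert op.n_ecs == 2

    def test_distinct_edits_stay_distinct(self):
        pairs = [
            make_pair(PYRUVATE, LACTATE, rid="R1"),
            make_pair("Oc1ccccc1", "COc1ccccc1", rid="R2"),
            make_pair("Oc1ccccc1", "CC(=O)Oc1ccccc1", rid="R3"),
            make_pair("Oc1ccc(O)cc1", "COc1ccc(O)cc1", rid="R4"),
            make_pair(
                COMPOUND_PANEL["phenylpyruvate"],
                COMPOUND_PANEL["phenyllactate"],
                rid="R5",
            ),
        ]
        library = build_operator_library(pairs, both_directions=False)
        # brute-force count of distinct (pattern, edits) among mined operators
        import json

        mined = [op for p in pairs for op in mine_operator(p)]
        distinct = {
            (op.pattern, json.dumps(list(op.edits), sort_keys=True)) for op in mined
        }
        assert len(library) == len(distinct)

    def test_dedupe_idempotence(self, toy_model):
        model, _ = toy_model
        once = build_operator_library(model.reactions)
        twice = build_operator_library(list(model.reactions) * 2)
        assert set(once.operators) == set(twice.operators)
        for oid in once.operators:
            assert (
                once.operators[oid].provenance == twice.operators[oid].provenance
            )

    def test_determinism_under_input_shuffle(self, toy_model):
        model, _ = toy_model
        rng = np.random.default_rng(3)
        shuffled = list(model.reactions)
        rng.shuffle(shuffled)
        a = build_operator_library(model.reactions)
        b = build_operator_library(shuffled)
        assert set(a.operators) == set(b.operators)
        assert all(
            a.operators[k].provenance == b.operators[k].provenance
            for k in a.operators
        )

    def test_currency_sized_pairs_excluded(self):
        small = make_pair("CC(=O)O", "CC(=O)N", rid="Rsmall")  # 4 vs 4 heavy
        tiny = make_pair("CO", "CN", rid="Rtiny")  # 2 vs 2 heavy
        library = build_operator_library([small, tiny], both_directions=False)
        rids = {rid for op in library for rid, _ in op.provenance}
        assert rids == {"Rsmall"}
        with pytest.raises(ValueError):
            build_operator_library([tiny], both_directions=False)

    def test_provenance_counts_for_recurrent_reduction(self):
        """Twelve same-pattern reduction reactions with fifteen ECs collapse
        to one forward operator reporting 12 reactions and 15 enzymes."""
        pairs = hydroxyphenyllactate_provenance_reactions()
        assert len(pairs) == 12
        library = build_operator_library(pairs)
        forward = [op for op in library if op.mass_delta > 0]
        assert len(forward) == 1
        assert forward[0].n_reactions == 12
        assert forward[0].n_ecs == 15

    def test_json_round_trip(self, toy_library):
        from emmfilter.operator_miner import OperatorLibrary

        data = toy_library.to_json()
        back = OperatorLibrary.from_json(data)
        assert set(back.operators) == set(toy_library.operators)
        assert back.to_json() == data
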