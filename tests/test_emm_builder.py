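"""EMM construction: site matching, operator application, model expansion."""

import numpy as np
import pytest

from emmfilter.chem_core import canonical_key, monoisotopic_mass, parse_structure
from emmfilter.emm_builder import (
    InvalidDerivativeError,
    MetabolicModel,
    Metabolite,
    apply_operator,
    build_emm,
    match_sites,
    merge_models,
    count_unique_masses,
)
from emmfilter.fixtures import COMPOUND_PANEL, ToySpec, make_toy_model
from emmfilter.operator_miner import (
    OperatorLibrary,
    build_operator_library,
    extract_signature,
    infer_atom_map,
    MappedReactionPair,
    mine_operator,
)


def pair_from(reactant, product, rid="R1", ecs=("1.1.1.1",)):
    r, p = parse_structure(reactant), parse_structure(product)
    return MappedReactionPair(rid, r, p, infer_atom_map(r, p), ecs)


@pytest.fixture(scope="module")
def reduction_op():
    """Keto→carbinol operator mined from an aryl-pyruvate reduction."""
    (op,) = mine_operator(
        pair_from(COMPOUND_PANEL["phenylpyruvate"], COMPOUND_PANEL["phenyllactate"])
    )
    return op


@pytest.fixture(scope="module")
def methylation_op():
    (op,) = mine_operator(pair_from("Oc1ccccc1", "COc1ccccc1"))
    return op


class TestMatchSites:
    def test_reduction_matches_only_the_keto_carbon(self, reduction_op):
        hpp = parse_structure(COMPOUND_PANEL["4-hydroxyphenylpyruvate"])
        sites = match_sites(hpp, reduction_op)
        assert len(sites) == 1
        assert extract_signature(hpp, sites[0]) == reduction_op.pattern
        assert hpp.GetAtomWithIdx(sites[0]).GetSymbol() == "C"

    def test_no_sites_on_benzene(self, reduction_op):
        assert match_sites(parse_structure("c1ccccc1"), reduction_op) == []

    def test_symmetric_phenolic_oxygens_give_two_sites(self, methylation_op):
        hq = parse_structure("Oc1ccc(O)cc1")
        sites = match_sites(hq, methylation_op)
        assert len(sites) == 2
        products = {
            canonical_key(apply_operator(hq, methylation_op, s)) for s in sites
        }
        # symmetry: both sites give 4-methoxyphenol
        assert products == {canonical_key(parse_structure("COc1ccc(O)cc1"))}


class TestApplyOperator:
    def test_hydroxyphenylpyruvate_to_hydroxyphenyllactate(self, reduction_op):
        hpp = parse_structure(COMPOUND_PANEL["4-hydroxyphenylpyruvate"])
        (site,) = match_sites(hpp, reduction_op)
        product = apply_operator(hpp, reduction_op, site)
        assert canonical_key(product) == canonical_key(
            parse_structure(COMPOUND_PANEL["4-hydroxyphenyllactate"])
        )
        assert monoisotopic_mass(product) == pytest.approx(182.0579, abs=1e-4)

    def test_round_trip_on_source_pair(self):
        pair = pair_from("CC(=O)C(=O)O", "CC(O)C(=O)O")
        (op,) = mine_operator(pair)
        assert any(
            canonical_key(apply_operator(pair.reactant, op, s))
            == canonical_key(pair.product)
            for s in match_sites(pair.reactant, op)
        )

    def test_mass_delta_is_respected(self, reduction_op):
        sub = parse_structure(COMPOUND_PANEL["pyruvate"])
        for site in match_sites(sub, reduction_op):
            product = apply_operator(sub, reduction_op, site)
            assert monoisotopic_mass(product) == pytest.approx(
                monoisotopic_mass(sub) + reduction_op.mass_delta, abs=1e-6
            )


def brute_force_derivatives(model, library):
    """Independent enumerator: every (metabolite, operator, atom) triple."""
    keys = set()
    for met in model.metabolites:
        for op in library:
            for atom in range(met.structure.GetNumAtoms()):
                if extract_signature(met.structure, atom) != op.pattern:
                    continue
                try:
                    product = apply_operator(met.structure, op, atom)
                except InvalidDerivativeError:
                    continue
                key = canonical_key(product)
                if key not in model.keys:
                    keys.add(key)
    return keys


class TestBuildEmm:
    def test_matches_brute_force_enumeration(self):
        for seed in range(5):
            spec = ToySpec(seed=seed, n_metabolites=8)
            model, _ = make_toy_model(spec, compute_expectations=False)
            full = build_operator_library(model.reactions)
            ops = sorted(full, key=lambda o: o.operator_id)[:5]
            library = OperatorLibrary()
            for op in ops:
                library.add(op)
            emm = build_emm(model, library)
            assert set(emm.derivatives) == brute_force_derivatives(model, library)

    def test_model_products_are_excluded(self, reduction_op):
        # model already contains the only possible product
        mets = [
            Metabolite.from_smiles("M1", "pp", COMPOUND_PANEL["phenylpyruvate"]),
            Metabolite.from_smiles("M2", "pl", COMPOUND_PANEL["phenyllactate"]),
        ]
        library = OperatorLibrary()
        library.add(reduction_op)
        emm = build_emm(MetabolicModel(metabolites=mets), library)
        assert emm.derivatives == {}

    def test_exclusion_invariant(self, toy_emm):
        assert set(toy_emm.derivatives) & toy_emm.model.keys == set()

    def test_mass_conservation(self, toy_emm):
        parents = {m.metabolite_id: m.mass for m in toy_emm.model.metabolites}
        deltas = {
            op.operator_id: op.mass_delta for op in toy_emm.library
        }
        for record in toy_emm.derivatives.values():
            best = min(
                abs(record.mass - (parents[p] + deltas[o]))
                for p in record.parent_ids
                for o in record.operator_ids
            )
            assert best < 1e-6

    def test_adding_an_operator_never_shrinks_the_emm(self, toy_model, toy_library):
        model, _ = toy_model
        ops = sorted(toy_library, key=lambda o: o.operator_id)
        partial = OperatorLibrary()
        previous = 0
        for op in ops[:8]:
            partial.add(op)
            count = len(build_emm(model, partial).derivatives)
            assert count >= previous
            previous = count

    def test_statistics_deterministic_under_shuffle(self, toy_model, toy_library):
        model, _ = toy_model
        rng = np.random.default_rng(11)
        mets = list(model.metabolites)
        rng.shuffle(mets)
        shuffled = MetabolicModel(metabolites=mets, reactions=model.reactions)
        a = build_emm(model, toy_library).statistics()
        b = build_emm(shuffled, toy_library).statistics()
        assert a == b

    def test_deeper_application_is_monotone(self, toy_model, toy_library):
        model, _ = toy_model
        d1 = len(build_emm(model, toy_library, depth=1).derivatives)
        d2 = len(build_emm(model, toy_library, depth=2).derivatives)
        assert d2 >= d1

    def test_statistics_fold_changes_recompute(self, toy_emm):
        stats = toy_emm.statistics()
        assert stats["metabolite_fold_change"] == pytest.approx(
            round(stats["unique_derivatives"] / stats["model_metabolites"], 2)
        )
        assert stats["mass_fold_change"] == pytest.approx(
            round(
                stats["unique_derivative_masses"] / stats["model_unique_masses"], 2
            )
        )
        assert stats["unique_derivative_masses"] <= stats["unique_derivatives"]


class TestUniqueMassGrouping:
    def test_groups_within_tolerance(self):
        assert count_unique_masses([100.0, 100.00005, 100.001, 200.0]) == 3

    def test_empty(self):
        assert count_unique_masses([]) == 0


class TestMergeModels:
    def test_self_merge_is_identity(self, toy_model):
        model, _ = toy_model
        merged = merge_models([model, model])
        assert merged.keys == model.keys
        assert len(merged.reactions) == len(model.reactions)

    def test_disjoint_union(self):
        m1 = MetabolicModel(
            metabolites=[
                Metabolite.from_smiles("A1", "pyruvate", "CC(=O)C(=O)O"),
                Metabolite.from_smiles("A2", "phenol", "Oc1ccccc1"),
            ]
        )
        m2 = MetabolicModel(
            metabolites=[
                Metabolite.from_smiles("B1", "lactate", "CC(O)C(=O)O"),
                Metabolite.from_smiles("B2", "benzoate", "O=C(O)c1ccccc1"),
            ]
        )
        assert len(merge_models([m1, m2]).metabolites) == 4

    def test_same_structure_two_ids_collapses_with_synonym(self):
        m1 = MetabolicModel(
            metabolites=[Metabolite.from_smiles("X1", "ethanol", "CCO")]
        )
        m2 = MetabolicModel(
            metabolites=[Metabolite.from_smiles("X2", "ethyl alcohol", "OCC")]
        )
        merged = merge_models([m1, m2])
        assert len(merged.metabolites) == 1
        assert "X2" in merged.metabolites[0].name

    def test_conflicting_reaction_ids_rejected(self):
        p1 = pair_from("CC(=O)C(=O)O", "CC(O)C(=O)O", rid="R1")
        p2 = pair_from("Oc1ccccc1", "COc1ccccc1", rid="R1")
        m1 = MetabolicModel(
            metabolites=[Metabolite.from_smiles("A", "a", "CC(=O)C(=O)O")],
            reactions=[p1],
        )
        m2 = MetabolicModel(
            metabolites=[Metabolite.from_smiles("B", "b", "Oc1ccccc1")],
            reactions=[p2],
        )
        with pytest.raises(ValueError, match="R1"):
            merge_models([m1, m2])
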