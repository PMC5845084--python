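import random

import pytest

from oracles import brute_force_min_changes, graphs_isomorphic
from conftest import pipeline_template

from rxntemplater.chem import Molecule
from rxntemplater.io import ReactionRecord
from rxntemplater.mapping import (
    AtomMap,
    all_sites,
    complete_symmetric_gap,
    compute_mapping,
    count_changed_atoms,
    select_resonance_combination,
    validate_mapping,
)


class TestComputeMapping:
    def test_methane_abstraction_matches_brute_force(self, abstraction_record):
        rec = abstraction_record
        amap = compute_mapping(rec)
        assert validate_mapping(rec, amap).state == "complete"
        got = count_changed_atoms(rec.reactants, rec.products, amap)
        oracle_min, _ = brute_force_min_changes(rec)
        assert got == oracle_min == 3
        # exactly one methane H ends up in H2
        h2_mi = next(
            i for i, m in enumerate(rec.products) if len(m) == 2
        )
        methane_h = [
            s for s in amap.pairs
            if s[0] == 0 and rec.reactants[0].atoms[s[1]].element == "H"
        ]
        into_h2 = [s for s in methane_h if amap.pairs[s][0] == h2_mi]
        assert len(into_h2) == 1

    def test_identity_reaction(self):
        rec = ReactionRecord(
            [Molecule.from_smiles("CCO")], [Molecule.from_smiles("CCO")], None, "id", "x"
        )
        amap = compute_mapping(rec)
        assert validate_mapping(rec, amap).state == "complete"
        assert count_changed_atoms(rec.reactants, rec.products, amap) == 0

    def test_fig6_diels_alder_six_carbons(self):
        rec = ReactionRecord(
            [Molecule.from_smiles("C=CC"), Molecule.from_smiles("C=C(C)C=C")],
            [Molecule.from_smiles("CC1CCC(C)=CC1")],
            None,
            "fig6",
            "x",
        )
        amap = compute_mapping(rec)
        assert validate_mapping(rec, amap).state == "complete"
        from rxntemplater.extraction import detect_changes

        changes = detect_changes(rec, amap)
        assert len(changes.reactive_atoms) == 6
        assert all(
            rec.reactants[mi].atoms[ai].element == "C"
            for mi, ai in changes.reactive_atoms
        )

    def test_plugin_failure_yields_empty_map(self, abstraction_record):
        def broken(record):
            raise RuntimeError("boom")

        amap = compute_mapping(abstraction_record, broken)
        assert len(amap) == 0
        assert validate_mapping(abstraction_record, amap).state == "failed"

    def test_optimality_on_random_small_reactions(self):
        from rxntemplater.testgen import generate_synthetic_corpus

        corpus = generate_synthetic_corpus(
            {"h_abstraction": 1, "beta_scission": 1, "recombination": 1, "addition": 1},
            12,
            seed=5,
            small=True,
        )
        for rec in corpus.records:
            stripped = ReactionRecord(
                rec.reactants, rec.products, None, rec.source_id, "x"
            )
            amap = compute_mapping(stripped)
            assert validate_mapping(stripped, amap).state == "complete"
            got = count_changed_atoms(stripped.reactants, stripped.products, amap)
            oracle_min, _ = brute_force_min_changes(stripped)
            assert got == oracle_min, rec.source_id


class TestValidateMapping:
    def test_complete(self, abstraction_record):
        amap = compute_mapping(abstraction_record)
        assert validate_mapping(abstraction_record, amap).state == "complete"

    def test_missing_pair_incomplete(self, abstraction_record):
        amap = compute_mapping(abstraction_record)
        r = next(iter(amap.pairs))
        del amap.pairs[r]
        assert validate_mapping(abstraction_record, amap).state == "incomplete"

    def test_element_mismatch_failed(self, abstraction_record):
        rec = abstraction_record
        amap = AtomMap()
        c_site = next(
            s for s in all_sites(rec.reactants)
            if rec.reactants[s[0]].atoms[s[1]].element == "C"
        )
        h_site = next(
            s for s in all_sites(rec.products)
            if rec.products[s[0]].atoms[s[1]].element == "H"
        )
        amap.add(c_site, h_site)
        status = validate_mapping(rec, amap)
        assert status.state == "failed"
        assert "mismatch" in status.detail


class TestResonanceSelection:
    def test_butenyl_dimerization_prefers_primary_radicals(self):
        # two secondary butenyl radicals recombine into octa-2,6-diene:
        # only the primary-primary combination explains the product cheaply
        butenyl = "C=C[CH]C"
        rec = ReactionRecord(
            [Molecule.from_smiles(butenyl), Molecule.from_smiles(butenyl)],
            [Molecule.from_smiles("CC=CCCC=CC")],
            None,
            "dimer",
            "x",
        )
        variant, amap = select_resonance_combination(rec)
        assert validate_mapping(variant, amap).state == "complete"
        for mol in variant.reactants:
            rad = next(a for a in mol.atoms if a.unpaired_electrons)
            n_h = sum(1 for n in mol.neighbors(rad.index) if mol.atoms[n].element == "H")
            assert n_h == 2  # primary carbon radical

    def test_no_resonance_equals_compute_mapping(self, abstraction_record):
        variant, amap = select_resonance_combination(abstraction_record)
        direct = compute_mapping(abstraction_record)
        assert amap.pairs == direct.pairs

    def test_allyl_plus_h_deterministic_tie(self):
        rec = ReactionRecord(
            [Molecule.from_smiles("[CH2]C=C"), Molecule.from_smiles("[H]")],
            [Molecule.from_smiles("C=CC")],
            None,
            "allyl",
            "x",
        )
        v1, m1 = select_resonance_combination(rec)
        v2, m2 = select_resonance_combination(rec)
        assert m1.pairs == m2.pairs
        assert [a.state_signature() for a in v1.reactants] == [
            a.state_signature() for a in v2.reactants
        ]
        # the H radical and the carbon it lands on change
        assert count_changed_atoms(v1.reactants, v1.products, m1) == 2


def _strip_two_carbons(rec):
    amap = compute_mapping(rec)
    partial = amap.copy()
    for s in list(partial.pairs):
        if rec.reactants[s[0]].atoms[s[1]].element == "C":
            del partial.pairs[s]
    return partial


class TestSymmetricCompletion:
    def test_methyl_recombination_completed(self):
        rec = ReactionRecord(
            [Molecule.from_smiles("[CH3]"), Molecule.from_smiles("[CH3]")],
            [Molecule.from_smiles("CC")],
            None,
            "recomb",
            "x",
        )
        partial = _strip_two_carbons(rec)
        completed, status = complete_symmetric_gap(rec, partial)
        assert status.state == "heuristically_completed"
        assert validate_mapping(rec, completed).state == "complete"
        # never alters existing pairs
        assert all(completed.pairs[k] == v for k, v in partial.pairs.items())

    def test_completion_reproduces_direct_template(self):
        # the retained-neighbor rule must pick the completion whose template
        # is the one the fully computed mapping would have produced
        rec = ReactionRecord(
            [Molecule.from_smiles("[CH3]"), Molecule.from_smiles("[CH3]")],
            [Molecule.from_smiles("CC")],
            None,
            "recomb",
            "x",
        )
        direct = pipeline_template(rec)
        partial = _strip_two_carbons(rec)
        completed, status = complete_symmetric_gap(rec, partial)
        assert status.state == "heuristically_completed"
        assert pipeline_template(rec, completed).key() == direct.key()

    def test_fully_mapped_returned_unchanged(self, abstraction_record):
        amap = compute_mapping(abstraction_record)
        out, status = complete_symmetric_gap(abstraction_record, amap)
        assert status.state == "complete"
        assert out.pairs == amap.pairs

    def test_three_unmapped_not_completed(self):
        rec = ReactionRecord(
            [Molecule.from_smiles("[CH3]"), Molecule.from_smiles("[CH3]"), Molecule.from_smiles("[H]")],
            [Molecule.from_smiles("CC"), Molecule.from_smiles("[H]")],
            None,
            "three",
            "x",
        )
        amap = compute_mapping(rec)
        partial = amap.copy()
        removed = 0
        for s in list(partial.pairs):
            if rec.reactants[s[0]].atoms[s[1]].element == "C" and removed < 2:
                del partial.pairs[s]
                removed += 1
        lone_h = next(
            s for s in partial.pairs
            if rec.reactants[s[0]].atoms[s[1]].element == "H" and s[0] == 2
        )
        del partial.pairs[lone_h]
        out, status = complete_symmetric_gap(rec, partial)
        assert status.state == "incomplete"
        assert out.pairs == partial.pairs

    def test_no_atoms_mapped_fails(self, abstraction_record):
        out, status = complete_symmetric_gap(abstraction_record, AtomMap())
        assert status.state == "failed"

    def test_asymmetric_gap_not_completed(self):
        # two unmapped carbons in clearly different surroundings on both sides
        rec = ReactionRecord(
            [Molecule.from_smiles("CCO"), Molecule.from_smiles("C")],
            [Molecule.from_smiles("CCO"), Molecule.from_smiles("C")],
            None,
            "asym",
            "x",
        )
        amap = compute_mapping(rec)
        partial = amap.copy()
        # drop the methane carbon and the CH2 carbon: not symmetric
        targets = []
        for s in list(partial.pairs):
            mol = rec.reactants[s[0]]
            a = mol.atoms[s[1]]
            if a.element != "C":
                continue
            if s[0] == 1 or any(mol.atoms[n].element == "O" for n in mol.neighbors(s[1])):
                targets.append(s)
        for s in targets[:2]:
            del partial.pairs[s]
        out, status = complete_symmetric_gap(rec, partial)
        assert status.state == "incomplete"
        assert out.pairs == partial.pairs


class TestPremappedBypass:
    def test_identical_template_premapped_vs_computed(self):
        from rxntemplater.testgen import generate_reaction

        rec = generate_reaction("h_abstraction", random.Random(2), source_id="x_h_abstraction")
        tpl_pre = pipeline_template(rec, rec.mapping)
        stripped = ReactionRecord(rec.reactants, rec.products, None, "y", "x")
        tpl_mapped = pipeline_template(stripped)
        assert tpl_pre.key() == tpl_mapped.key()
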