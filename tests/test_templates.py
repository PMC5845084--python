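import random

import pytest
from rdkit import Chem

from conftest import pipeline_template

from rxntemplater.chem import Molecule, canonical_key
from rxntemplater.io import Corpus, ReactionRecord
from rxntemplater.templates import (
    Constraint,
    FragmentAtom,
    _atom_token,
    apply_template,
    classify_template,
    deduplicate_and_count,
    fragment_smarts,
    generate_constraints,
    is_reverse_pair,
    template_equals,
    templates_from_yaml,
    templates_to_yaml,
)
from rxntemplater.testgen import generate_reaction, generate_synthetic_corpus


def _abstraction(donor_smiles, radical_smiles, prod_smiles, h2_like, source_id):
    return ReactionRecord(
        [Molecule.from_smiles(donor_smiles), Molecule.from_smiles(radical_smiles)],
        [Molecule.from_smiles(prod_smiles), Molecule.from_smiles(h2_like)],
        None,
        source_id,
        "x",
    )


class TestTemplateEquals:
    def test_same_family_different_reactions_equal(self):
        a = pipeline_template(_abstraction("C", "[H]", "[CH3]", "[H][H]", "a"))
        b = pipeline_template(_abstraction("CC", "[H]", "C[CH2]", "[H][H]", "b"))
        assert template_equals(a, b)
        assert a.key() == b.key()

    def test_different_abstractor_not_equal(self):
        by_h = pipeline_template(_abstraction("C", "[H]", "[CH3]", "[H][H]", "a"))
        by_c = pipeline_template(_abstraction("C", "C[CH2]", "[CH3]", "CC", "b"))
        assert not template_equals(by_h, by_c)
        assert by_h.key() != by_c.key()

    def test_reflexive(self, abstraction_record):
        tpl = pipeline_template(abstraction_record)
        assert template_equals(tpl, tpl)

    def test_equivalence_on_sample(self):
        corpus = generate_synthetic_corpus(
            {"h_abstraction": 1, "beta_scission": 1}, 10, seed=2
        )
        tpls = [pipeline_template(r, r.mapping) for r in corpus.records]
        for a in tpls:
            for b in tpls:
                assert template_equals(a, b) == template_equals(b, a)
                assert template_equals(a, b) == (a.key() == b.key())


class TestDeduplication:
    def test_one_family_one_row(self):
        stream = [
            pipeline_template(r, r.mapping)
            for r in generate_synthetic_corpus({"recombination": 1}, 10, seed=9).records
        ]
        # several distinct radical pairs appear, but identical reactions collapse
        table = deduplicate_and_count(stream)
        assert sum(t.count for t in table) == 10
        assert len(table) < 10

    def test_ten_identical_reactions(self):
        stream = []
        for i in range(10):
            rec = _abstraction("C", "[H]", "[CH3]", "[H][H]", f"r{i}")
            stream.append(pipeline_template(rec))
        table = deduplicate_and_count(stream)
        assert len(table) == 1
        assert table[0].count == 10
        assert len(table[0].source_ids) == 10

    def test_empty_stream(self):
        assert deduplicate_and_count([]) == []

    def test_order_independence(self):
        corpus = generate_synthetic_corpus(
            {"h_abstraction": 1, "addition": 1, "beta_scission": 1}, 15, seed=4
        )
        stream = [pipeline_template(r, r.mapping) for r in corpus.records]
        t1 = deduplicate_and_count(stream)
        rng = random.Random(0)
        shuffled = stream[:]
        rng.shuffle(shuffled)
        t2 = deduplicate_and_count(shuffled)
        assert [(t.key(), t.count) for t in t1] == [(t.key(), t.count) for t in t2]

    def test_reverse_pair_linked(self):
        bs = generate_reaction("beta_scission", random.Random(0), small=True, source_id="a_beta_scission")
        # reverse reaction: products and reactants swapped, mapping inverted
        from rxntemplater.mapping import AtomMap

        rev = ReactionRecord(
            bs.products, bs.reactants, AtomMap(dict(bs.mapping.inverse)), "b_addition", "x"
        )
        table = deduplicate_and_count(
            [pipeline_template(bs, bs.mapping), pipeline_template(rev, rev.mapping)]
        )
        assert len(table) == 2
        assert table[0].reverse_of == table[1].template_id
        assert table[1].reverse_of == table[0].template_id


class TestReversePairs:
    def test_beta_scission_vs_addition(self):
        bs = generate_reaction("beta_scission", random.Random(1), small=True, source_id="x_beta_scission")
        from rxntemplater.mapping import AtomMap

        rev = ReactionRecord(
            bs.products, bs.reactants, AtomMap(dict(bs.mapping.inverse)), "y_addition", "x"
        )
        a = pipeline_template(bs, bs.mapping)
        b = pipeline_template(rev, rev.mapping)
        assert is_reverse_pair(a, b)
        assert is_reverse_pair(b, a)

    def test_self_inverse_h_transfer(self):
        # CH4 + C2H5. and its reverse C2H6 + CH3. share one template; after
        # deduplication that template is its own reverse
        fwd = _abstraction("C", "C[CH2]", "[CH3]", "CC", "fwd")
        rev = _abstraction("CC", "[CH3]", "C[CH2]", "C", "rev")
        table = deduplicate_and_count([pipeline_template(fwd), pipeline_template(rev)])
        assert len(table) == 1
        assert table[0].reverse_of == table[0].template_id
        assert is_reverse_pair(table[0], table[0])

    def test_documented_false_positive_12_vs_14_shift(self):
        # 1-2 H shift in 1-pentyl vs 1-4 H shift in 2-pentyl: species-level
        # reverse check flags them as reverse although the centers differ
        from rxntemplater.chem import Atom, Bond
        from rxntemplater.testgen import _first_h, _realize, _saturate

        def pentyl(radical_at):
            mol = Molecule()
            chain = []
            for i in range(5):
                chain.append(mol.add_atom(Atom("C")))
                if i:
                    mol.add_bond(Bond(chain[i - 1], chain[i], 1))
            mol.atoms[chain[radical_at]].unpaired_electrons = 1
            _saturate(mol)
            return mol, chain

        m1, c1 = pentyl(0)  # 1-pentyl
        h1 = _first_h(m1, c1[1])
        p1, map1 = _realize(
            [m1],
            [
                ("break", (0, c1[1]), (0, h1)),
                ("form", (0, c1[0]), (0, h1), 1),
                ("radical", (0, c1[0]), -1),
                ("radical", (0, c1[1]), +1),
            ],
        )
        shift12 = ReactionRecord([m1], p1, map1, "shift12", "x")

        m2, c2 = pentyl(1)  # 2-pentyl
        h2 = _first_h(m2, c2[4])
        p2, map2 = _realize(
            [m2],
            [
                ("break", (0, c2[4]), (0, h2)),
                ("form", (0, c2[1]), (0, h2), 1),
                ("radical", (0, c2[1]), -1),
                ("radical", (0, c2[4]), +1),
            ],
        )
        shift14 = ReactionRecord([m2], p2, map2, "shift14", "x")

        a = pipeline_template(shift12, map1)
        b = pipeline_template(shift14, map2)
        assert not template_equals(a, b)  # different centers
        assert is_reverse_pair(a, b)  # the documented false positive


class TestSmarts:
    def test_atom_tokens(self):
        assert _atom_token(FragmentAtom("C", 0, 0, 3, 4, "reactive")) == "[CX3v4]"
        assert _atom_token(FragmentAtom("C", 0, 1, 3, 3, "reactive")) == "[CX3v3]"
        assert _atom_token(FragmentAtom("O", -1, 0, 1, 1, "reactive")) == "[OX1v1-]"
        assert _atom_token(FragmentAtom("C", 0, 0, 3, 4, "reactive", aromatic=True)) == "[cX3v4]"

    def test_patterns_are_valid_smarts(self):
        corpus = generate_synthetic_corpus(
            {f: 1 for f in ("h_abstraction", "diels_alder", "hoo_elimination", "substitution")},
            12,
            seed=8,
        )
        for rec in corpus.records:
            tpl = pipeline_template(rec, rec.mapping)
            for pat in tpl.center_smarts + [s for frag in tpl.atom_smarts for s in frag]:
                assert Chem.MolFromSmarts(pat) is not None, pat

    def test_self_match_at_center_atoms(self, abstraction_record):
        from rxntemplater.extraction import build_reactive_center, detect_changes
        from rxntemplater.mapping import compute_mapping

        rec = abstraction_record
        amap = compute_mapping(rec)
        changes = detect_changes(rec, amap)
        center = build_reactive_center(rec, changes)
        tpl = pipeline_template(rec, amap)
        by_mol = {}
        for mi, ai in center.atoms:
            by_mol.setdefault(mi, set()).add(ai)
        matched_any = set()
        for pat in tpl.center_smarts:
            q = Chem.MolFromSmarts(pat)
            for mi, members in by_mol.items():
                target = rec.reactants[mi].to_rdkit()
                matches = {frozenset(m) for m in target.GetSubstructMatches(q)}
                if frozenset(members) in matches:
                    matched_any.add(mi)
        assert matched_any == set(by_mol)

    def test_atom_first_patterns_match_same_sets(self):
        tpl = pipeline_template(
            _abstraction("CC", "[H]", "C[CH2]", "[H][H]", "af")
        )
        mol = Molecule.from_smiles("CC").to_rdkit()
        for fi, frag_pats in enumerate(tpl.atom_smarts):
            sets = []
            for k, pat in enumerate(frag_pats):
                q = Chem.MolFromSmarts(pat)
                assert q is not None
                sets.append({frozenset(m) for m in mol.GetSubstructMatches(q)})
            # every per-atom pattern describes the same fragment
            assert all(s == sets[0] for s in sets)

    def test_single_atom_center_pattern(self):
        tpl = pipeline_template(
            ReactionRecord(
                [Molecule.from_smiles("[CH3]"), Molecule.from_smiles("[CH3]")],
                [Molecule.from_smiles("CC")],
                None,
                "r",
                "x",
            )
        )
        for frag, pats in zip(tpl.fragments, tpl.atom_smarts):
            if len(frag.atoms) == 1:
                assert pats == [tpl.center_smarts[tpl.atom_smarts.index(pats)]]

    def test_fig6_six_atom_first_patterns(self):
        rec = ReactionRecord(
            [Molecule.from_smiles("C=CC"), Molecule.from_smiles("C=C(C)C=C")],
            [Molecule.from_smiles("CC1CCC(C)=CC1")],
            None,
            "fig6",
            "x",
        )
        tpl = pipeline_template(rec)
        assert sum(len(p) for p in tpl.atom_smarts) == 6


class TestConstraints:
    def test_global_max_heavy(self):
        corpus = Corpus(
            [
                ReactionRecord(
                    [Molecule.from_smiles("CCCCCC")],
                    [Molecule.from_smiles("CCCCCC")],
                    None,
                    "big",
                    "x",
                )
            ]
        )
        tpl = pipeline_template(_abstraction("C", "[H]", "[CH3]", "[H][H]", "a"))
        cons = generate_constraints(corpus, tpl)
        glob = next(c for c in cons if c.scope == "global")
        assert glob.kind == "max_heavy_atoms" and glob.value == 6

    def test_per_reactant_single_electrons(self, abstraction_record):
        tpl = pipeline_template(abstraction_record)
        cons = generate_constraints(Corpus([abstraction_record]), tpl)
        per = sorted(
            (c.value for c in cons if c.scope == "per_reactant")
        )
        assert per == [0, 1]  # closed-shell methane, monoradical H

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            Constraint("global", "max_heavy_atoms", -1)


class TestApplyTemplate:
    def test_abstraction_regenerates_products(self, abstraction_record):
        tpl = pipeline_template(abstraction_record)
        results = apply_template(tpl, abstraction_record.reactants, check_constraints=False)
        expected = tuple(
            sorted(canonical_key(m).key for m in abstraction_record.products)
        )
        assert any(
            tuple(sorted(canonical_key(m).key for m in prods)) == expected
            for prods in results
        )

    def test_constraint_violation_rejected(self, abstraction_record):
        tpl = pipeline_template(abstraction_record)
        tpl.constraints = [Constraint("global", "max_heavy_atoms", 0)]
        assert apply_template(tpl, abstraction_record.reactants) == []

    def test_diels_alder_butadiene_ethene(self, diels_alder_record):
        tpl = pipeline_template(diels_alder_record)
        results = apply_template(tpl, diels_alder_record.reactants, check_constraints=False)
        cyclohexene = canonical_key(Molecule.from_smiles("C1=CCCCC1")).key
        assert any(
            len(prods) == 1 and canonical_key(prods[0]).key == cyclohexene
            for prods in results
        )

    def test_no_embedding_empty(self, abstraction_record):
        tpl = pipeline_template(abstraction_record)
        # water + water offers no C-H to abstract
        out = apply_template(
            tpl,
            [Molecule.from_smiles("O"), Molecule.from_smiles("O")],
            check_constraints=False,
        )
        assert out == []


class TestClassification:
    def test_examples(self):
        cases = {
            "h_abstraction": "hydrogen_abstraction",
            "h_shift": "hydrogen_shift",
            "beta_scission": "beta_scission",
            "addition": "addition",
            "recombination": "recombination",
            "substitution": "substitution",
            "diels_alder": "addition/cycloaddition",
            "hoo_elimination": "other/peroxide_elimination",
        }
        for family, prefix in cases.items():
            rec = generate_reaction(family, random.Random(3), source_id=f"c_{family}")
            tpl = pipeline_template(rec, rec.mapping)
            assert classify_template(tpl).startswith(prefix), family

    def test_carbon_centered_abstraction_label(self):
        rec = _abstraction("C", "C[CH2]", "[CH3]", "CC", "cc")
        tpl = pipeline_template(rec)
        assert classify_template(tpl) == "hydrogen_abstraction/carbon_centered/from_carbon"

    def test_empty_recipe_identical(self):
        from rxntemplater.templates import ReactionTemplate

        assert classify_template(ReactionTemplate([], [])) == "identical"


class TestYamlRoundTrip:
    def test_serialization_preserves_application(self, abstraction_record):
        tpl = pipeline_template(abstraction_record)
        tpl.template_id = "T0000"
        text = templates_to_yaml([tpl])
        back = templates_from_yaml(text)[0]
        r1 = apply_template(tpl, abstraction_record.reactants, check_constraints=False)
        r2 = apply_template(back, abstraction_record.reactants, check_constraints=False)
        k1 = {tuple(sorted(canonical_key(m).key for m in p)) for p in r1}
        k2 = {tuple(sorted(canonical_key(m).key for m in p)) for p in r2}
        assert k1 == k2

    def test_kinetics_placeholder_present(self, abstraction_record):
        tpl = pipeline_template(abstraction_record)
        assert "kinetics" in templates_to_yaml([tpl])
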