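import random

import pytest

from rxntemplater.chem import Atom, Bond, Molecule
from rxntemplater.io import ReactionRecord


@pytest.fixture
def methane():
    return Molecule.from_smiles("C")


@pytest.fixture
def h_radical():
    return Molecule.from_smiles("[H]")


@pytest.fixture
def abstraction_record(methane, h_radical):
    """CH4 + H. -> CH3. + H2"""
    return ReactionRecord(
        [methane, h_radical],
        [Molecule.from_smiles("[CH3]"), Molecule.from_smiles("[H][H]")],
        None,
        "abstraction",
        "synthetic",
    )


@pytest.fixture
def diels_alder_record():
    """butadiene + ethene -> cyclohexene"""
    return ReactionRecord(
        [Molecule.from_smiles("C=CC=C"), Molecule.from_smiles("C=C")],
        [Molecule.from_smiles("C1=CCCCC1")],
        None,
        "diels_alder",
        "synthetic",
    )


def permute_molecule(mol: Molecule, rng: random.Random) -> Molecule:
    """Same molecule with atoms stored in a random order."""
    order = list(range(len(mol.atoms)))
    rng.shuffle(order)
    old_to_new = {old: new for new, old in enumerate(order)}
    out = Molecule()
    for old in order:
        out.add_atom(mol.atoms[old])
    for b in mol.bonds:
        out.add_bond(Bond(old_to_new[b.i], old_to_new[b.j], b.order, b.stereo))
    return out


def pipeline_template(record, amap=None, include_hetero=True):
    """Shorthand: map (if needed), extract, formalize one record."""
    from rxntemplater.extraction import build_reactive_center, detect_changes
    from rxntemplater.mapping import compute_mapping, validate_mapping
    from rxntemplater.templates import build_template

    if amap is None:
        amap = record.mapping or compute_mapping(record)
    assert validate_mapping(record, amap).state == "complete"
    changes = detect_changes(record, amap)
    center = build_reactive_center(record, changes, include_hetero)
    return build_template(record, amap, changes, center)
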