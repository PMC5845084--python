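"""Synthetic reaction corpora and round-trip validation.

Reactions are built programmatically as pre-mapped records: reactant graphs
are constructed atom by atom, a small edit script (the intended mechanism) is
applied to a combined copy, and the product molecules plus the complete atom
map fall out of the bookkeeping.  Eight families of small-radical pyrolysis
and simple organic chemistry are covered, each with a recorded ground-truth
family label for classifier validation.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from typing import Optional

from .chem import Atom, Bond, Molecule, canonical_key
from .io import Corpus, ReactionRecord
from .mapping import AtomMap, Site, compute_mapping, validate_mapping

logger = logging.getLogger(__name__)

FAMILIES = (
    "h_abstraction",
    "h_shift",
    "beta_scission",
    "addition",
    "recombination",
    "substitution",
    "diels_alder",
    "hoo_elimination",
)

#: expected classifier prefix per generator family
FAMILY_CLASS_PREFIX = {
    "h_abstraction": "hydrogen_abstraction",
    "h_shift": "hydrogen_shift",
    "beta_scission": "beta_scission",
    "addition": "addition",
    "recombination": "recombination",
    "substitution": "substitution",
    "diels_alder": "addition/cycloaddition",
    "hoo_elimination": "other/peroxide_elimination",
}

_TARGET_VALENCE = {"C": 4, "O": 2, "H": 1, "Cl": 1, "N": 3}


# ---------------------------------------------------------------------------
# molecule construction helpers


def _chain(mol: Molecule, n: int, element: str = "C") -> list[int]:
    idxs = [mol.add_atom(Atom(element)) for _ in range(n)]
    for a, b in zip(idxs, idxs[1:]):
        mol.add_bond(Bond(a, b, 1))
    return idxs


def _saturate(mol: Molecule) -> None:
    """Fill every open valence with an explicit hydrogen."""
    for atom in list(mol.atoms):
        if atom.element == "H":
            continue
        target = _TARGET_VALENCE[atom.element] - atom.unpaired_electrons + atom.formal_charge
        while mol.valence(atom.index) < target:
            h = mol.add_atom(Atom("H"))
            mol.add_bond(Bond(atom.index, h, 1))


def _first_h(mol: Molecule, atom: int) -> int:
    for n in sorted(mol.neighbors(atom)):
        if mol.atoms[n].element == "H":
            return n
    raise ValueError(f"atom {atom} carries no hydrogen")


def _radical(kind: str, n_c: int = 0) -> Molecule:
    """Small radical species: H., OH., or an n-alkyl radical of n_c carbons."""
    mol = Molecule()
    if kind == "H":
        mol.add_atom(Atom("H", unpaired_electrons=1))
        return mol
    if kind == "OH":
        mol.add_atom(Atom("O", unpaired_electrons=1))
        _saturate(mol)
        return mol
    idxs = _chain(mol, max(1, n_c))
    mol.atoms[idxs[0]].unpaired_electrons = 1
    _saturate(mol)
    return mol


def _decorate(mol: Molecule, rng: random.Random, protected: set[int], p: float = 0.4) -> None:
    """Randomly replace an H outside ``protected`` by a small substituent.

    The H atom itself is mutated into the substituent root so all existing
    indices stay stable.
    """
    if rng.random() >= p:
        return
    candidates = [
        a.index
        for a in mol.atoms
        if a.element == "H"
        and a.index not in protected
        and a.unpaired_electrons == 0
        and mol.degree(a.index) == 1
        and mol.atoms[mol.neighbors(a.index)[0]].element == "C"
        and mol.neighbors(a.index)[0] not in protected
    ]
    if not candidates:
        return
    h = rng.choice(candidates)
    kind = rng.choice(["methyl", "ethyl", "hydroxyl", "chloro"])
    _mutate_h_to_fragment(mol, h, kind)


def _mutate_h_to_fragment(mol: Molecule, h: int, kind: str) -> list[int]:
    """Turn hydrogen ``h`` into the root atom of a substituent; returns the
    indices of all atoms belonging to the new fragment (root first)."""
    atom = mol.atoms[h]
    new = [h]
    if kind == "methyl":
        atom.element = "C"
    elif kind == "ethyl":
        atom.element = "C"
        c2 = mol.add_atom(Atom("C"))
        mol.add_bond(Bond(h, c2, 1))
        new.append(c2)
    elif kind == "vinyl":
        atom.element = "C"
        c2 = mol.add_atom(Atom("C"))
        mol.add_bond(Bond(h, c2, 2))
        new.append(c2)
    elif kind == "hydroxyl":
        atom.element = "O"
    elif kind == "chloro":
        atom.element = "Cl"
    else:
        raise ValueError(f"unknown fragment {kind!r}")
    before = {a.index for a in mol.atoms}
    _saturate(mol)
    new.extend(a.index for a in mol.atoms if a.index not in before)
    return new


# ---------------------------------------------------------------------------
# realizing an edit script into products + mapping

Edit = tuple  # ('break', a, b) | ('form', a, b, order) | ('order', a, b, new) | ('radical', a, delta)


def _realize(reactants: list[Molecule], edits: list[Edit]) -> tuple[list[Molecule], AtomMap]:
    offsets = []
    total = 0
    for m in reactants:
        offsets.append(total)
        total += len(m.atoms)

    def g(site: Site) -> int:
        return offsets[site[0]] + site[1]

    combined = Molecule()
    for m in reactants:
        for a in m.atoms:
            combined.add_atom(a)
    for mi, m in enumerate(reactants):
        for b in m.bonds:
            combined.add_bond(Bond(b.i + offsets[mi], b.j + offsets[mi], b.order, b.stereo))

    for e in edits:
        if e[0] == "break":
            combined.remove_bond(g(e[1]), g(e[2]))
        elif e[0] == "form":
            combined.add_bond(Bond(g(e[1]), g(e[2]), e[3]))
        elif e[0] == "order":
            combined.bond_between(g(e[1]), g(e[2])).order = e[3]
        elif e[0] == "radical":
            combined.atoms[g(e[1])].unpaired_electrons += e[2]
            if combined.atoms[g(e[1])].unpaired_electrons < 0:
                raise ValueError("negative radical count")
        else:
            raise ValueError(f"unknown edit {e[0]!r}")

    # split into product molecules, deterministic component order
    import networkx as nx

    comps = sorted(nx.connected_components(combined.to_networkx()), key=min)
    products: list[Molecule] = []
    where: dict[int, Site] = {}
    for pi, comp in enumerate(comps):
        m = Molecule()
        for old in sorted(comp):
            new = m.add_atom(combined.atoms[old])
            where[old] = (pi, new)
        for b in combined.bonds:
            if b.i in comp and b.j in comp:
                m.add_bond(Bond(where[b.i][1], where[b.j][1], b.order, b.stereo))
        if not m.is_valence_valid():
            raise ValueError(f"edit script produced invalid valences: {m}")
        products.append(m)

    amap = AtomMap()
    for mi, m in enumerate(reactants):
        for a in m.atoms:
            amap.add((mi, a.index), where[offsets[mi] + a.index])
    return products, amap


# ---------------------------------------------------------------------------
# family generators


def _gen_h_abstraction(rng: random.Random, small: bool) -> tuple[list[Molecule], list[Edit]]:
    donor_mol = Molecule()
    length = 1 if small else rng.randint(1, 4)
    chain = _chain(donor_mol, length)
    donor = rng.choice(chain)
    if not small and rng.random() < 0.35:
        # hetero-adjacent donor: hydroxyl on the reacting carbon
        o = donor_mol.add_atom(Atom("O"))
        donor_mol.add_bond(Bond(donor, o, 1))
    _saturate(donor_mol)
    if not small:
        _decorate(donor_mol, rng, protected={donor})
    kind, n_c = rng.choice([("H", 0), ("C", 1), ("C", 2), ("OH", 0)])
    abstractor = _radical(kind, n_c if not small else min(n_c, 1))
    rad_site = next(a.index for a in abstractor.atoms if a.unpaired_electrons)
    h = _first_h(donor_mol, donor)
    edits: list[Edit] = [
        ("break", (0, donor), (0, h)),
        ("form", (0, h), (1, rad_site), 1),
        ("radical", (0, donor), +1),
        ("radical", (1, rad_site), -1),
    ]
    return [donor_mol, abstractor], edits


def _gen_h_shift(rng: random.Random, small: bool) -> tuple[list[Molecule], list[Edit]]:
    mol = Molecule()
    length = 3 if small else rng.randint(3, 5)
    chain = _chain(mol, length)
    c_from = chain[0]
    mol.atoms[c_from].unpaired_electrons = 1
    k = 2 if small else rng.randint(1, length - 1)
    c_to = chain[k]
    _saturate(mol)
    if not small:
        _decorate(mol, rng, protected=set(chain))
    h = _first_h(mol, c_to)
    edits: list[Edit] = [
        ("break", (0, c_to), (0, h)),
        ("form", (0, c_from), (0, h), 1),
        ("radical", (0, c_from), -1),
        ("radical", (0, c_to), +1),
    ]
    return [mol], edits


def _gen_beta_scission(rng: random.Random, small: bool) -> tuple[list[Molecule], list[Edit]]:
    mol = Molecule()
    length = 3 if small else rng.randint(3, 6)
    chain = _chain(mol, length)
    mol.atoms[chain[0]].unpaired_electrons = 1
    _saturate(mol)
    if not small:
        _decorate(mol, rng, protected=set(chain[:3]))
    edits: list[Edit] = [
        ("break", (0, chain[1]), (0, chain[2])),
        ("order", (0, chain[0]), (0, chain[1]), 2),
        ("radical", (0, chain[0]), -1),
        ("radical", (0, chain[2]), +1),
    ]
    return [mol], edits


def _gen_addition(rng: random.Random, small: bool) -> tuple[list[Molecule], list[Edit]]:
    if small and rng.random() < 0.5:
        rad = _radical("H")
    else:
        rad = _radical("C", 1 if small else rng.choice([1, 2]))
    rad_site = next(a.index for a in rad.atoms if a.unpaired_electrons)
    alkene = Molecule()
    n = 2 if small else rng.randint(2, 4)
    chain = _chain(alkene, n)
    alkene.bond_between(chain[0], chain[1]).order = 2
    _saturate(alkene)
    if not small:
        _decorate(alkene, rng, protected={chain[0], chain[1]})
    edits: list[Edit] = [
        ("form", (0, rad_site), (1, chain[0]), 1),
        ("order", (1, chain[0]), (1, chain[1]), 1),
        ("radical", (0, rad_site), -1),
        ("radical", (1, chain[1]), +1),
    ]
    return [rad, alkene], edits


def _gen_recombination(rng: random.Random, small: bool) -> tuple[list[Molecule], list[Edit]]:
    if small:
        kinds = [("H", 0), ("C", 1), ("OH", 0)]  # keeps sides at <= 10 atoms
    else:
        kinds = [("H", 0), ("C", 1), ("C", 2), ("OH", 0)]
    k1, n1 = rng.choice(kinds)
    k2, n2 = rng.choice(kinds)
    r1 = _radical(k1, n1)
    r2 = _radical(k2, n2)
    s1 = next(a.index for a in r1.atoms if a.unpaired_electrons)
    s2 = next(a.index for a in r2.atoms if a.unpaired_electrons)
    edits: list[Edit] = [
        ("form", (0, s1), (1, s2), 1),
        ("radical", (0, s1), -1),
        ("radical", (1, s2), -1),
    ]
    return [r1, r2], edits


def _gen_substitution(rng: random.Random, small: bool) -> tuple[list[Molecule], list[Edit]]:
    rcl = Molecule()
    length = 1 if small else rng.randint(1, 3)
    chain = _chain(rcl, length)
    cl = rcl.add_atom(Atom("Cl"))
    rcl.add_bond(Bond(chain[0], cl, 1))
    _saturate(rcl)
    if not small:
        _decorate(rcl, rng, protected={chain[0], cl})
    water = Molecule()
    o = water.add_atom(Atom("O"))
    _saturate(water)
    oh = _first_h(water, o)
    edits: list[Edit] = [
        ("break", (0, chain[0]), (0, cl)),
        ("break", (1, o), (1, oh)),
        ("form", (0, chain[0]), (1, o), 1),
        ("form", (0, cl), (1, oh), 1),
    ]
    return [rcl, water], edits


def _gen_diels_alder(rng: random.Random, small: bool) -> tuple[list[Molecule], list[Edit]]:
    diene = Molecule()
    d = _chain(diene, 4)
    diene.bond_between(d[0], d[1]).order = 2
    diene.bond_between(d[2], d[3]).order = 2
    if not small and rng.random() < 0.5:
        me = diene.add_atom(Atom("C"))
        diene.add_bond(Bond(rng.choice([d[1], d[2]]), me, 1))
    _saturate(diene)
    ene = Molecule()
    e = _chain(ene, 2)
    ene.bond_between(e[0], e[1]).order = 2
    if not small and rng.random() < 0.5:
        me = ene.add_atom(Atom("C"))
        ene.add_bond(Bond(e[0], me, 1))
        _saturate(ene)
    else:
        _saturate(ene)
    edits: list[Edit] = [
        ("form", (0, d[0]), (1, e[0]), 1),
        ("form", (0, d[3]), (1, e[1]), 1),
        ("order", (0, d[0]), (0, d[1]), 1),
        ("order", (0, d[1]), (0, d[2]), 2),
        ("order", (0, d[2]), (0, d[3]), 1),
        ("order", (1, e[0]), (1, e[1]), 1),
    ]
    return [diene, ene], edits


def _gen_hoo_elimination(
    rng: random.Random, small: bool
) -> tuple[list[Molecule], list[Edit], dict]:
    mol = Molecule()
    n_c = 2 if small else rng.randint(2, 4)
    chain = _chain(mol, n_c)
    c_alpha, c_beta = chain[-1], chain[-2]
    o1 = mol.add_atom(Atom("O"))
    o2 = mol.add_atom(Atom("O", unpaired_electrons=1))
    mol.add_bond(Bond(c_alpha, o1, 1))
    mol.add_bond(Bond(o1, o2, 1))
    _saturate(mol)
    h_beta = _first_h(mol, c_beta)
    edits: list[Edit] = [
        ("break", (0, c_beta), (0, h_beta)),
        ("break", (0, c_alpha), (0, o1)),
        ("form", (0, h_beta), (0, o2), 1),
        ("order", (0, c_alpha), (0, c_beta), 2),
        ("radical", (0, o2), -1),
        ("radical", (0, o1), +1),
    ]
    meta = {"h_beta": (0, h_beta), "h_alpha": (0, _first_h(mol, c_alpha))}
    return [mol], edits, meta


_GENERATORS = {
    "h_abstraction": _gen_h_abstraction,
    "h_shift": _gen_h_shift,
    "beta_scission": _gen_beta_scission,
    "addition": _gen_addition,
    "recombination": _gen_recombination,
    "substitution": _gen_substitution,
    "diels_alder": _gen_diels_alder,
}


def generate_reaction(
    family: str,
    rng: random.Random,
    small: bool = False,
    wrong_peroxide_mapping: bool = False,
    source_id: str = "",
) -> ReactionRecord:
    """One pre-mapped, balanced reaction of the requested family."""
    if family == "hoo_elimination":
        reactants, edits, meta = _gen_hoo_elimination(rng, small)
        products, amap = _realize(reactants, edits)
        if wrong_peroxide_mapping:
            a, b = meta["h_alpha"], meta["h_beta"]
            amap.pairs[a], amap.pairs[b] = amap.pairs[b], amap.pairs[a]
    elif family in _GENERATORS:
        reactants, edits = _GENERATORS[family](rng, small)
        products, amap = _realize(reactants, edits)
    else:
        raise ValueError(f"unknown family {family!r}")
    rec = ReactionRecord(reactants, products, amap, source_id or family, "synthetic")
    assert validate_mapping(rec, amap).state == "complete"
    return rec


def generate_synthetic_corpus(
    families: dict[str, float],
    n: int,
    seed: int = 42,
    small: bool = False,
    wrong_peroxide_mapping: bool = False,
) -> Corpus:
    """Deterministic corpus with the requested family proportions.

    Counts per family follow the largest-remainder method so they always sum
    to ``n`` exactly; the family of each record is recorded in its source_id
    (``synth<idx>_<family>``) as ground truth.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    bad = set(families) - set(FAMILIES)
    if bad:
        raise ValueError(f"unknown families: {sorted(bad)}")
    total = sum(families.values())
    if not families or total <= 0 or any(v < 0 for v in families.values()):
        raise ValueError("family proportions must be positive")
    shares = {f: v / total for f, v in families.items()}
    counts = {f: int(n * s) for f, s in shares.items()}
    remainders = sorted(
        shares, key=lambda f: (-(n * shares[f] - counts[f]), f)
    )
    k = n - sum(counts.values())
    for f in remainders[:k]:
        counts[f] += 1
    records = []
    idx = 0
    for family in sorted(counts):
        for _ in range(counts[family]):
            rng = random.Random(seed * 1_000_003 + idx)
            records.append(
                generate_reaction(
                    family,
                    rng,
                    small=small,
                    wrong_peroxide_mapping=wrong_peroxide_mapping,
                    source_id=f"synth{idx:05d}_{family}",
                )
            )
            idx += 1
    return Corpus(records, [f"synthetic(seed={seed}, n={n})"])


def ground_truth_family(record: ReactionRecord) -> str:
    return record.source_id.split("_", 1)[1]


# ---------------------------------------------------------------------------
# test reactions (variant generation around a fixed center)


@dataclass
class TestReaction:
    base_record: ReactionRecord
    variant: ReactionRecord
    shared_center: set[Site]


def _center_sites(record: ReactionRecord, amap: AtomMap, include_hetero: bool = True) -> set[Site]:
    from .extraction import build_reactive_center, detect_changes

    changes = detect_changes(record, amap)
    center = build_reactive_center(record, changes, include_hetero)
    return center.sites()


def generate_test_reactions(
    record: ReactionRecord,
    amap: AtomMap,
    n: int = 25,
    seed: int = 42,
) -> list[TestReaction]:
    """Variants of a mapped reaction that share its reactive center.

    Random substituents are grafted onto hydrogens outside the center,
    symmetrically on both sides of the reaction, and the mapping is extended
    over the new atoms.  Duplicate variants are dropped, so fewer than ``n``
    may come back for small or highly symmetric substrates.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    center = _center_sites(record, amap)
    out: list[TestReaction] = []
    seen_keys = set()
    base_key = _reaction_key(record)
    attempts = 0
    rng = random.Random(seed)
    while len(out) < n and attempts < n * 20:
        attempts += 1
        variant = _make_variant(record, amap, center, rng)
        if variant is None:
            continue
        key = _reaction_key(variant)
        if key == base_key or key in seen_keys:
            continue
        seen_keys.add(key)
        variant.source_id = f"{record.source_id}_variant{len(out)}"
        out.append(TestReaction(record, variant, set(center)))
    if len(out) < n:
        logger.info(
            "%s: only %d/%d distinct variants possible", record.source_id, len(out), n
        )
    return out


def _reaction_key(record: ReactionRecord) -> tuple:
    return (
        tuple(sorted(canonical_key(m).key for m in record.reactants)),
        tuple(sorted(canonical_key(m).key for m in record.products)),
    )


def _make_variant(
    record: ReactionRecord, amap: AtomMap, center: set[Site], rng: random.Random
) -> Optional[ReactionRecord]:
    reactants = [m.copy() for m in record.reactants]
    products = [m.copy() for m in record.products]
    new_map = amap.copy()
    protected_r = center
    candidates = []
    for mi, m in enumerate(reactants):
        for a in m.atoms:
            s = (mi, a.index)
            if (
                a.element == "H"
                and s not in protected_r
                and m.degree(a.index) == 1
                and (mi, m.neighbors(a.index)[0]) not in protected_r
                and m.atoms[m.neighbors(a.index)[0]].element == "C"
            ):
                candidates.append(s)
    if not candidates:
        return None
    n_edits = rng.randint(1, min(3, len(candidates)))
    for _ in range(n_edits):
        if not candidates:
            break
        s = rng.choice(candidates)
        candidates.remove(s)
        p = new_map.pairs[s]
        kind = rng.choice(["methyl", "ethyl", "vinyl", "hydroxyl", "chloro"])
        new_r = _mutate_h_to_fragment(reactants[s[0]], s[1], kind)
        new_p = _mutate_h_to_fragment(products[p[0]], p[1], kind)
        if len(new_r) != len(new_p):
            return None
        for ra, pa in zip(new_r[1:], new_p[1:]):
            new_map.add((s[0], ra), (p[0], pa))
    variant = ReactionRecord(
        reactants, products, new_map, record.source_id + "_variant", "synthetic"
    )
    if validate_mapping(variant, new_map).state != "complete":
        return None
    return variant


# ---------------------------------------------------------------------------
# round-trip validation


def round_trip_check(
    corpus: Corpus, include_hetero: bool = True, mapper=None
) -> list[dict]:
    """Per-reaction pass/fail: the template extracted from each record must
    regenerate the record's own products when applied to its reactants."""
    from .extraction import build_reactive_center, detect_changes, mechanism_acceptable
    from .templates import apply_template, build_template

    report = []
    for rec in corpus.records:
        entry = {"source_id": rec.source_id, "status": "", "pass": False}
        amap = rec.mapping if rec.mapping is not None else compute_mapping(rec, mapper)
        state = validate_mapping(rec, amap).state
        if state not in ("complete",):
            entry["status"] = f"mapping_{state}"
            report.append(entry)
            continue
        changes = detect_changes(rec, amap)
        ok, reason = mechanism_acceptable(rec, changes)
        if not ok:
            entry["status"] = "mechanism_rejected"
            report.append(entry)
            continue
        center = build_reactive_center(rec, changes, include_hetero)
        tpl = build_template(rec, amap, changes, center)
        expected = tuple(sorted(canonical_key(m).key for m in rec.products))
        found = False
        for prods in apply_template(tpl, rec.reactants, check_constraints=False):
            if tuple(sorted(canonical_key(m).key for m in prods)) == expected:
                found = True
                break
        entry["pass"] = found
        entry["status"] = "ok" if found else "products_not_regenerated"
        report.append(entry)
    return report
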