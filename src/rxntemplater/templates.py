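"""Reaction templates: deduplication, SMARTS + recipe + constraints, application.

A template is the labeled reactive center of a reaction (one fragment per
participating reactant molecule, each atom annotated with its neighbor count
``X`` and valence ``v`` measured in the source molecule) together with the
recipe of graph edits and auto-generated molecular constraints.  Fragments are
brought into a canonical atom order so that template identity is a plain
string comparison, with a full label-preserving isomorphism check as the
semantic reference predicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import permutations
from typing import Iterable, Optional

import networkx as nx
from rdkit import Chem
from networkx.algorithms import isomorphism as nxiso

from .chem import Atom, Bond, Molecule, MoleculeKey, canonical_key, canonical_ranks
from .extraction import ChangeSet, ReactiveCenter
from .mapping import AtomMap, Site

logger = logging.getLogger(__name__)

ACTION_KINDS = (
    "BREAK_BOND",
    "CHANGE_BOND_ORDER",
    "FORM_BOND",
    "GAIN_RADICAL",
    "LOSE_RADICAL",
    "CHANGE_CHARGE",
    "CHANGE_STEREO",
)

#: cap on embeddings explored per fragment during application
EMBEDDING_CAP = 128
#: cap on distinct (reactant keys, product keys) signatures kept per template
SIGNATURE_CAP = 200


@dataclass
class FragmentAtom:
    element: str
    charge: int
    unpaired: int
    x: int  # neighbor count in the source molecule (H included)
    v: int  # valence in the source molecule
    role: str  # reactive | connector | hetero_expansion
    aromatic: bool = False


@dataclass
class FragmentBond:
    i: int
    j: int
    order: int
    aromatic: bool = False


@dataclass
class CenterFragment:
    atoms: list[FragmentAtom] = field(default_factory=list)
    bonds: list[FragmentBond] = field(default_factory=list)
    source_unpaired: int = 0  # unpaired electrons of the whole source reactant

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, a in enumerate(self.atoms):
            g.add_node(
                i,
                element=a.element,
                charge=a.charge,
                unpaired=a.unpaired,
                x=a.x,
                v=a.v,
                role=a.role,
            )
        for b in self.bonds:
            g.add_edge(b.i, b.j, order=b.order)
        return g

    def serial(self) -> str:
        atoms = ";".join(
            f"{a.element},{a.charge},{a.unpaired},X{a.x},v{a.v},{a.role},{int(a.aromatic)}"
            for a in self.atoms
        )
        bonds = ";".join(
            f"{min(b.i, b.j)}-{max(b.i, b.j)}:{b.order}"
            for b in sorted(self.bonds, key=lambda b: (min(b.i, b.j), max(b.i, b.j)))
        )
        return atoms + "|" + bonds


@dataclass
class Action:
    kind: str
    atoms: tuple[tuple[int, int], ...]  # (fragment index, atom index) refs
    before: object = None
    after: object = None

    def serial(self) -> str:
        return f"{self.kind}{sorted(self.atoms)}:{self.before}->{self.after}"


@dataclass
class Constraint:
    scope: str  # global | per_reactant
    kind: str  # max_heavy_atoms | max_single_electrons
    value: int
    reactant: Optional[int] = None

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("constraint value must be >= 0")


@dataclass
class ReactionTemplate:
    fragments: list[CenterFragment]
    recipe: list[Action]
    stereo_actions: list[Action] = field(default_factory=list)
    center_smarts: list[str] = field(default_factory=list)
    atom_smarts: list[list[str]] = field(default_factory=list)  # per fragment, per atom
    constraints: list[Constraint] = field(default_factory=list)
    count: int = 1
    status: str = "ok"  # ok | identical | failure
    reverse_of: Optional[str] = None
    source_ids: list[str] = field(default_factory=list)
    signatures: dict = field(default_factory=dict)  # (rkeys, pkeys) -> exemplar record
    template_id: str = ""
    class_path: str = ""

    def key(self) -> str:
        return "||".join(f.serial() for f in self.fragments) + "##" + ";".join(
            a.serial() for a in self.recipe
        )


# ---------------------------------------------------------------------------
# template construction


_KIND_TO_ACTION = {
    "neighbor_loss": "BREAK_BOND",
    "neighbor_gain": "FORM_BOND",
    "bond_order_change": "CHANGE_BOND_ORDER",
    "radical_gain": "GAIN_RADICAL",
    "radical_loss": "LOSE_RADICAL",
    "charge_change": "CHANGE_CHARGE",
    "stereo_change": "CHANGE_STEREO",
}


def _aromatic_flags(mol: Molecule) -> tuple[set[int], set[tuple[int, int]]]:
    """Re-perceive aromaticity on the source molecule (RDKit default model)."""
    try:
        rdmol = mol.to_rdkit()
        Chem.SetAromaticity(rdmol)
        atoms = {a.GetIdx() for a in rdmol.GetAtoms() if a.GetIsAromatic()}
        bonds = set()
        for b in rdmol.GetBonds():
            if b.GetIsAromatic():
                i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
                bonds.add((min(i, j), max(i, j)))
        return atoms, bonds
    except Exception:
        return set(), set()


def _canonical_fragment_order(
    frag: CenterFragment, action_marks: list[tuple]
) -> list[int]:
    """Canonical atom order using RDKit graph canonicalization.

    Atom invariants beyond the chemical ones (X, v, role, participation in
    recipe actions) are folded into the isotope field so symmetry that the
    recipe breaks is broken for the ranking as well.
    """
    rw = Chem.RWMol()
    for i, a in enumerate(frag.atoms):
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.charge)
        ra.SetNumRadicalElectrons(a.unpaired)
        ra.SetNoImplicit(True)
        inv = hash((a.x, a.v, a.role, a.aromatic, action_marks[i])) % 199 + 1
        ra.SetIsotope(inv)
        rw.AddAtom(ra)
    orders = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
    for b in frag.bonds:
        rw.AddBond(b.i, b.j, orders.get(b.order, Chem.BondType.SINGLE))
    mol = rw.GetMol()
    try:
        ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True, includeIsotopes=True))
    except Exception:
        ranks = list(range(len(frag.atoms)))
    order = sorted(range(len(frag.atoms)), key=lambda i: ranks[i])
    return order


def _reorder_fragment(frag: CenterFragment, order: list[int]) -> tuple[CenterFragment, dict[int, int]]:
    old_to_new = {old: new for new, old in enumerate(order)}
    atoms = [frag.atoms[old] for old in order]
    bonds = [
        FragmentBond(old_to_new[b.i], old_to_new[b.j], b.order, b.aromatic)
        for b in frag.bonds
    ]
    return CenterFragment(atoms, bonds, frag.source_unpaired), old_to_new


def build_template(record, amap: AtomMap, changes: ChangeSet, center: ReactiveCenter) -> ReactionTemplate:
    """Formalize one mapped, extracted reaction into a canonical template."""
    mols_in_center = sorted({mi for mi, _ in center.atoms})
    # raw fragments with site bookkeeping
    raw_frags: list[CenterFragment] = []
    site_ref: dict[Site, tuple[int, int]] = {}  # site -> (raw frag idx, atom idx)
    for fi, mi in enumerate(mols_in_center):
        mol = record.reactants[mi]
        arom_atoms, arom_bonds = _aromatic_flags(mol)
        ranks = canonical_ranks(mol)
        members = sorted(
            (ai for m, ai in center.atoms if m == mi), key=lambda ai: ranks[ai]
        )
        frag = CenterFragment(source_unpaired=mol.total_unpaired())
        local = {}
        for k, ai in enumerate(members):
            a = mol.atoms[ai]
            frag.atoms.append(
                FragmentAtom(
                    element=a.element,
                    charge=a.formal_charge,
                    unpaired=a.unpaired_electrons,
                    x=mol.degree(ai),
                    v=mol.valence(ai),
                    role=center.atoms[(mi, ai)],
                    aromatic=ai in arom_atoms,
                )
            )
            local[ai] = k
            site_ref[(mi, ai)] = (fi, k)
        for b in mol.bonds:
            if b.i in local and b.j in local:
                frag.bonds.append(
                    FragmentBond(
                        local[b.i],
                        local[b.j],
                        b.order,
                        (min(b.i, b.j), max(b.i, b.j)) in arom_bonds,
                    )
                )
        raw_frags.append(frag)

    # raw actions referencing (raw frag, atom)
    raw_actions: list[Action] = []
    for item in changes.items:
        refs = tuple(site_ref[s] for s in item.site)
        raw_actions.append(
            Action(_KIND_TO_ACTION[item.kind], refs, item.before, item.after)
        )

    # canonical order within each fragment (recipe participation breaks ties)
    marks_per_frag = []
    for fi, frag in enumerate(raw_frags):
        marks = [[] for _ in frag.atoms]
        for act in raw_actions:
            for f, a in act.atoms:
                if f == fi:
                    marks[a].append((act.kind, str(act.before), str(act.after)))
        marks_per_frag.append([tuple(sorted(m)) for m in marks])
    reordered = []
    remaps = []
    for frag, marks in zip(raw_frags, marks_per_frag):
        order = _canonical_fragment_order(frag, marks)
        f2, remap = _reorder_fragment(frag, order)
        reordered.append(f2)
        remaps.append(remap)
    actions = [
        replace(a, atoms=tuple((f, remaps[f][ai]) for f, ai in a.atoms))
        for a in raw_actions
    ]

    # canonical fragment order: sort by serial; for ties try permutations and
    # keep the lexicographically smallest overall key
    base_order = sorted(range(len(reordered)), key=lambda i: reordered[i].serial())

    def apply_frag_order(order: list[int]) -> tuple[list[CenterFragment], list[Action]]:
        pos = {old: new for new, old in enumerate(order)}
        frs = [reordered[old] for old in order]
        acts = [
            replace(a, atoms=tuple((pos[f], ai) for f, ai in a.atoms)) for a in actions
        ]
        acts = sorted(acts, key=lambda a: (ACTION_KINDS.index(a.kind), a.serial()))
        return frs, acts

    candidates = [base_order]
    serials = [reordered[i].serial() for i in base_order]
    if len(set(serials)) != len(serials) and len(base_order) <= 4:
        candidates = [
            list(p)
            for p in permutations(base_order)
            if [reordered[i].serial() for i in p] == serials
        ]
    best = None
    for cand in candidates:
        frs, acts = apply_frag_order(cand)
        key = "||".join(f.serial() for f in frs) + "##" + ";".join(a.serial() for a in acts)
        if best is None or key < best[0]:
            best = (key, frs, acts)
    _, frags, acts = best

    stereo = [a for a in acts if a.kind == "CHANGE_STEREO"]
    recipe = [a for a in acts if a.kind != "CHANGE_STEREO"]
    status = "ok" if recipe else "identical"

    tpl = ReactionTemplate(
        fragments=frags,
        recipe=recipe,
        stereo_actions=stereo,
        status=status,
        source_ids=[record.source_id],
    )
    tpl.center_smarts = [fragment_smarts(f) for f in tpl.fragments]
    tpl.atom_smarts = [
        [fragment_smarts(f, first=i) for i in range(len(f.atoms))]
        for f in tpl.fragments
    ]
    rkeys = tuple(sorted(canonical_key(m).key for m in record.reactants))
    pkeys = tuple(sorted(canonical_key(m).key for m in record.products))
    tpl.signatures[(rkeys, pkeys)] = record
    return tpl


# ---------------------------------------------------------------------------
# equality / dedup / reverse detection


def _tpl_node_match(n1, n2):
    return all(n1[k] == n2[k] for k in ("element", "charge", "unpaired", "x", "v", "role"))


def _tpl_edge_match(e1, e2):
    return e1["order"] == e2["order"]


def _union_graph(tpl: ReactionTemplate) -> tuple[nx.Graph, list[tuple[int, int]]]:
    g = nx.Graph()
    nodes = []
    for fi, frag in enumerate(tpl.fragments):
        fg = frag.to_networkx()
        for n, data in fg.nodes(data=True):
            g.add_node((fi, n), **data)
            nodes.append((fi, n))
        for u, v, data in fg.edges(data=True):
            g.add_edge((fi, u), (fi, v), **data)
    return g, nodes


def template_equals(a: ReactionTemplate, b: ReactionTemplate) -> bool:
    """Label-preserving isomorphism of the centers that also identifies the
    recipes item for item."""
    if len(a.fragments) != len(b.fragments) or len(a.recipe) != len(b.recipe):
        return False
    ga, _ = _union_graph(a)
    gb, _ = _union_graph(b)
    matcher = nxiso.GraphMatcher(
        ga, gb, node_match=_tpl_node_match, edge_match=_tpl_edge_match
    )
    recipe_b = _recipe_multiset(b.recipe, ident=lambda x: x)
    for mapping in matcher.isomorphisms_iter():
        mapped = _recipe_multiset(a.recipe, ident=lambda ref: mapping[ref])
        if mapped == recipe_b:
            return True
    return False


def _recipe_multiset(recipe: list[Action], ident) -> frozenset:
    out = []
    for act in recipe:
        refs = frozenset(ident(r) for r in act.atoms)
        out.append((act.kind, refs, str(act.before), str(act.after)))
    return frozenset((item, out.count(item)) for item in out)


def deduplicate_and_count(stream: Iterable[ReactionTemplate]) -> list[ReactionTemplate]:
    """Collapse a stream of extracted templates into a unique table.

    The canonical key is the primary hash; on collision groups the semantic
    isomorphism check arbitrates.  Output order (and counts) are independent
    of input order because rows are sorted by canonical key at the end.
    """
    by_key: dict[str, ReactionTemplate] = {}
    for tpl in stream:
        k = tpl.key()
        if k in by_key:
            tgt = by_key[k]
            tgt.count += 1
            tgt.source_ids.extend(tpl.source_ids[:1])
            if len(tgt.signatures) < SIGNATURE_CAP:
                for sig, rec in tpl.signatures.items():
                    tgt.signatures.setdefault(sig, rec)
        else:
            # rows are fresh objects so the input stream is never mutated
            by_key[k] = replace(
                tpl,
                count=1,
                source_ids=list(tpl.source_ids[:1]),
                signatures=dict(tpl.signatures),
                constraints=list(tpl.constraints),
            )
    table = sorted(by_key.values(), key=lambda t: t.key())
    for i, tpl in enumerate(table):
        tpl.template_id = f"T{i:04d}"
        tpl.class_path = classify_template(tpl)
    link_reverse_pairs(table)
    return table


def is_reverse_pair(a: ReactionTemplate, b: ReactionTemplate) -> bool:
    """Reverse when, for some representative reactions, the products of one
    equal the reactants of the other and vice versa, and applying each recipe
    to its reactants reproduces the other's reactants."""
    for (r_a, p_a), rec_a in a.signatures.items():
        if (p_a, r_a) not in b.signatures:
            continue
        rec_b = b.signatures[(p_a, r_a)]
        if _application_reaches(a, rec_a, p_a) and _application_reaches(b, rec_b, r_a):
            return True
    return False


def _application_reaches(tpl: ReactionTemplate, record, target_keys: tuple) -> bool:
    try:
        for prods in apply_template(tpl, record.reactants, check_constraints=False):
            if tuple(sorted(canonical_key(m).key for m in prods)) == target_keys:
                return True
    except Exception as exc:
        logger.warning("reverse-check application failed: %s", exc)
    return False


def link_reverse_pairs(table: list[ReactionTemplate]) -> None:
    for tpl in table:
        tpl.reverse_of = None
    for i, a in enumerate(table):
        for b in table[i:]:
            if a.reverse_of is not None and b.reverse_of is not None:
                continue
            if is_reverse_pair(a, b):
                if a.reverse_of is None:
                    a.reverse_of = b.template_id
                if b.reverse_of is None:
                    b.reverse_of = a.template_id


# ---------------------------------------------------------------------------
# SMARTS generation


_BOND_SYMBOL = {1: "-", 2: "=", 3: "#"}


def _atom_token(a: FragmentAtom) -> str:
    # inside brackets a bare 'H' is the hydrogen-count primitive, so element
    # hydrogen must be spelled by atomic number
    if a.element == "H":
        sym = "#1"
    elif a.aromatic and len(a.element) == 1:
        sym = a.element.lower()
    else:
        sym = a.element
    if a.charge > 0:
        charge = "+" if a.charge == 1 else f"+{a.charge}"
    elif a.charge < 0:
        charge = "-" if a.charge == -1 else f"-{-a.charge}"
    else:
        charge = ""
    return f"[{sym}X{a.x}v{a.v}{charge}]"


def fragment_smarts(frag: CenterFragment, first: int = 0) -> str:
    """SMARTS for one center fragment, written with atom ``first`` first.

    Every atom carries its neighbor count (X) and valence (v) as measured in
    the source molecule; all bonds are explicit; aromatic atoms/bonds are
    emitted lowercase / with ``:``.
    """
    if first < 0 or first >= len(frag.atoms):
        raise IndexError(f"atom {first} not in fragment")
    adj: dict[int, list[tuple[int, FragmentBond]]] = {i: [] for i in range(len(frag.atoms))}
    for b in frag.bonds:
        adj[b.i].append((b.j, b))
        adj[b.j].append((b.i, b))
    for i in adj:
        adj[i].sort(key=lambda t: t[0])

    visited: set[int] = set()
    closures: dict[tuple[int, int], int] = {}
    n_closure = [0]

    # pre-compute ring-closure bonds via DFS spanning tree
    tree_edges: set[tuple[int, int]] = set()
    stack = [first]
    seen = {first}
    parent = {first: None}
    order_seen = []
    while stack:
        u = stack.pop()
        order_seen.append(u)
        for v, _b in adj[u]:
            if v not in seen:
                seen.add(v)
                parent[v] = u
                tree_edges.add((min(u, v), max(u, v)))
                stack.append(v)
    for b in frag.bonds:
        e = (min(b.i, b.j), max(b.i, b.j))
        if e not in tree_edges:
            n_closure[0] += 1
            closures[e] = n_closure[0]

    def bond_sym(b: FragmentBond) -> str:
        if b.aromatic:
            return ":"
        return _BOND_SYMBOL[b.order]

    def emit(u: int) -> str:
        visited.add(u)
        s = _atom_token(frag.atoms[u])
        # ring closures opened/closed at this atom
        for v, b in adj[u]:
            e = (min(u, v), max(u, v))
            if e in closures:
                num = closures[e]
                digit = str(num) if num < 10 else f"%{num}"
                s += bond_sym(b) + digit
        children = [
            (v, b)
            for v, b in adj[u]
            if v not in visited and (min(u, v), max(u, v)) in tree_edges
        ]
        parts = []
        for k, (v, b) in enumerate(children):
            sub = bond_sym(b) + emit(v)
            parts.append(sub)
        if not parts:
            return s
        return s + "".join(f"({p})" for p in parts[:-1]) + parts[-1]

    return emit(first)


def generate_center_smarts(frag: CenterFragment) -> str:
    return fragment_smarts(frag, 0)


def generate_atom_first_smarts(frag: CenterFragment, target: int) -> str:
    return fragment_smarts(frag, target)


# ---------------------------------------------------------------------------
# constraints


def generate_constraints(corpus, tpl: ReactionTemplate) -> list[Constraint]:
    """Global size limit from the largest corpus molecule; per-reactant single
    electron limits from the template's source reactants."""
    if not corpus.records:
        raise ValueError("constraints need a non-empty corpus")
    largest = max(
        m.heavy_atom_count()
        for rec in corpus.records
        for m in list(rec.reactants) + list(rec.products)
    )
    out = [Constraint("global", "max_heavy_atoms", largest)]
    for i, frag in enumerate(tpl.fragments):
        out.append(
            Constraint("per_reactant", "max_single_electrons", frag.source_unpaired, i)
        )
    return out


# ---------------------------------------------------------------------------
# template application


def _target_graph(mol: Molecule) -> nx.Graph:
    g = nx.Graph()
    for a in mol.atoms:
        g.add_node(
            a.index,
            element=a.element,
            charge=a.formal_charge,
            x=mol.degree(a.index),
            v=mol.valence(a.index),
        )
    for b in mol.bonds:
        g.add_edge(b.i, b.j, order=b.order)
    return g


def _match_node(target, pattern):
    return (
        target["element"] == pattern["element"]
        and target["charge"] == pattern["charge"]
        and target["x"] == pattern["x"]
        and target["v"] == pattern["v"]
    )


def _fragment_embeddings(frag: CenterFragment, mol: Molecule) -> list[dict[int, int]]:
    """All induced embeddings (fragment atom -> molecule atom), capped."""
    pg = frag.to_networkx()
    tg = _target_graph(mol)
    matcher = nxiso.GraphMatcher(
        tg, pg, node_match=_match_node, edge_match=_tpl_edge_match
    )
    out = []
    for m in matcher.subgraph_isomorphisms_iter():
        out.append({p: t for t, p in m.items()})
        if len(out) >= EMBEDDING_CAP:
            break
    return out


def satisfies_constraints(tpl: ReactionTemplate, mols: list[Molecule]) -> bool:
    for c in tpl.constraints:
        if c.kind == "max_heavy_atoms":
            if any(m.heavy_atom_count() > c.value for m in mols):
                return False
        elif c.kind == "max_single_electrons" and c.reactant is not None:
            if c.reactant < len(mols) and mols[c.reactant].total_unpaired() > c.value:
                return False
    return True


def apply_template(
    tpl: ReactionTemplate,
    reactants: list[Molecule],
    check_constraints: bool = True,
) -> list[list[Molecule]]:
    """Apply the recipe at every embedding of the center; return the distinct
    valence-valid product sets."""
    if len(reactants) != len(tpl.fragments):
        return []
    if check_constraints and tpl.constraints and not satisfies_constraints(tpl, reactants):
        return []
    n = len(tpl.fragments)
    results: dict[tuple, list[Molecule]] = {}
    for assignment in permutations(range(len(reactants)), n):
        per_frag = []
        ok = True
        for fi, mi in enumerate(assignment):
            embs = _fragment_embeddings(tpl.fragments[fi], reactants[mi])
            if not embs:
                ok = False
                break
            per_frag.append(embs)
        if not ok:
            continue
        for combo in _iter_combos(per_frag):
            prods = _apply_at(tpl, reactants, assignment, combo)
            if prods is None:
                continue
            k = tuple(sorted(canonical_key(m).key for m in prods))
            results.setdefault(k, prods)
    return list(results.values())


def _iter_combos(per_frag: list[list[dict]]):
    if not per_frag:
        yield []
        return
    for head in per_frag[0]:
        for tail in _iter_combos(per_frag[1:]):
            yield [head] + tail


def _apply_at(
    tpl: ReactionTemplate,
    reactants: list[Molecule],
    assignment: tuple[int, ...],
    embeddings: list[dict[int, int]],
) -> Optional[list[Molecule]]:
    # combined graph over all reactant molecules
    offsets = []
    total = 0
    for m in reactants:
        offsets.append(total)
        total += len(m.atoms)
    combined = Molecule()
    for m in reactants:
        for a in m.atoms:
            combined.add_atom(a)
    for mi, m in enumerate(reactants):
        for b in m.bonds:
            combined.add_bond(Bond(b.i + offsets[mi], b.j + offsets[mi], b.order, b.stereo))

    def gidx(ref: tuple[int, int]) -> int:
        fi, ai = ref
        mi = assignment[fi]
        return embeddings[fi][ai] + offsets[mi]

    try:
        for act in tpl.recipe:
            if act.kind == "BREAK_BOND":
                i, j = (gidx(r) for r in act.atoms)
                if combined.bond_between(i, j) is None:
                    return None
                combined.remove_bond(i, j)
            elif act.kind == "FORM_BOND":
                i, j = (gidx(r) for r in act.atoms)
                if combined.bond_between(i, j) is not None:
                    return None
                combined.add_bond(Bond(i, j, int(act.after)))
            elif act.kind == "CHANGE_BOND_ORDER":
                i, j = (gidx(r) for r in act.atoms)
                b = combined.bond_between(i, j)
                if b is None or b.order != act.before:
                    return None
                b.order = int(act.after)
            elif act.kind == "GAIN_RADICAL" or act.kind == "LOSE_RADICAL":
                (i,) = (gidx(r) for r in act.atoms)
                a = combined.atoms[i]
                delta = int(act.after) - int(act.before)
                if a.unpaired_electrons + delta < 0:
                    return None
                a.unpaired_electrons += delta
            elif act.kind == "CHANGE_CHARGE":
                (i,) = (gidx(r) for r in act.atoms)
                combined.atoms[i].formal_charge += int(act.after) - int(act.before)
    except (KeyError, ValueError):
        return None

    # split into connected components
    g = combined.to_networkx()
    comps = list(nx.connected_components(g))
    prods = []
    for comp in comps:
        idx_map = {}
        m = Molecule()
        for old in sorted(comp):
            idx_map[old] = m.add_atom(combined.atoms[old])
        for b in combined.bonds:
            if b.i in idx_map and b.j in idx_map:
                m.add_bond(Bond(idx_map[b.i], idx_map[b.j], b.order, b.stereo))
        if not m.is_valence_valid():
            return None
        prods.append(m)
    return prods


# ---------------------------------------------------------------------------
# classification


_ELEMENT_NAME = {"C": "carbon", "H": "hydrogen", "O": "oxygen", "N": "nitrogen", "S": "sulfur"}


def _elname(sym: str) -> str:
    return _ELEMENT_NAME.get(sym, sym)


def classify_template(tpl: ReactionTemplate) -> str:
    """Rule-based class path from the recipe shape."""
    if not tpl.recipe:
        return "identical"
    frags = tpl.fragments

    def elem(ref):
        return frags[ref[0]].atoms[ref[1]].element

    breaks = [a for a in tpl.recipe if a.kind == "BREAK_BOND"]
    forms = [a for a in tpl.recipe if a.kind == "FORM_BOND"]
    order_up = [
        a
        for a in tpl.recipe
        if a.kind == "CHANGE_BOND_ORDER" and int(a.after) > int(a.before)
    ]
    order_down = [
        a
        for a in tpl.recipe
        if a.kind == "CHANGE_BOND_ORDER" and int(a.after) < int(a.before)
    ]
    rad_gain = [a for a in tpl.recipe if a.kind == "GAIN_RADICAL"]
    rad_loss = [a for a in tpl.recipe if a.kind == "LOSE_RADICAL"]
    n_frag = len(frags)
    any_radical = any(a.unpaired for f in frags for a in f.atoms)

    def h_transfer() -> Optional[tuple]:
        """(H ref, donor ref, acceptor ref) for a single H break+form pair."""
        if len(breaks) != 1 or len(forms) != 1:
            return None
        b_atoms, f_atoms = breaks[0].atoms, forms[0].atoms
        shared = set(b_atoms) & set(f_atoms)
        if len(shared) != 1:
            return None
        h = shared.pop()
        if elem(h) != "H":
            return None
        donor = next(r for r in b_atoms if r != h)
        acceptor = next(r for r in f_atoms if r != h)
        return h, donor, acceptor

    # peroxide elimination: C-O scission + C-H scission + O-H formation
    if n_frag == 1 and len(breaks) == 2 and len(forms) == 1 and order_up:
        broken_elems = {tuple(sorted(elem(r) for r in a.atoms)) for a in breaks}
        formed_elems = {tuple(sorted(elem(r) for r in a.atoms)) for a in forms}
        if broken_elems == {("C", "H"), ("C", "O")} and formed_elems == {("H", "O")}:
            return "other/peroxide_elimination"

    ht = h_transfer()
    if ht is not None:
        h, donor, acceptor = ht
        if n_frag == 2:
            return f"hydrogen_abstraction/{_elname(elem(acceptor))}_centered/from_{_elname(elem(donor))}"
        return f"hydrogen_shift/from_{_elname(elem(donor))}_to_{_elname(elem(acceptor))}"

    if n_frag == 1 and len(breaks) == 1 and not forms and order_up and any_radical:
        a, b = breaks[0].atoms
        return f"beta_scission/{'_'.join(sorted(_elname(elem(r)) for r in (a, b)))}"

    if n_frag == 2 and len(forms) == 2 and not breaks and order_down and not any_radical:
        return "addition/cycloaddition"

    if n_frag == 2 and len(forms) == 1 and not breaks and order_down:
        a, b = forms[0].atoms
        return f"addition/{'_'.join(sorted(_elname(elem(r)) for r in (a, b)))}"

    if (
        n_frag == 2
        and len(forms) == 1
        and not breaks
        and not order_up
        and not order_down
        and len(rad_loss) >= 2
    ):
        return "recombination"

    if n_frag == 2 and breaks and forms:
        return "substitution"

    return "other"


# ---------------------------------------------------------------------------
# serialization


def templates_to_yaml(table: list[ReactionTemplate], corpus=None) -> str:
    import yaml

    docs = []
    for tpl in table:
        docs.append(
            {
                "id": tpl.template_id,
                "class": tpl.class_path,
                "status": tpl.status,
                "reactants": [
                    {
                        "center_smarts": tpl.center_smarts[i],
                        "atoms": [
                            {
                                "label": f"a{i}_{k}",
                                "role": frag.atoms[k].role,
                                "smarts": tpl.atom_smarts[i][k],
                            }
                            for k in range(len(frag.atoms))
                        ],
                        "graph": {
                            "atoms": [
                                [a.element, a.charge, a.unpaired, a.x, a.v, a.role, int(a.aromatic)]
                                for a in frag.atoms
                            ],
                            "bonds": [
                                [b.i, b.j, b.order, int(b.aromatic)] for b in frag.bonds
                            ],
                            "source_unpaired": frag.source_unpaired,
                        },
                    }
                    for i, frag in enumerate(tpl.fragments)
                ],
                "recipe": [
                    {
                        "action": a.kind,
                        "atoms": [f"a{f}_{k}" for f, k in a.atoms],
                        "before": a.before,
                        "after": a.after,
                    }
                    for a in tpl.recipe
                ],
                "constraints": [
                    {
                        "scope": c.scope,
                        "kind": c.kind,
                        "value": c.value,
                        **({"reactant": c.reactant} if c.reactant is not None else {}),
                    }
                    for c in tpl.constraints
                ],
                "kinetics": {"group_additivity": {"database_path": None}},
                "provenance": {
                    "count": tpl.count,
                    "reverse_of": tpl.reverse_of,
                    "source_ids": tpl.source_ids[:50],
                },
            }
        )
    return yaml.safe_dump({"templates": docs}, sort_keys=False)


def templates_from_yaml(text: str) -> list[ReactionTemplate]:
    """Rebuild applicable templates from their YAML serialization."""
    import yaml

    data = yaml.safe_load(text)
    table = []
    for doc in data.get("templates", []):
        frags = []
        for rblock in doc["reactants"]:
            g = rblock["graph"]
            frag = CenterFragment(
                atoms=[
                    FragmentAtom(el, ch, up, x, v, role, bool(ar))
                    for el, ch, up, x, v, role, ar in g["atoms"]
                ],
                bonds=[FragmentBond(i, j, o, bool(ar)) for i, j, o, ar in g["bonds"]],
                source_unpaired=g.get("source_unpaired", 0),
            )
            frags.append(frag)
        recipe = []
        for a in doc.get("recipe", []):
            refs = tuple(
                (int(lbl.split("_")[0][1:]), int(lbl.split("_")[1])) for lbl in a["atoms"]
            )
            recipe.append(Action(a["action"], refs, a.get("before"), a.get("after")))
        tpl = ReactionTemplate(
            fragments=frags,
            recipe=recipe,
            center_smarts=[r["center_smarts"] for r in doc["reactants"]],
            atom_smarts=[
                [at["smarts"] for at in r["atoms"]] for r in doc["reactants"]
            ],
            constraints=[
                Constraint(c["scope"], c["kind"], c["value"], c.get("reactant"))
                for c in doc.get("constraints", [])
            ],
            count=doc.get("provenance", {}).get("count", 1),
            status=doc.get("status", "ok"),
            reverse_of=doc.get("provenance", {}).get("reverse_of"),
            source_ids=doc.get("provenance", {}).get("source_ids", []),
            template_id=doc.get("id", ""),
            class_path=doc.get("class", ""),
        )
        table.append(tpl)
    return table


def distribution_rows(table: list[ReactionTemplate]) -> list[dict]:
    return [
        {
            "id": t.template_id,
            "class": t.class_path,
            "count": t.count,
            "reverse_of": t.reverse_of or "",
            "status": t.status,
        }
        for t in table
    ]
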