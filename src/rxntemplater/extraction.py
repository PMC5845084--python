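"""Change detection and reactive-center construction for mapped reactions."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .chem import Molecule, canonical_ranks
from .mapping import AtomMap, Site, validate_mapping

logger = logging.getLogger(__name__)

KINDS = (
    "neighbor_gain",
    "neighbor_loss",
    "bond_order_change",
    "radical_gain",
    "radical_loss",
    "charge_change",
    "stereo_change",
)


@dataclass
class ChangeItem:
    kind: str
    site: tuple[Site, ...]  # reactant-side atoms involved (1 for atom, 2 for bond)
    before: object = None
    after: object = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown change kind {self.kind!r}")
        if self.before == self.after:
            raise ValueError("a change must change something")


@dataclass
class ChangeSet:
    items: list[ChangeItem] = field(default_factory=list)
    reactive_atoms: set[Site] = field(default_factory=set)


@dataclass
class ReactiveCenter:
    """Reactant atoms in the center with their role labels.

    labels: reactive | connector | hetero_expansion
    """

    atoms: dict[Site, str] = field(default_factory=dict)

    def sites(self, label: Optional[str] = None) -> set[Site]:
        if label is None:
            return set(self.atoms)
        return {s for s, lab in self.atoms.items() if lab == label}


def detect_changes(record, amap: AtomMap) -> ChangeSet:
    """Per-atom comparison of every mapped pair.

    A neighbor matches when its element and its mapped counterpart agree and
    the bond order is unchanged.  Gaining or losing a stereo descriptor
    (defined <-> undefined) is not treated as a change; only a flip between
    two defined descriptors is.
    """
    if validate_mapping(record, amap).state != "complete":
        raise ValueError("detect_changes requires a complete mapping")
    reactants, products = record.reactants, record.products
    pairs = amap.pairs
    inverse = amap.inverse
    cs = ChangeSet()
    seen_bond_items: set[tuple] = set()

    def add(item: ChangeItem) -> None:
        cs.items.append(item)
        cs.reactive_atoms.update(item.site)

    for r, p in sorted(pairs.items()):
        ra = reactants[r[0]].atoms[r[1]]
        pa = products[p[0]].atoms[p[1]]
        if ra.formal_charge != pa.formal_charge:
            add(ChangeItem("charge_change", (r,), ra.formal_charge, pa.formal_charge))
        if ra.unpaired_electrons != pa.unpaired_electrons:
            kind = (
                "radical_gain"
                if pa.unpaired_electrons > ra.unpaired_electrons
                else "radical_loss"
            )
            add(ChangeItem(kind, (r,), ra.unpaired_electrons, pa.unpaired_electrons))
        if ra.stereo and pa.stereo and ra.stereo != pa.stereo:
            add(ChangeItem("stereo_change", (r,), ra.stereo, pa.stereo))
        # neighbor / bond comparisons (one item per bond, not per endpoint)
        for n in reactants[r[0]].neighbors(r[1]):
            rn: Site = (r[0], n)
            cp = pairs[rn]
            bond_key = tuple(sorted((r, rn)))
            if bond_key in seen_bond_items:
                continue
            rb = reactants[r[0]].bond_between(r[1], n)
            pb = (
                products[p[0]].bond_between(p[1], cp[1]) if cp[0] == p[0] else None
            )
            if pb is None:
                seen_bond_items.add(bond_key)
                add(ChangeItem("neighbor_loss", bond_key, rb.order, None))
            elif pb.order != rb.order:
                seen_bond_items.add(bond_key)
                add(ChangeItem("bond_order_change", bond_key, rb.order, pb.order))
            elif rb.stereo and pb.stereo and rb.stereo != pb.stereo:
                seen_bond_items.add(bond_key)
                add(ChangeItem("stereo_change", bond_key, rb.stereo, pb.stereo))
        for pn_idx in products[p[0]].neighbors(p[1]):
            pn: Site = (p[0], pn_idx)
            rn = inverse[pn]
            if rn[0] == r[0] and reactants[r[0]].bond_between(r[1], rn[1]) is not None:
                continue  # already neighbors in the reactant
            bond_key = tuple(sorted((r, rn)))
            if bond_key in seen_bond_items:
                continue
            seen_bond_items.add(bond_key)
            pb = products[p[0]].bond_between(p[1], pn_idx)
            add(ChangeItem("neighbor_gain", bond_key, None, pb.order))
    return cs


# ---------------------------------------------------------------------------
# connecting disconnected centers


def connect_center(molecule: Molecule, reactive: set[int]) -> set[int]:
    """Atoms needed to connect ``reactive`` within one molecule.

    All-pairs BFS shortest paths between the reactive atoms form a complete
    weighted graph; a minimal spanning tree picks the cheapest connections and
    the atoms on the realizing paths (minus the reactive atoms themselves) are
    returned.  Kruskal edges are pre-sorted by (weight, canonical endpoint
    ranks) and each MST edge is realized by the canonically smallest shortest
    path, so connector identification is deterministic.
    """
    reactive = set(reactive)
    if len(reactive) <= 1:
        return set()
    g = molecule.to_networkx()
    ranks = canonical_ranks(molecule)
    nodes = sorted(reactive, key=lambda i: ranks[i])
    dist = nx.Graph()
    for i, a in enumerate(nodes):
        lengths = nx.single_source_shortest_path_length(g, a)
        for b in nodes[i + 1 :]:
            dist.add_edge(a, b, weight=lengths[b])
    edges = sorted(
        dist.edges(data="weight"),
        key=lambda e: (e[2], min(ranks[e[0]], ranks[e[1]]), max(ranks[e[0]], ranks[e[1]])),
    )
    # Kruskal
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    connectors: set[int] = set()
    for a, b, _w in edges:
        ra_, rb_ = find(a), find(b)
        if ra_ == rb_:
            continue
        parent[ra_] = rb_
        path = min(
            nx.all_shortest_paths(g, a, b),
            key=lambda p: tuple(ranks[i] for i in p),
        )
        connectors.update(path)
    return connectors - reactive


def build_reactive_center(
    record, changes: ChangeSet, include_hetero: bool = True
) -> ReactiveCenter:
    """Reactive atoms, plus connectors per molecule, plus optional adjacent
    heteroatoms (labeled ``hetero_expansion``)."""
    center = ReactiveCenter()
    for s in changes.reactive_atoms:
        center.atoms[s] = "reactive"
    by_mol: dict[int, set[int]] = {}
    for mi, ai in changes.reactive_atoms:
        by_mol.setdefault(mi, set()).add(ai)
    for mi, atoms in by_mol.items():
        for c in connect_center(record.reactants[mi], atoms):
            center.atoms.setdefault((mi, c), "connector")
    if include_hetero:
        for mi, atoms in by_mol.items():
            mol = record.reactants[mi]
            for ai in atoms:
                for n in mol.neighbors(ai):
                    if mol.atoms[n].element not in ("C", "H"):
                        center.atoms.setdefault((mi, n), "hetero_expansion")
    return center


# ---------------------------------------------------------------------------
# mechanism acceptability


def mechanism_acceptable(record, changes: ChangeSet) -> tuple[bool, str]:
    """Radical reactants must react via (one of) their radical atoms."""
    for mi, mol in enumerate(record.reactants):
        rad_atoms = [a.index for a in mol.atoms if a.unpaired_electrons > 0]
        if not rad_atoms:
            continue
        if not any((mi, ai) in changes.reactive_atoms for ai in rad_atoms):
            return (
                False,
                f"radical reactant {mi} does not participate via its radical atom",
            )
    return True, ""


# ---------------------------------------------------------------------------
# peroxide (ROO.) elimination correction


def _find_peroxy(mol: Molecule) -> Optional[tuple[int, int, int]]:
    """Return (terminal radical O, inner O, alpha C) of an ROO. group."""
    for a in mol.atoms:
        if a.element != "O" or a.unpaired_electrons < 1:
            continue
        nbrs = mol.neighbors(a.index)
        if len(nbrs) != 1:
            continue
        inner = nbrs[0]
        if mol.atoms[inner].element != "O":
            continue
        carbons = [
            n
            for n in mol.neighbors(inner)
            if n != a.index and mol.atoms[n].element == "C"
        ]
        if len(carbons) == 1:
            return a.index, inner, carbons[0]
    return None


def _is_hoo_radical(mol: Molecule) -> bool:
    return (
        mol.element_counts() == {"H": 1, "O": 2}
        and mol.total_unpaired() == 1
    )


def peroxide_ts_ring_size(record, amap: AtomMap) -> Optional[int]:
    """Size of the cyclic transition state implied by the mapped H transfer
    of an ROO. -> olefin + HOO. reaction; None when the pattern is absent."""
    if len(record.reactants) != 1:
        return None
    mol = record.reactants[0]
    peroxy = _find_peroxy(mol)
    if peroxy is None:
        return None
    hoo = [mi for mi, m in enumerate(record.products) if _is_hoo_radical(m)]
    if len(hoo) != 1 or len(record.products) != 2:
        return None
    hoo_mi = hoo[0]
    hoo_mol = record.products[hoo_mi]
    h_idx = next(a.index for a in hoo_mol.atoms if a.element == "H")
    inv = amap.inverse
    h_src = inv.get((hoo_mi, h_idx))
    if h_src is None:
        return None
    donors = [n for n in mol.neighbors(h_src[1])]
    if len(donors) != 1:
        return None
    donor = donors[0]
    terminal_o = peroxy[0]
    try:
        path = nx.shortest_path(mol.to_networkx(), donor, terminal_o)
    except nx.NetworkXNoPath:
        return None
    return len(path) + 1  # + transferred H


def correct_peroxide_elimination(record, amap: AtomMap) -> AtomMap:
    """Remap an ROO. elimination whose mapping implies a four-membered cyclic
    transition state so the transferred H originates from the beta carbon
    (five-membered transition state).  Anything else passes through."""
    ring = peroxide_ts_ring_size(record, amap)
    if ring != 4:
        return amap
    mol = record.reactants[0]
    _term_o, _inner_o, c_alpha = _find_peroxy(mol)
    hoo_mi = next(
        mi for mi, m in enumerate(record.products) if _is_hoo_radical(m)
    )
    h_idx = next(
        a.index for a in record.products[hoo_mi].atoms if a.element == "H"
    )
    inv = amap.inverse
    h_old = inv[(hoo_mi, h_idx)]  # H on the alpha carbon
    ranks = canonical_ranks(mol)
    # beta carbon: carbon neighbor of the alpha carbon carrying at least one H
    betas = [
        n
        for n in mol.neighbors(c_alpha)
        if mol.atoms[n].element == "C"
        and any(mol.atoms[x].element == "H" for x in mol.neighbors(n))
    ]
    if not betas:
        logger.warning(
            "%s: 4-ring peroxide mapping found but no beta C-H to remap",
            getattr(record, "source_id", "?"),
        )
        return amap
    beta = min(betas, key=lambda i: ranks[i])
    h_new_idx = min(
        (x for x in mol.neighbors(beta) if mol.atoms[x].element == "H"),
        key=lambda i: ranks[i],
    )
    h_new: Site = (0, h_new_idx)
    fixed = amap.copy()
    fixed.pairs[h_old], fixed.pairs[h_new] = fixed.pairs[h_new], fixed.pairs[h_old]
    return fixed
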