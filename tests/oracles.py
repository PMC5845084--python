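"""Independent reference implementations used to check the package.

Everything here is deliberately written from scratch (brute force, plain
BFS, exhaustive enumeration) and must not call into the code paths it
verifies.
"""

from __future__ import annotations

from collections import deque
from itertools import permutations, product

import networkx as nx


def molecule_graph(mol) -> nx.Graph:
    g = nx.Graph()
    for a in mol.atoms:
        g.add_node(
            a.index,
            element=a.element,
            charge=a.formal_charge,
            unpaired=a.unpaired_electrons,
        )
    for b in mol.bonds:
        g.add_edge(b.i, b.j, order=b.order)
    return g


def graphs_isomorphic(mol_a, mol_b) -> bool:
    return nx.is_isomorphic(
        molecule_graph(mol_a),
        molecule_graph(mol_b),
        node_match=lambda x, y: (x["element"], x["charge"], x["unpaired"])
        == (y["element"], y["charge"], y["unpaired"]),
        edge_match=lambda x, y: x["order"] == y["order"],
    )


def bfs_eccentricity(mol, root: int) -> int:
    """Plain BFS eccentricity, no networkx shortest-path machinery."""
    adj = {a.index: [] for a in mol.atoms}
    for b in mol.bonds:
        adj[b.i].append(b.j)
        adj[b.j].append(b.i)
    dist = {root: 0}
    q = deque([root])
    far = 0
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                far = max(far, dist[v])
                q.append(v)
    return far


def _changed_count(reactants, products, pairs) -> int:
    """Number of reactant atoms whose environment changed; independent of the
    package's own scoring code."""
    changed = 0
    for (rmi, rai), (pmi, pai) in pairs.items():
        ra = reactants[rmi].atoms[rai]
        pa = products[pmi].atoms[pai]
        if ra.formal_charge != pa.formal_charge or ra.unpaired_electrons != pa.unpaired_electrons:
            changed += 1
            continue
        r_nbrs = reactants[rmi].neighbors(rai)
        p_nbrs = set(products[pmi].neighbors(pai))
        if len(r_nbrs) != len(p_nbrs):
            changed += 1
            continue
        ok = True
        for n in r_nbrs:
            img = pairs.get((rmi, n))
            if img is None or img[0] != pmi or img[1] not in p_nbrs:
                ok = False
                break
            if (
                reactants[rmi].bond_between(rai, n).order
                != products[pmi].bond_between(pai, img[1]).order
            ):
                ok = False
                break
        if not ok:
            changed += 1
    return changed


def brute_force_min_changes(record, cap: int = 5_000_000):
    """Exhaustive minimum over all element-preserving atom bijections.

    Returns (min changed-atom count, one optimal mapping).  Raises if the
    enumeration would exceed ``cap`` bijections.
    """
    r_by_el: dict[str, list] = {}
    p_by_el: dict[str, list] = {}
    for mi, m in enumerate(record.reactants):
        for a in m.atoms:
            r_by_el.setdefault(a.element, []).append((mi, a.index))
    for mi, m in enumerate(record.products):
        for a in m.atoms:
            p_by_el.setdefault(a.element, []).append((mi, a.index))
    assert {e: len(v) for e, v in r_by_el.items()} == {
        e: len(v) for e, v in p_by_el.items()
    }, "unbalanced reaction"
    elements = sorted(r_by_el)
    n_total = 1
    for el in elements:
        k = len(r_by_el[el])
        for i in range(2, k + 1):
            n_total *= i
        if n_total > cap:
            raise ValueError(f"too many bijections (> {cap})")
    best = None
    best_pairs = None
    for combo in product(*(permutations(p_by_el[el]) for el in elements)):
        pairs = {}
        for el, perm in zip(elements, combo):
            for r, p in zip(r_by_el[el], perm):
                pairs[r] = p
        c = _changed_count(record.reactants, record.products, pairs)
        if best is None or c < best:
            best, best_pairs = c, pairs
    return best, best_pairs


def connected_after_removal(mol, kept: set[int]) -> bool:
    """Is the induced subgraph on ``kept`` connected?"""
    g = molecule_graph(mol).subgraph(kept)
    return g.number_of_nodes() > 0 and nx.is_connected(g)
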