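"""Atom-atom mapping: baseline mapper, resonance selection, heuristic completion.

An :class:`AtomMap` is a partial bijection from reactant atoms to product
atoms; atoms are addressed as ``(molecule position, atom index)`` pairs.  The
baseline mapper is a seeded branch-and-bound search that minimizes the number
of reactant atoms whose environment changes; it is exact for small reactions
and falls back to a greedy extension beyond a size threshold.  External
mappers (e.g. pre-mapped RXN input) plug in through the same interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product as iproduct
from typing import Callable, Optional

from .chem import Molecule, canonical_ranks, enumerate_resonance_flagged, environments_identical

logger = logging.getLogger(__name__)

Site = tuple[int, int]  # (molecule position within its side, atom index)

#: exact search is attempted up to this many heavy atoms per side
EXACT_SEARCH_LIMIT = 14
#: cap on resonance-structure combinations per reaction
COMBINATION_CAP = 64


class MappingError(ValueError):
    pass


@dataclass
class AtomMap:
    """Partial injective map from reactant sites to product sites."""

    pairs: dict[Site, Site] = field(default_factory=dict)

    def add(self, r: Site, p: Site) -> None:
        if r in self.pairs:
            raise MappingError(f"reactant site {r} already mapped")
        if p in self.pairs.values():
            raise MappingError(f"product site {p} already mapped")
        self.pairs[r] = p

    def get(self, r: Site) -> Optional[Site]:
        return self.pairs.get(r)

    @property
    def inverse(self) -> dict[Site, Site]:
        return {p: r for r, p in self.pairs.items()}

    def copy(self) -> "AtomMap":
        return AtomMap(dict(self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class MappingStatus:
    state: str  # complete | heuristically_completed | incomplete | failed
    detail: str = ""


# ---------------------------------------------------------------------------
# site enumeration helpers


def all_sites(mols: list[Molecule]) -> list[Site]:
    return [(mi, a.index) for mi, m in enumerate(mols) for a in m.atoms]


def site_element(mols: list[Molecule], s: Site) -> str:
    return mols[s[0]].atoms[s[1]].element


def validate_mapping(record, amap: AtomMap) -> MappingStatus:
    """Completeness / consistency check; complete iff bijective over all atoms."""
    r_sites = set(all_sites(record.reactants))
    p_sites = set(all_sites(record.products))
    for r, p in amap.pairs.items():
        if r not in r_sites or p not in p_sites:
            return MappingStatus("failed", f"pair {r}->{p} references a missing atom")
        if site_element(record.reactants, r) != site_element(record.products, p):
            return MappingStatus(
                "failed",
                f"element mismatch {site_element(record.reactants, r)}->"
                f"{site_element(record.products, p)} at {r}->{p}",
            )
    mapped_p = list(amap.pairs.values())
    if len(set(mapped_p)) != len(mapped_p):
        return MappingStatus("failed", "mapping not injective")
    if set(amap.pairs) == r_sites and set(mapped_p) == p_sites:
        return MappingStatus("complete")
    if not amap.pairs:
        return MappingStatus("failed", "empty mapping")
    return MappingStatus(
        "incomplete", f"{len(r_sites) - len(amap.pairs)} reactant atoms unmapped"
    )


# ---------------------------------------------------------------------------
# change counting (used for mapper scoring and resonance selection)


def atom_changed(
    reactants: list[Molecule], products: list[Molecule], pairs: dict[Site, Site], r: Site
) -> bool:
    """Did the environment of reactant atom ``r`` change under a complete map?

    Mirrors the per-atom comparison taxonomy: neighbors (element + mapped
    counterpart + bond order), single-electron count and charge.  Stereo is
    deliberately excluded from mapper scoring.
    """
    p = pairs[r]
    ra = reactants[r[0]].atoms[r[1]]
    pa = products[p[0]].atoms[p[1]]
    if ra.formal_charge != pa.formal_charge:
        return True
    if ra.unpaired_electrons != pa.unpaired_electrons:
        return True
    rn = reactants[r[0]].neighbors(r[1])
    pn = products[p[0]].neighbors(p[1])
    if len(rn) != len(pn):
        return True
    pn_set = set(pn)
    for n in rn:
        cp = pairs.get((r[0], n))
        if cp is None or cp[0] != p[0] or cp[1] not in pn_set:
            return True
        if (
            reactants[r[0]].bond_between(r[1], n).order
            != products[p[0]].bond_between(p[1], cp[1]).order
        ):
            return True
    return False


def count_changed_atoms(
    reactants: list[Molecule], products: list[Molecule], amap: AtomMap
) -> int:
    return sum(
        1 for r in amap.pairs if atom_changed(reactants, products, amap.pairs, r)
    )


# ---------------------------------------------------------------------------
# baseline mapper: seeded branch-and-bound


def _env_hashes(mols: list[Molecule], rounds: int = 3) -> dict[Site, int]:
    """Iterated neighborhood hash per site (Morgan-style, order-sensitive)."""
    h: dict[Site, int] = {}
    for mi, m in enumerate(mols):
        for a in m.atoms:
            h[(mi, a.index)] = hash((a.element, a.formal_charge, a.unpaired_electrons))
    for _ in range(rounds):
        nh: dict[Site, int] = {}
        for mi, m in enumerate(mols):
            for a in m.atoms:
                s = (mi, a.index)
                nb = sorted(
                    (m.bond_between(a.index, n).order, h[(mi, n)])
                    for n in m.neighbors(a.index)
                )
                nh[s] = hash((h[s], tuple(nb)))
        h = nh
    return h


def _site_rank_order(mols: list[Molecule]) -> dict[Site, int]:
    """Deterministic global order of sites by (molecule, canonical rank)."""
    order: dict[Site, int] = {}
    base = 0
    for mi, m in enumerate(mols):
        ranks = canonical_ranks(m)
        for a in m.atoms:
            order[(mi, a.index)] = base + ranks[a.index]
        base += len(m.atoms)
    return order


@dataclass
class _SideInfo:
    """Pre-digested view of one reaction side for the heavy-atom search."""

    heavy: list[Site]
    charge: dict[Site, int]
    unpaired: dict[Site, int]
    degree: dict[Site, int]
    n_h: dict[Site, int]  # terminal hydrogens per heavy atom
    heavy_nbrs: dict[Site, list[tuple[Site, int]]]  # (site, bond order)
    h_of: dict[Site, list[Site]]  # heavy atom -> its H sites (canonical order)
    h2_pairs: list[tuple[Site, Site]]
    lone_h: dict[tuple[int, int], list[Site]]  # (charge, unpaired) -> H sites
    n_hydrogens: int


def _digest_side(mols: list[Molecule]) -> _SideInfo:
    order = _site_rank_order(mols)
    info = _SideInfo([], {}, {}, {}, {}, {}, {}, [], {}, 0)
    seen_h2: set[Site] = set()
    for mi, m in enumerate(mols):
        for a in sorted(m.atoms, key=lambda a: order[(mi, a.index)]):
            s: Site = (mi, a.index)
            if a.element != "H":
                info.heavy.append(s)
                info.charge[s] = a.formal_charge
                info.unpaired[s] = a.unpaired_electrons
                info.degree[s] = m.degree(a.index)
                hs = [
                    (mi, n)
                    for n in m.neighbors(a.index)
                    if m.atoms[n].element == "H"
                ]
                info.h_of[s] = sorted(hs, key=lambda t: order[t])
                info.n_h[s] = len(hs)
                info.heavy_nbrs[s] = [
                    ((mi, n), m.bond_between(a.index, n).order)
                    for n in m.neighbors(a.index)
                    if m.atoms[n].element != "H"
                ]
                continue
            info.n_hydrogens += 1
            nbrs = m.neighbors(a.index)
            if not nbrs:
                key = (a.formal_charge, a.unpaired_electrons)
                info.lone_h.setdefault(key, []).append(s)
            elif m.atoms[nbrs[0]].element == "H":
                if s not in seen_h2:
                    partner = (mi, nbrs[0])
                    seen_h2.update((s, partner))
                    info.h2_pairs.append((s, partner))
    return info


class _HeavySearch:
    """Branch-and-bound over element-preserving heavy-atom bijections.

    Hydrogens attached to a mapped heavy pair are interchangeable, so the
    optimal hydrogen layer has closed form: min(nH) hydrogens per heavy pair
    stay unchanged, H2 pairs match H2 pairs and lone H match lone H; every
    other hydrogen counts as changed.  The search therefore only branches on
    heavy atoms, with an admissible bound from atoms already provably changed.
    """

    NODE_CAP = 300_000

    def __init__(self, reactants: list[Molecule], products: list[Molecule]):
        self.r = _digest_side(reactants)
        self.p = _digest_side(products)
        self.p_by_elem: dict[str, list[Site]] = {}
        for s in self.p.heavy:
            self.p_by_elem.setdefault(site_element(products, s), []).append(s)
        self.r_elem = {s: site_element(reactants, s) for s in self.r.heavy}
        # process atoms molecule by molecule so the partial map stays connected
        self.order = list(self.r.heavy)
        self.best_cost: tuple = (float("inf"), float("inf"), float("inf"))
        self.best: Optional[dict[Site, Site]] = None
        self.nodes = 0
        self.truncated = False
        # hydrogen cost terms independent of the heavy assignment
        self.h_base_unchanged = 2 * min(len(self.r.h2_pairs), len(self.p.h2_pairs))
        for key, sites in self.r.lone_h.items():
            self.h_base_unchanged += min(len(sites), len(self.p.lone_h.get(key, [])))

    def _provably_changed(self, s: Site, p: Site, partial: dict[Site, Site]) -> bool:
        r, pi = self.r, self.p
        if (
            r.charge[s] != pi.charge[p]
            or r.unpaired[s] != pi.unpaired[p]
            or r.degree[s] != pi.degree[p]
            or r.n_h[s] != pi.n_h[p]
        ):
            return True
        p_nbrs = {n: o for n, o in pi.heavy_nbrs[p]}
        for n, o in r.heavy_nbrs[s]:
            img = partial.get(n)
            if img is not None and p_nbrs.get(img) != o:
                return True
        return False

    def _leaf_cost(self, m: dict[Site, Site]) -> tuple[int, int, int]:
        """(changed atoms, structural edits, order edits).

        Structural edits are broken plus formed bonds (a moved hydrogen counts
        as one break and one form); order edits are bond-order changes between
        atoms that stay bonded.  The split rewards mappings that shuffle
        electrons over mappings that shuffle the sigma framework, mirroring a
        minimal structural-and-bond-change objective.
        """
        heavy_cost = sum(1 for s, p in m.items() if self._provably_changed(s, p, m))
        unchanged_h = self.h_base_unchanged + sum(
            min(self.r.n_h[s], self.p.n_h[p]) for s, p in m.items()
        )
        inv = {p: s for s, p in m.items()}
        breaks_forms = 0
        order_edits = 0
        seen: set[frozenset[Site]] = set()
        for s, p in m.items():
            p_nbrs = {n: o for n, o in self.p.heavy_nbrs[p]}
            for n, o in self.r.heavy_nbrs[s]:
                key = frozenset((s, n))
                if key in seen:
                    continue
                seen.add(key)
                img_o = p_nbrs.get(m[n])
                if img_o is None:
                    breaks_forms += 1
                elif img_o != o:
                    order_edits += 1
        seen_p: set[frozenset[Site]] = set()
        for p, s in inv.items():
            r_nbrs = {n for n, _o in self.r.heavy_nbrs[s]}
            for n, _o in self.p.heavy_nbrs[p]:
                key = frozenset((p, n))
                if key in seen_p:
                    continue
                seen_p.add(key)
                if inv[n] not in r_nbrs:
                    breaks_forms += 1
        breaks_forms += 2 * (self.r.n_hydrogens - unchanged_h)
        primary = heavy_cost + (self.r.n_hydrogens - unchanged_h)
        return primary, breaks_forms, order_edits

    def run(self) -> Optional[dict[Site, Site]]:
        if len(self.r.heavy) != len(self.p.heavy):
            return None
        self._extend({}, set(), 0, 0)
        return self.best

    def _extend(
        self, partial: dict[Site, Site], used: set[Site], depth: int, lb: int
    ) -> None:
        self.nodes += 1
        if self.nodes > self.NODE_CAP:
            self.truncated = True
            return
        if depth == len(self.order):
            cost = self._leaf_cost(partial)
            if cost < self.best_cost:
                self.best_cost = cost
                self.best = dict(partial)
            return
        s = self.order[depth]
        for cand in self.p_by_elem.get(self.r_elem[s], []):
            if cand in used:
                continue
            add = 1 if self._provably_changed(s, cand, partial) else 0
            if lb + add > self.best_cost[0]:
                continue
            partial[s] = cand
            used.add(cand)
            self._extend(partial, used, depth + 1, lb + add)
            del partial[s]
            used.discard(cand)


def _hydrogen_layer(
    reactants: list[Molecule],
    products: list[Molecule],
    heavy_map: dict[Site, Site],
) -> dict[Site, Site]:
    """Deterministic optimal hydrogen assignment on top of a heavy-atom map."""
    r = _digest_side(reactants)
    p = _digest_side(products)
    pairs: dict[Site, Site] = dict(heavy_map)
    used_p: set[Site] = set()
    r_pool: list[Site] = []
    # hydrogens on mapped heavy pairs
    for s in r.heavy:
        ph = r.h_of[s]
        qh = p.h_of[heavy_map[s]]
        n = min(len(ph), len(qh))
        for h_r, h_p in zip(ph[:n], qh[:n]):
            pairs[h_r] = h_p
            used_p.add(h_p)
        r_pool.extend(ph[n:])
    # H2 pairs
    n2 = min(len(r.h2_pairs), len(p.h2_pairs))
    for (a1, a2), (b1, b2) in zip(r.h2_pairs[:n2], p.h2_pairs[:n2]):
        pairs[a1], pairs[a2] = b1, b2
        used_p.update((b1, b2))
    for a1, a2 in r.h2_pairs[n2:]:
        r_pool.extend((a1, a2))
    # lone hydrogens by (charge, unpaired)
    for key, sites in sorted(r.lone_h.items()):
        tgt = p.lone_h.get(key, [])
        n = min(len(sites), len(tgt))
        for h_r, h_p in zip(sites[:n], tgt[:n]):
            pairs[h_r] = h_p
            used_p.add(h_p)
        r_pool.extend(sites[n:])
    # leftovers in canonical order
    p_order = _site_rank_order(products)
    p_pool = sorted(
        (
            s
            for mi, m in enumerate(products)
            for a in m.atoms
            if a.element == "H" and (s := (mi, a.index)) not in used_p
        ),
        key=lambda s: p_order[s],
    )
    r_order = _site_rank_order(reactants)
    for h_r, h_p in zip(sorted(r_pool, key=lambda s: r_order[s]), p_pool):
        pairs[h_r] = h_p
    return pairs


def _greedy_mapping(reactants: list[Molecule], products: list[Molecule]) -> dict[Site, Site]:
    """Anchor-and-extend heuristic for reactions too large for exact search."""
    rh = _env_hashes(reactants)
    ph = _env_hashes(products)
    r_order = _site_rank_order(reactants)
    p_order = _site_rank_order(products)
    pairs: dict[Site, Site] = {}
    used: set[Site] = set()
    # anchors: environment hash unique on both sides
    from collections import Counter

    rc = Counter(rh.values())
    pc = Counter(ph.values())
    p_by_hash = {}
    for s, h in ph.items():
        p_by_hash.setdefault(h, []).append(s)
    for s in sorted(rh, key=lambda s: r_order[s]):
        h = rh[s]
        if rc[h] == 1 and pc.get(h) == 1:
            cand = p_by_hash[h][0]
            if cand not in used:
                pairs[s] = cand
                used.add(cand)
    # greedy extension: map neighbors of mapped atoms preferring preserved bonds
    changed = True
    while changed:
        changed = False
        for s in sorted(rh, key=lambda s: r_order[s]):
            if s in pairs:
                continue
            elem = site_element(reactants, s)
            best_cand, best_score = None, -1
            for cand in sorted(ph, key=lambda s: p_order[s]):
                if cand in used or site_element(products, cand) != elem:
                    continue
                score = 0
                for n in reactants[s[0]].neighbors(s[1]):
                    cp = pairs.get((s[0], n))
                    if cp and cp[0] == cand[0] and products[cand[0]].bond_between(
                        cand[1], cp[1]
                    ):
                        score += 1
                if score > best_score:
                    best_cand, best_score = cand, score
            if best_cand is not None:
                pairs[s] = best_cand
                used.add(best_cand)
                changed = True
    return pairs


def baseline_mapper(record) -> AtomMap:
    """Built-in minimal-change mapper (plug-in signature: record -> AtomMap).

    Exact (change-count optimal) whenever the heavy-atom search completes
    within its node budget; otherwise falls back to the greedy anchor-and-
    extend heuristic, matching the expectation that computed mappings are
    only trustworthy for small molecules.
    """
    amap = AtomMap()
    n_r = sum(len(m) for m in record.reactants)
    n_p = sum(len(m) for m in record.products)
    if n_r != n_p:
        return amap
    n_heavy = sum(m.heavy_atom_count() for m in record.reactants)
    if n_heavy <= EXACT_SEARCH_LIMIT:
        search = _HeavySearch(record.reactants, record.products)
        best = search.run()
        if best is not None and not search.truncated:
            amap.pairs = _hydrogen_layer(record.reactants, record.products, best)
            return amap
        if best is not None:
            logger.info(
                "heavy-atom search truncated on %s; result may be suboptimal",
                getattr(record, "source_id", "?"),
            )
            amap.pairs = _hydrogen_layer(record.reactants, record.products, best)
            return amap
    amap.pairs = _greedy_mapping(record.reactants, record.products)
    return amap


def compute_mapping(record, mapper: Callable | None = None) -> AtomMap:
    """Run a mapper plug-in; failures surface as an empty map."""
    mapper = mapper or baseline_mapper
    try:
        return mapper(record)
    except Exception as exc:  # plug-in failure -> empty map, state failed
        logger.warning("mapper failed on %s: %s", getattr(record, "source_id", "?"), exc)
        return AtomMap()


# ---------------------------------------------------------------------------
# resonance combination selection


def select_resonance_combination(record, mapper: Callable | None = None):
    """Map every combination of per-molecule resonance structures; keep the one
    with the fewest atoms whose connectivity changed (first on ties)."""
    from .io import ReactionRecord  # local import to avoid a cycle

    r_variants = [enumerate_resonance_flagged(m)[0] for m in record.reactants]
    p_variants = [enumerate_resonance_flagged(m)[0] for m in record.products]
    n_combos = 1
    for v in r_variants + p_variants:
        n_combos *= len(v)
    if n_combos > COMBINATION_CAP:
        logger.warning(
            "resonance combinations (%d) exceed cap on %s; using input structures",
            n_combos,
            getattr(record, "source_id", "?"),
        )
        r_variants = [[m] for m in record.reactants]
        p_variants = [[m] for m in record.products]

    best = None  # (count, record_variant, amap)
    for r_combo in iproduct(*r_variants):
        for p_combo in iproduct(*p_variants):
            variant = ReactionRecord(
                reactants=[m.copy() for m in r_combo],
                products=[m.copy() for m in p_combo],
                mapping=None,
                source_id=record.source_id,
                origin_format=record.origin_format,
            )
            amap = compute_mapping(variant, mapper)
            if validate_mapping(variant, amap).state != "complete":
                continue
            n = count_changed_atoms(variant.reactants, variant.products, amap)
            if best is None or n < best[0]:
                best = (n, variant, amap)
    if best is None:
        variant = ReactionRecord(
            reactants=[m.copy() for m in record.reactants],
            products=[m.copy() for m in record.products],
            mapping=None,
            source_id=record.source_id,
            origin_format=record.origin_format,
        )
        return variant, compute_mapping(variant, mapper)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# heuristic completion of symmetric gaps


def _unmapped(record, amap: AtomMap) -> tuple[list[Site], list[Site]]:
    r_un = [s for s in all_sites(record.reactants) if s not in amap.pairs]
    mapped_p = set(amap.pairs.values())
    p_un = [s for s in all_sites(record.products) if s not in mapped_p]
    return r_un, p_un


def _retained_neighbors(record, pairs: dict[Site, Site], r: Site, p: Site) -> int:
    """Number of (neighbor, bond) relations preserved if r is mapped to p."""
    score = 0
    for n in record.reactants[r[0]].neighbors(r[1]):
        cp = pairs.get((r[0], n))
        if cp is None or cp[0] != p[0]:
            continue
        pb = record.products[p[0]].bond_between(p[1], cp[1])
        rb = record.reactants[r[0]].bond_between(r[1], n)
        if pb is not None and pb.order == rb.order:
            score += 1
    return score


def complete_symmetric_gap(record, partial: AtomMap) -> tuple[AtomMap, MappingStatus]:
    """Fill a two-atom mapping gap when the unmapped atoms are symmetric.

    Fires only when exactly two reactant atoms and two product atoms of one
    element are unmapped and the two atoms on at least one side (reactants
    checked first) sit in identical chemical surroundings.  The assignment
    retaining the most mapped neighbors wins; remaining ties fall back to
    canonical order.  Any other unmapped pattern is left untouched.
    """
    status = validate_mapping(record, partial)
    if status.state in ("complete", "failed"):
        return partial, status
    r_un, p_un = _unmapped(record, partial)
    if len(partial.pairs) == 0:
        return partial, MappingStatus("failed", "no atoms mapped; cannot complete")
    if len(r_un) != 2 or len(p_un) != 2:
        return partial, MappingStatus(
            "incomplete", f"{len(r_un)} unmapped reactant atoms; cannot complete"
        )
    elems_r = {site_element(record.reactants, s) for s in r_un}
    elems_p = {site_element(record.products, s) for s in p_un}
    if len(elems_r) != 1 or elems_r != elems_p:
        return partial, MappingStatus("incomplete", "unmapped atoms differ in element")
    (ra, rb), (pa, pb) = r_un, p_un
    sym_r = environments_identical(
        record.reactants[ra[0]], ra[1], record.reactants[rb[0]], rb[1]
    )
    sym_p = environments_identical(
        record.products[pa[0]], pa[1], record.products[pb[0]], pb[1]
    )
    if not (sym_r or sym_p):
        return partial, MappingStatus(
            "incomplete", "unmapped atoms are not chemically identical on either side"
        )
    assignments = [((ra, pa), (rb, pb)), ((ra, pb), (rb, pa))]
    scored = []
    for assign in assignments:
        score = sum(_retained_neighbors(record, partial.pairs, r, p) for r, p in assign)
        scored.append((score, assign))
    scored.sort(key=lambda t: -t[0])
    out = partial.copy()
    for r, p in scored[0][1]:
        out.add(r, p)
    final = validate_mapping(record, out)
    if final.state != "complete":
        return partial, MappingStatus("incomplete", "completion did not close the map")
    return out, MappingStatus("heuristically_completed", "symmetric two-atom gap filled")
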