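"""Molecular graph model with explicit hydrogens, radicals and localized bonds.

The internal representation is deliberately simple: a :class:`Molecule` is a
list of :class:`Atom` and :class:`Bond` objects with all hydrogens explicit
and all bond orders localized (Kekulé form).  RDKit is used at the boundaries
for identifier parsing, canonical keys and SMARTS emission; everything that
has to reason about *changes* (mapping, extraction) works on this graph.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import networkx as nx
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

RDLogger.DisableLog("rdApp.*")

#: default caps for resonance enumeration
RESONANCE_CAP = 16

_STANDARD_VALENCE = {
    "H": 1, "C": 4, "N": 3, "O": 2, "F": 1, "Cl": 1, "Br": 1, "I": 1,
    "S": 2, "P": 3, "Si": 4, "B": 3,
}


@dataclass
class Atom:
    """A single atom: element symbol, charge, unpaired electron count, stereo."""

    element: str
    formal_charge: int = 0
    unpaired_electrons: int = 0
    stereo: Optional[str] = None  # 'R'/'S'
    index: int = -1

    def copy(self) -> "Atom":
        return replace(self)


@dataclass
class Bond:
    """Bond between two atom indices with a localized integer order."""

    i: int
    j: int
    order: int = 1
    stereo: Optional[str] = None  # 'E'/'Z'

    def key(self) -> tuple[int, int]:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)

    def other(self, idx: int) -> int:
        return self.j if idx == self.i else self.i

    def copy(self) -> "Bond":
        return replace(self)


@dataclass(frozen=True)
class MoleculeKey:
    """Canonical identity of a molecule."""

    key: str
    scheme: str  # 'inchi' | 'fingerprint_fallback'


class Molecule:
    """Connected molecular graph; one molecule per instance, explicit H."""

    def __init__(self, atoms: Iterable[Atom] = (), bonds: Iterable[Bond] = ()):
        self.atoms: list[Atom] = []
        self.bonds: list[Bond] = []
        self._bond_index: dict[tuple[int, int], Bond] = {}
        for a in atoms:
            self.add_atom(a)
        for b in bonds:
            self.add_bond(b)

    # -- construction -----------------------------------------------------

    def add_atom(self, atom: Atom) -> int:
        atom = atom.copy()
        atom.index = len(self.atoms)
        self.atoms.append(atom)
        return atom.index

    def add_bond(self, bond: Bond) -> Bond:
        if bond.i == bond.j:
            raise ValueError("bond endpoints must be distinct")
        bond = bond.copy()
        k = bond.key()
        if k in self._bond_index:
            raise ValueError(f"duplicate bond {k}")
        self.bonds.append(bond)
        self._bond_index[k] = bond
        return bond

    def remove_bond(self, i: int, j: int) -> None:
        k = (i, j) if i < j else (j, i)
        b = self._bond_index.pop(k)
        self.bonds.remove(b)

    def copy(self) -> "Molecule":
        return Molecule(self.atoms, self.bonds)

    # -- queries ----------------------------------------------------------

    def bond_between(self, i: int, j: int) -> Optional[Bond]:
        return self._bond_index.get((i, j) if i < j else (j, i))

    def neighbors(self, idx: int) -> list[int]:
        return [b.other(idx) for b in self.bonds if idx in (b.i, b.j)]

    def degree(self, idx: int) -> int:
        return len(self.neighbors(idx))

    def valence(self, idx: int) -> int:
        """Sum of bond orders at an atom (explicit-H convention)."""
        return sum(b.order for b in self.bonds if idx in (b.i, b.j))

    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.atoms if a.element != "H")

    def element_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for a in self.atoms:
            out[a.element] = out.get(a.element, 0) + 1
        return out

    def net_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)

    def total_unpaired(self) -> int:
        return sum(a.unpaired_electrons for a in self.atoms)

    def is_connected(self) -> bool:
        if len(self.atoms) <= 1:
            return True
        return nx.is_connected(self.to_networkx())

    def is_valence_valid(self) -> bool:
        """Lenient octet check against standard valences.

        Unknown elements and hypervalent S/N/P patterns are accepted; the
        check exists to reject obviously broken edits (pentavalent carbon).
        """
        for a in self.atoms:
            std = _STANDARD_VALENCE.get(a.element)
            if std is None:
                continue
            if a.element == "C":
                allowed = {std - abs(a.formal_charge)}
            else:
                allowed = {std + a.formal_charge}
            if a.element in ("S", "P", "N") and a.formal_charge == 0:
                allowed |= {std + 2, std + 4}
            if self.valence(a.index) + a.unpaired_electrons not in allowed:
                return False
        return True

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for a in self.atoms:
            g.add_node(
                a.index,
                element=a.element,
                charge=a.formal_charge,
                unpaired=a.unpaired_electrons,
            )
        for b in self.bonds:
            g.add_edge(b.i, b.j, order=b.order)
        return g

    def state_signature(self) -> tuple:
        """Exact per-index state; used to dedup resonance structures."""
        return (
            tuple((a.element, a.formal_charge, a.unpaired_electrons) for a in self.atoms),
            tuple(sorted((b.key(), b.order) for b in self.bonds)),
        )

    # -- RDKit bridge -----------------------------------------------------

    def to_rdkit(self, sanitize: bool = True) -> Chem.Mol:
        rw = Chem.RWMol()
        for a in self.atoms:
            ra = Chem.Atom(a.element)
            ra.SetFormalCharge(a.formal_charge)
            ra.SetNumRadicalElectrons(a.unpaired_electrons)
            ra.SetNoImplicit(True)
            rw.AddAtom(ra)
        orders = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
        for b in self.bonds:
            rw.AddBond(b.i, b.j, orders[b.order])
        mol = rw.GetMol()
        if sanitize:
            try:
                Chem.SanitizeMol(mol)
            except Exception:
                Chem.SanitizeMol(
                    mol,
                    Chem.SanitizeFlags.SANITIZE_ALL
                    ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES,
                )
        return mol

    @classmethod
    def from_rdkit(cls, rdmol: Chem.Mol) -> "Molecule":
        rdmol = Chem.Mol(rdmol)
        try:
            Chem.Kekulize(rdmol, clearAromaticFlags=True)
        except Exception:
            pass
        Chem.AssignStereochemistry(rdmol, cleanIt=True, force=True)
        mol = cls()
        for ra in rdmol.GetAtoms():
            stereo = None
            if ra.HasProp("_CIPCode"):
                stereo = ra.GetProp("_CIPCode")
            mol.add_atom(
                Atom(
                    element=ra.GetSymbol(),
                    formal_charge=ra.GetFormalCharge(),
                    unpaired_electrons=ra.GetNumRadicalElectrons(),
                    stereo=stereo,
                )
            )
        order_of = {
            Chem.BondType.SINGLE: 1,
            Chem.BondType.DOUBLE: 2,
            Chem.BondType.TRIPLE: 3,
            Chem.BondType.AROMATIC: 1,  # unreachable after Kekulize
        }
        for rb in rdmol.GetBonds():
            stereo = None
            if rb.GetStereo() == Chem.BondStereo.STEREOE:
                stereo = "E"
            elif rb.GetStereo() == Chem.BondStereo.STEREOZ:
                stereo = "Z"
            mol.add_bond(
                Bond(
                    rb.GetBeginAtomIdx(),
                    rb.GetEndAtomIdx(),
                    order_of.get(rb.GetBondType(), 1),
                    stereo=stereo,
                )
            )
        return mol

    @classmethod
    def from_smiles(cls, smiles: str) -> "Molecule":
        rdmol = Chem.MolFromSmiles(smiles)
        if rdmol is None:
            raise ValueError(f"unparsable SMILES: {smiles!r}")
        return cls.from_rdkit(Chem.AddHs(rdmol))

    @classmethod
    def from_inchi(cls, inchi: str) -> "Molecule":
        rdmol = Chem.MolFromInchi(inchi)
        if rdmol is None:
            raise ValueError(f"unparsable InChI: {inchi!r}")
        return cls.from_rdkit(Chem.AddHs(rdmol))

    @classmethod
    def from_identifier(cls, ident: str) -> "Molecule":
        ident = ident.strip()
        if ident.startswith("InChI="):
            return cls.from_inchi(ident)
        return cls.from_smiles(ident)

    def to_smiles(self) -> str:
        return Chem.MolToSmiles(self.to_rdkit())

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:  # pragma: no cover
        try:
            return f"Molecule({self.to_smiles()})"
        except Exception:
            return f"Molecule({len(self.atoms)} atoms)"


# ---------------------------------------------------------------------------
# canonical identity


def canonical_key(mol: Molecule) -> MoleculeKey:
    """Canonical identifier; InChI with an explicit radical layer appended.

    Standard InChI does not reliably separate all radical states (e.g. singlet
    vs. triplet carbenes), so per-element unpaired-electron counts are appended
    as an extra layer.  When InChI generation fails the canonical SMILES is
    hashed as a fingerprint fallback.
    """
    rad_layer = ""
    if mol.total_unpaired():
        counts: dict[str, int] = {}
        for a in mol.atoms:
            if a.unpaired_electrons:
                counts[a.element] = counts.get(a.element, 0) + a.unpaired_electrons
        rad_layer = "/u" + ".".join(f"{el}{n}" for el, n in sorted(counts.items()))
    try:
        rdmol = mol.to_rdkit()
        inchi = Chem.MolToInchi(rdmol, treatWarningAsError=False)
        if inchi:
            return MoleculeKey(inchi + rad_layer, "inchi")
    except Exception:
        pass
    try:
        smi = mol.to_smiles()
    except Exception:
        smi = repr(sorted(mol.state_signature()[0]))
    digest = hashlib.sha1((smi + rad_layer).encode()).hexdigest()
    return MoleculeKey(digest, "fingerprint_fallback")


def molecules_equal(a: Molecule, b: Molecule) -> bool:
    return canonical_key(a) == canonical_key(b)


# ---------------------------------------------------------------------------
# resonance enumeration


def enumerate_resonance(mol: Molecule, cap: int = RESONANCE_CAP) -> list[Molecule]:
    """All localized electron arrangements reachable by allylic radical shifts.

    Moves an unpaired electron across a conjugated path:  a•–b=c  →  a=b–c•.
    Charged resonance and lone-pair delocalization are out of scope.  The
    input structure is always first in the result.  If more than ``cap``
    structures are found, only the input is returned and ``overflowed`` is set
    on the list via the second return convention of
    :func:`enumerate_resonance_flagged`.
    """
    structs, _ = enumerate_resonance_flagged(mol, cap)
    return structs


def enumerate_resonance_flagged(
    mol: Molecule, cap: int = RESONANCE_CAP
) -> tuple[list[Molecule], bool]:
    seen = {mol.state_signature()}
    out = [mol.copy()]
    queue = [mol.copy()]
    while queue:
        cur = queue.pop(0)
        for a in cur.atoms:
            if a.unpaired_electrons < 1:
                continue
            for b_idx in cur.neighbors(a.index):
                ab = cur.bond_between(a.index, b_idx)
                if ab.order != 1:
                    continue
                for c_idx in cur.neighbors(b_idx):
                    if c_idx == a.index:
                        continue
                    bc = cur.bond_between(b_idx, c_idx)
                    if bc.order < 2:
                        continue
                    nxt = cur.copy()
                    nxt.bond_between(a.index, b_idx).order += 1
                    nxt.bond_between(b_idx, c_idx).order -= 1
                    nxt.atoms[a.index].unpaired_electrons -= 1
                    nxt.atoms[c_idx].unpaired_electrons += 1
                    sig = nxt.state_signature()
                    if sig in seen:
                        continue
                    seen.add(sig)
                    out.append(nxt)
                    queue.append(nxt)
                    if len(out) > cap:
                        return [mol.copy()], True
    return out, False


def resonance_invariant_key(mol: Molecule) -> MoleculeKey:
    """A key shared by all resonance structures of ``mol`` (minimum over forms)."""
    keys = [canonical_key(m) for m in enumerate_resonance(mol)]
    return min(keys, key=lambda k: (k.scheme, k.key))


# ---------------------------------------------------------------------------
# subgraph radius & chemically-identical environments


def subgraph_radius(mol: Molecule, root: int) -> int:
    """Bonds needed before the shell rooted at ``root`` covers the molecule."""
    if root < 0 or root >= len(mol.atoms):
        raise IndexError(f"atom {root} not in molecule")
    dist = nx.single_source_shortest_path_length(mol.to_networkx(), root)
    return max(dist.values())


def _shell_members(mol: Molecule, root: int, radius: int) -> set[int]:
    dist = nx.single_source_shortest_path_length(mol.to_networkx(), root)
    return {i for i, d in dist.items() if d <= radius}


def _rooted_shell_graph(mol: Molecule, root: int, radius: int) -> nx.Graph:
    members = _shell_members(mol, root, radius)
    g = mol.to_networkx().subgraph(members).copy()
    for n in g.nodes:
        g.nodes[n]["is_root"] = n == root
    return g


def _node_match(n1: dict, n2: dict) -> bool:
    return (
        n1["element"] == n2["element"]
        and n1["charge"] == n2["charge"]
        and n1["unpaired"] == n2["unpaired"]
        and n1["is_root"] == n2["is_root"]
    )


def _edge_match(e1: dict, e2: dict) -> bool:
    return e1["order"] == e2["order"]


def _shells_isomorphic(
    molA: Molecule, a: int, molB: Molecule, b: int, radius: int
) -> bool:
    ga = _rooted_shell_graph(molA, a, radius)
    gb = _rooted_shell_graph(molB, b, radius)
    return nx.is_isomorphic(ga, gb, node_match=_node_match, edge_match=_edge_match)


def environments_identical(molA: Molecule, a: int, molB: Molecule, b: int) -> bool:
    """True iff the two atoms sit in identical chemical surroundings.

    Same molecule object: the molecule must have the same radius relative to
    both atoms and every shell of radius ``r - i`` (i = 1..r) around each atom
    must be isomorphic (a symmetry axis between the atoms).  Different
    molecules: every shell of radius ``r - i`` (i = 0..r) must be isomorphic
    (same position in two identical molecules).
    """
    atomA, atomB = molA.atoms[a], molB.atoms[b]
    if atomA.element != atomB.element:
        return False
    r_a = subgraph_radius(molA, a)
    r_b = subgraph_radius(molB, b)
    if molA is molB:
        if a == b:
            return True
        if r_a != r_b:
            return False
        return all(_shells_isomorphic(molA, a, molB, b, r_a - i) for i in range(1, r_a + 1))
    if r_a != r_b:
        return False
    return all(_shells_isomorphic(molA, a, molB, b, r_a - i) for i in range(0, r_a + 1))


# ---------------------------------------------------------------------------
# canonical atom ranks (deterministic tie-breaking everywhere)


def canonical_ranks(mol: Molecule) -> list[int]:
    """Stable canonical rank per atom (RDKit canonical ranking, H included)."""
    try:
        rdmol = mol.to_rdkit()
        return list(Chem.CanonicalRankAtoms(rdmol, breakTies=True))
    except Exception:
        order = sorted(
            range(len(mol.atoms)),
            key=lambda i: (mol.atoms[i].element, mol.degree(i), i),
        )
        ranks = [0] * len(mol.atoms)
        for r, i in enumerate(order):
            ranks[i] = r
        return ranks
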