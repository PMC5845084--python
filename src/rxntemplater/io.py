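"""Reaction ingestion and serialization.

Three database formats are read: plain identifier lists (SMILES/InChI per
reaction), directories of MDL RXN (V2000) files, and CHEMKIN mechanism files
whose species declarations carry an InChI or SMILES comment.  Corpora are
persisted as an ``.rxnd`` bundle: a directory of mapped RXN files plus a JSON
index, so every pipeline stage can be inspected and re-run independently.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from rdkit import Chem

from .chem import Molecule
from .mapping import AtomMap, Site, all_sites

logger = logging.getLogger(__name__)


@dataclass
class ReactionRecord:
    reactants: list[Molecule]
    products: list[Molecule]
    mapping: Optional[AtomMap] = None
    source_id: str = ""
    origin_format: str = ""  # identifier_list | rxn | chemkin | synthetic

    def __post_init__(self):
        if not self.reactants or not self.products:
            raise ValueError("a reaction needs at least one reactant and one product")


@dataclass
class Corpus:
    records: list[ReactionRecord] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.source_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("source_id not unique within corpus")

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# identifier lists

SIDE_DELIMITER = " >> "


def read_identifier_list(path: str | Path, delimiter: str = SIDE_DELIMITER) -> Corpus:
    """One reaction per line: identifiers joined by ``+`` or ``.``, sides split
    by ``>>``.  SMILES and InChI may be mixed; bad lines are skipped."""
    path = Path(path)
    records: list[ReactionRecord] = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if delimiter.strip() not in line:
            logger.warning("%s:%d: no reaction delimiter; skipped", path.name, ln)
            continue
        lhs, rhs = line.split(delimiter.strip(), 1)
        try:
            reactants = [_parse_identifier(t) for t in _split_side(lhs)]
            products = [_parse_identifier(t) for t in _split_side(rhs)]
            records.append(
                ReactionRecord(
                    reactants, products, None, f"{path.name}:{ln}", "identifier_list"
                )
            )
        except ValueError as exc:
            logger.warning("%s:%d: %s; skipped", path.name, ln, exc)
    return Corpus(records, [str(path)])


def _split_side(side: str) -> list[str]:
    tokens: list[str] = []
    for part in re.split(r"\s\+\s", side.strip()):
        part = part.strip()
        if not part:
            raise ValueError("empty species token")
        # '.' also separates species within a side (SMILES mixture notation),
        # but never inside an InChI
        if part.startswith("InChI="):
            tokens.append(part)
        else:
            tokens.extend(p for p in part.split(".") if p)
    if not tokens:
        raise ValueError("empty reaction side")
    return tokens


def _parse_identifier(token: str) -> Molecule:
    mol = Molecule.from_identifier(token)
    if not mol.is_connected():
        raise ValueError(f"identifier {token!r} is not a single connected molecule")
    return mol


# ---------------------------------------------------------------------------
# MDL RXN (V2000)


def write_rxn(record: ReactionRecord, path: str | Path) -> None:
    """V2000 RXN with 1-based atom-map indices when a mapping is present."""
    path = Path(path)
    map_nums: dict[tuple[str, Site], int] = {}
    if record.mapping is not None:
        for k, (r, p) in enumerate(sorted(record.mapping.pairs.items()), start=1):
            map_nums[("r", r)] = k
            map_nums[("p", p)] = k
    blocks = []
    for side, mols in (("r", record.reactants), ("p", record.products)):
        for mi, mol in enumerate(mols):
            rdmol = mol.to_rdkit()
            for atom in rdmol.GetAtoms():
                atom.SetAtomMapNum(map_nums.get((side, (mi, atom.GetIdx())), 0))
            blocks.append(Chem.MolToMolBlock(rdmol, kekulize=True))
    lines = [
        "$RXN",
        record.source_id,
        "  rxntemplater",
        "",
        f"{len(record.reactants):>3d}{len(record.products):>3d}",
    ]
    for b in blocks:
        lines.append("$MOL")
        lines.append(b.rstrip("\n"))
    path.write_text("\n".join(lines) + "\n")


def _read_rxn_file(path: Path) -> ReactionRecord:
    text = path.read_text()
    if not text.startswith("$RXN"):
        raise ValueError("missing $RXN header")
    header, *mol_texts = text.split("$MOL\n")
    counts_line = header.rstrip("\n").splitlines()[4]
    n_r, n_p = int(counts_line[:3]), int(counts_line[3:6])
    if len(mol_texts) != n_r + n_p:
        raise ValueError(
            f"counts line declares {n_r}+{n_p} molecules, found {len(mol_texts)}"
        )
    mols: list[Molecule] = []
    mapnums: list[dict[int, int]] = []  # per molecule: atom index -> map number
    for mt in mol_texts:
        rdmol = Chem.MolFromMolBlock(mt, sanitize=True, removeHs=False)
        if rdmol is None:
            raise ValueError("malformed mol block")
        nums = {a.GetIdx(): a.GetAtomMapNum() for a in rdmol.GetAtoms()}
        for a in rdmol.GetAtoms():
            a.SetAtomMapNum(0)
        mols.append(Molecule.from_rdkit(rdmol))
        mapnums.append(nums)
    reactants, products = mols[:n_r], mols[n_r:]
    r_nums: dict[int, Site] = {}
    p_nums: dict[int, Site] = {}
    for mi in range(n_r):
        for ai, num in mapnums[mi].items():
            if num > 0:
                r_nums[num] = (mi, ai)
    for mi in range(n_p):
        for ai, num in mapnums[n_r + mi].items():
            if num > 0:
                p_nums[num] = (mi, ai)
    mapping = None
    shared = set(r_nums) & set(p_nums)
    if shared:
        mapping = AtomMap()
        for num in sorted(shared):
            mapping.add(r_nums[num], p_nums[num])
    return ReactionRecord(reactants, products, mapping, path.stem, "rxn")


def read_rxn_directory(path: str | Path) -> Corpus:
    path = Path(path)
    records: list[ReactionRecord] = []
    for f in sorted(path.glob("*.rxn")):
        try:
            records.append(_read_rxn_file(f))
        except (ValueError, IndexError) as exc:
            logger.warning("%s: %s; skipped", f.name, exc)
    return Corpus(records, [str(path)])


# ---------------------------------------------------------------------------
# CHEMKIN mechanisms

_ARRHENIUS_TAIL = re.compile(r"\s+[-+0-9.eEdD]+\s+[-+0-9.eEdD]+\s+[-+0-9.eEdD]+\s*$")
_AUX_KEYWORDS = ("LOW", "TROE", "SRI", "PLOG", "REV", "DUP", "FORD", "RORD", "HIGH")


class ChemkinError(ValueError):
    pass


def read_chemkin(path: str | Path) -> Corpus:
    """Interpret a CHEMKIN mechanism; species identities come exclusively from
    the ``!`` identifier comments, never from the species names."""
    path = Path(path)
    species: dict[str, Molecule] = {}
    records: list[ReactionRecord] = []
    block = None
    rxn_no = 0
    for raw in path.read_text().splitlines():
        line = raw.rstrip()
        stripped = line.strip()
        if not stripped:
            continue
        upper = stripped.upper()
        code = upper.split("!", 1)[0].strip()
        if code.startswith(("ELEMENTS", "ELEM")):
            block = "elements"
            continue
        if code.startswith(("SPECIES", "SPEC")):
            block = "species"
            continue
        if code.startswith(("REACTIONS", "REAC")):
            block = "reactions"
            continue
        if code == "END":
            block = None
            continue
        if block == "species":
            _parse_species_line(stripped, species, path)
        elif block == "reactions":
            body = stripped.split("!", 1)[0].strip()
            if not body:
                continue
            if any(body.upper().startswith(k) for k in _AUX_KEYWORDS) or body.startswith("/"):
                continue  # pressure-dependence / auxiliary sub-blocks
            if "=" not in body:
                continue
            rxn_no += 1
            rec = _parse_reaction_line(body, species, f"{path.stem}:R{rxn_no}")
            if rec is not None:
                records.append(rec)
    return Corpus(records, [str(path)])


def _parse_species_line(line: str, species: dict[str, Molecule], path: Path) -> None:
    if "!" in line:
        names_part, comment = line.split("!", 1)
        names = names_part.split()
        ident = comment.strip()
        if len(names) > 1:
            raise ChemkinError(
                f"{path.name}: one identifier comment for several species: {names}"
            )
        if names:
            if not ident:
                raise ChemkinError(
                    f"{path.name}: species {names[0]!r} has an empty identifier comment"
                )
            species[names[0]] = Molecule.from_identifier(ident)
        return
    names = line.split()
    if names:
        raise ChemkinError(
            f"{path.name}: species without identifier comment: {', '.join(names)}"
        )


def _parse_reaction_line(
    body: str, species: dict[str, Molecule], source_id: str
) -> Optional[ReactionRecord]:
    eqn = _ARRHENIUS_TAIL.sub("", body).strip()
    for arrow in ("<=>", "=>", "="):
        if arrow in eqn:
            lhs, rhs = eqn.split(arrow, 1)
            break
    else:
        return None
    try:
        reactants = _parse_chemkin_side(lhs, species)
        products = _parse_chemkin_side(rhs, species)
        if not reactants or not products:
            raise KeyError("side reduced to third bodies only")
        return ReactionRecord(reactants, products, None, source_id, "chemkin")
    except KeyError as exc:
        logger.warning("%s: unknown species %s; skipped", source_id, exc)
        return None


def _parse_chemkin_side(side: str, species: dict[str, Molecule]) -> list[Molecule]:
    side = re.sub(r"\(\+\s*M\s*\)", "", side, flags=re.IGNORECASE)
    mols: list[Molecule] = []
    for token in side.split("+"):
        token = token.strip()
        if not token or token.upper() == "M":
            continue  # third body
        mult = 1
        name = token
        if token not in species:
            m = re.match(r"^(\d+)(.+)$", token)
            if m and m.group(2) in species:
                mult, name = int(m.group(1)), m.group(2)
            else:
                raise KeyError(token)
        mols.extend(species[name].copy() for _ in range(mult))
    return mols


# ---------------------------------------------------------------------------
# filters


def filter_unbalanced(corpus: Corpus) -> tuple[Corpus, list[dict]]:
    """Keep records whose element multisets (explicit H included) and net
    charges agree on both sides; rejected ids come back with their tallies."""
    kept, report = [], []
    for rec in corpus.records:
        r_tally: dict[str, int] = {}
        p_tally: dict[str, int] = {}
        for m in rec.reactants:
            for el, n in m.element_counts().items():
                r_tally[el] = r_tally.get(el, 0) + n
        for m in rec.products:
            for el, n in m.element_counts().items():
                p_tally[el] = p_tally.get(el, 0) + n
        r_charge = sum(m.net_charge() for m in rec.reactants)
        p_charge = sum(m.net_charge() for m in rec.products)
        if r_tally == p_tally and r_charge == p_charge:
            kept.append(rec)
        else:
            diff = {
                el: r_tally.get(el, 0) - p_tally.get(el, 0)
                for el in set(r_tally) | set(p_tally)
                if r_tally.get(el, 0) != p_tally.get(el, 0)
            }
            if r_charge != p_charge:
                diff["charge"] = r_charge - p_charge
            report.append({"source_id": rec.source_id, "imbalance": diff})
    return Corpus(kept, corpus.provenance), report


def filter_arity(corpus: Corpus, max_reactants: int = 2) -> Corpus:
    if max_reactants < 1:
        raise ValueError("max_reactants must be >= 1")
    kept = [r for r in corpus.records if len(r.reactants) <= max_reactants]
    return Corpus(kept, corpus.provenance)


# ---------------------------------------------------------------------------
# rxnd bundles (directory of RXN files + JSON index)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    index = {"provenance": corpus.provenance, "records": []}
    for k, rec in enumerate(corpus.records):
        fname = f"r{k:06d}.rxn"
        write_rxn(rec, path / fname)
        index["records"].append(
            {"file": fname, "source_id": rec.source_id, "origin_format": rec.origin_format}
        )
    (path / "index.json").write_text(json.dumps(index, indent=1))


def read_corpus(path: str | Path) -> Corpus:
    path = Path(path)
    index = json.loads((path / "index.json").read_text())
    records = []
    for entry in index["records"]:
        rec = _read_rxn_file(path / entry["file"])
        rec.source_id = entry["source_id"]
        rec.origin_format = entry["origin_format"]
        records.append(rec)
    return Corpus(records, index.get("provenance", []))
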