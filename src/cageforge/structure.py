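"""Structure data model and PDB I/O.

A :class:`Structure` is a flat list of atoms grouped into residues and
chains, with optional entity groups recording which chains are copies of
the same protein.  All coordinates are in Angstrom.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np

from ._tables import BACKBONE_ATOMS, NONCANONICAL_MAP, THREE_TO_ONE


class PDBFormatError(ValueError):
    """Raised for an unparseable ATOM/HETATM record; carries the line number."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    res_name: str
    chain_id: str
    res_seq: int
    icode: str
    xyz: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def polar(self) -> bool:
        """N, O and S atoms are polar; carbons (and everything else) apolar."""
        return self.element in ("N", "O", "S")

    def copy(self) -> "Atom":
        a = _copy.copy(self)
        a.xyz = self.xyz.copy()
        return a


@dataclass
class Residue:
    """A group of atoms sharing (chain, author number, insertion code)."""

    name: str
    chain_id: str
    number: int
    icode: str
    atom_indices: list = field(default_factory=list)
    _structure: "Structure" = None

    @property
    def atoms(self):
        return [self._structure.atoms[i] for i in self.atom_indices]

    @property
    def one_letter(self) -> str:
        name = NONCANONICAL_MAP.get(self.name, self.name)
        return THREE_TO_ONE.get(name, "X")

    def atom(self, name: str):
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def has_backbone(self) -> bool:
        present = {a.name for a in self.atoms}
        return all(n in present for n in ("N", "CA", "C"))

    def cbeta(self) -> np.ndarray:
        """C-beta coordinate; glycine (or a missing CB) falls back to CA."""
        a = self.atom("CB")
        if a is None:
            a = self.atom("CA")
        if a is None:
            raise ValueError(f"residue {self.chain_id}{self.number} has no CB/CA")
        return a.xyz

    def backbone_coords(self) -> np.ndarray:
        """(4, 3) array of N, CA, C, O coordinates."""
        out = np.empty((4, 3))
        for i, name in enumerate(BACKBONE_ATOMS):
            a = self.atom(name)
            if a is None:
                raise ValueError(
                    f"residue {self.chain_id}{self.number} missing backbone atom {name}"
                )
            out[i] = a.xyz
        return out

    @property
    def key(self):
        return (self.chain_id, self.number, self.icode)


class Structure:
    """Atoms, residues, chains and entity groups.

    Parameters
    ----------
    atoms
        Atom records in file order.  Residues are derived by grouping
        consecutive atoms with the same (chain, number, icode).
    entities
        Optional mapping of entity name -> list of chain ids marking
        chains that are copies of the same protein.  Defaults to one
        entity holding every chain.
    """

    def __init__(self, atoms, entities=None, name: str = ""):
        self.atoms: list[Atom] = list(atoms)
        self.name = name
        self._build_residues()
        if entities is None:
            entities = {"1": list(self.chain_ids)}
        self.entities = {k: list(v) for k, v in entities.items()}

    # -- construction ---------------------------------------------------

    def _build_residues(self):
        self.residues: list[Residue] = []
        current = None
        for i, a in enumerate(self.atoms):
            key = (a.chain_id, a.res_seq, a.icode)
            if current is None or current.key != key:
                current = Residue(a.res_name, a.chain_id, a.res_seq, a.icode, [], self)
                self.residues.append(current)
            current.atom_indices.append(i)

    # -- views ----------------------------------------------------------

    @property
    def chain_ids(self):
        seen = []
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.append(a.chain_id)
        return seen

    def chain_residues(self, chain_id: str):
        return [r for r in self.residues if r.chain_id == chain_id]

    @property
    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.empty((0, 3))
        return np.array([a.xyz for a in self.atoms])

    @coords.setter
    def coords(self, xyz: np.ndarray):
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, row in zip(self.atoms, xyz):
            a.xyz = row.copy()

    def sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.chain_residues(chain_id))

    def entity_of_chain(self, chain_id: str):
        for name, chains in self.entities.items():
            if chain_id in chains:
                return name
        return None

    # -- manipulation ---------------------------------------------------

    def copy(self) -> "Structure":
        return Structure([a.copy() for a in self.atoms],
                         entities={k: list(v) for k, v in self.entities.items()},
                         name=self.name)

    def transformed(self, transform) -> "Structure":
        """Return a copy with ``transform`` applied to every atom."""
        s = self.copy()
        s.coords = transform.apply(self.coords)
        return s

    def select_chains(self, chain_ids) -> "Structure":
        wanted = set(chain_ids)
        atoms = [a.copy() for a in self.atoms if a.chain_id in wanted]
        entities = {
            name: [c for c in chains if c in wanted]
            for name, chains in self.entities.items()
        }
        entities = {k: v for k, v in entities.items() if v}
        return Structure(atoms, entities=entities, name=self.name)

    def renumber_serials(self):
        for i, a in enumerate(self.atoms, start=1):
            a.serial = i

    @staticmethod
    def concatenate(parts, entity_names=None) -> "Structure":
        """Merge structures; chain ids are relabelled to stay unique."""
        alphabet = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
                    "abcdefghijklmnopqrstuvwxyz0123456789")
        atoms, entities = [], {}
        mappings = []
        next_idx = 0
        for pi, part in enumerate(parts):
            mapping = {}
            mappings.append(mapping)
            for cid in part.chain_ids:
                if next_idx >= len(alphabet):
                    raise ValueError("too many chains to relabel")
                mapping[cid] = alphabet[next_idx]
                next_idx += 1
            for a in part.atoms:
                b = a.copy()
                b.chain_id = mapping[a.chain_id]
                atoms.append(b)
            ename = entity_names[pi] if entity_names else str(pi + 1)
            for orig_ent, chains in part.entities.items():
                key = f"{ename}" if len(part.entities) == 1 else f"{ename}.{orig_ent}"
                entities.setdefault(key, []).extend(mapping[c] for c in chains)
        s = Structure(atoms, entities=entities)
        s.chain_maps = mappings
        s.renumber_serials()
        return s

    def __len__(self):
        return len(self.atoms)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    stripped = name.strip()
    if not stripped:
        return "C"
    if stripped[0].isdigit():
        stripped = stripped.lstrip("0123456789")
    return stripped[:1].upper()


def parse_pdb(text: str, name: str = "") -> tuple[Structure, list]:
    """Parse ATOM/HETATM records into a Structure.

    Alternate locations are resolved to the highest-occupancy conformer.
    Returns ``(structure, warnings)`` where warnings lists residues with
    missing backbone atoms.
    """
    raw = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec not in ("ATOM  ", "HETATM"):
            continue
        try:
            serial = int(line[6:11])
            atom_name = line[12:16].strip()
            altloc = line[16].strip()
            res_name = line[17:20].strip()
            chain_id = line[21].strip() or "A"
            res_seq = int(line[22:26])
            icode = line[26].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ_field = line[54:60].strip()
            occupancy = float(occ_field) if occ_field else 1.0
            element = line[76:78].strip() if len(line) >= 78 else ""
        except (ValueError, IndexError) as exc:
            raise PDBFormatError(f"unparseable record at line {lineno}: {exc}") from exc
        element = element.upper() or _guess_element(atom_name)
        raw.append(Atom(serial, atom_name, element, res_name, chain_id,
                        res_seq, icode, np.array([x, y, z]), occupancy, altloc))

    # altloc resolution: keep highest occupancy per (residue key, atom name)
    best = {}
    order = []
    for a in raw:
        key = (a.chain_id, a.res_seq, a.icode, a.name)
        if key not in best:
            best[key] = a
            order.append(key)
        elif a.occupancy > best[key].occupancy:
            best[key] = a
    atoms = [best[k] for k in order]
    for a in atoms:
        a.altloc = ""

    # entity grouping by identical chain sequence
    s = Structure(atoms, entities={}, name=name)
    seq_to_entity, entities = {}, {}
    for cid in s.chain_ids:
        seq = s.sequence(cid)
        if seq not in seq_to_entity:
            seq_to_entity[seq] = str(len(seq_to_entity) + 1)
        entities.setdefault(seq_to_entity[seq], []).append(cid)
    s.entities = entities

    warnings = [
        f"residue {r.chain_id}{r.number}{r.icode} missing backbone atoms"
        for r in s.residues
        if not r.has_backbone
    ]
    return s, warnings


def read_pdb(path) -> tuple[Structure, list]:
    with open(path) as fh:
        return parse_pdb(fh.read(), name=str(path))


_PDB_FMT = ("{rec:<6s}{serial:>5d} {name:<4s}{altloc:1s}{res:<3s} {chain:1s}"
            "{seq:>4d}{icode:1s}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}"
            "{b:>6.2f}          {elem:>2s}  ")


def _format_atom_name(name: str, element: str) -> str:
    # columns 13-16: element right-justified in 13-14 for 1-letter elements
    if len(element) == 1 and len(name) < 4:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(structure: Structure) -> str:
    lines = []
    serial = 0
    prev_chain = None
    for a in structure.atoms:
        if prev_chain is not None and a.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = a.chain_id
        serial += 1
        lines.append(_PDB_FMT.format(
            rec="ATOM", serial=serial % 100000,
            name=_format_atom_name(a.name, a.element), altloc="",
            res=a.res_name, chain=a.chain_id, seq=a.res_seq, icode=a.icode or "",
            x=a.xyz[0], y=a.xyz[1], z=a.xyz[2], occ=a.occupancy, b=0.0,
            elem=a.element))
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def save_pdb(structure: Structure, path):
    with open(path, "w") as fh:
        fh.write(write_pdb(structure))
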