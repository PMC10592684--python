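"""Point-group symmetry: group generators, assembly expansion and the
tetrahedral two-trimer (T:{C3}{C3}) entry."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import RigidTransform, rotation_about_axis
from .structure import Structure

_SQRT3 = np.sqrt(3.0)

# Canonical internal axes for the two C3 components of a tetrahedral
# two-component assembly: two distinct cube body diagonals.
T33_AXIS_A = np.array([1.0, 1.0, 1.0]) / _SQRT3
T33_AXIS_B = np.array([-1.0, -1.0, 1.0]) / _SQRT3

_CHAIN_ALPHABET = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
                   "abcdefghijklmnopqrstuvwxyz0123456789")


def _close_group(seed_matrices, max_order: int = 64) -> list:
    """Close a set of rotation matrices under multiplication."""
    elements = [np.eye(3)]

    def known(M):
        return any(np.allclose(M, E, atol=1e-9) for E in elements)

    frontier = [np.asarray(m, dtype=float) for m in seed_matrices]
    while frontier:
        M = frontier.pop()
        if known(M):
            continue
        elements.append(M)
        if len(elements) > max_order:
            raise ValueError("group closure exceeded maximum order")
        for E in list(elements):
            frontier.append(M @ E)
            frontier.append(E @ M)
    return elements


def _c3_generators():
    return [rotation_about_axis([0, 0, 1], a) for a in (0.0, 120.0, 240.0)]


def _t_generators():
    # C3 about the (1,1,1) diagonal (cyclic axis permutation) and C2 about z
    c3 = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    c2z = np.diag([-1.0, -1.0, 1.0])
    elements = _close_group([c3, c2z])
    if len(elements) != 12:
        raise AssertionError("tetrahedral group closure failed")
    return elements


@dataclass
class SymmetryEntry:
    """A point-group target with per-component internal axes and external
    degrees of freedom (rotation about / translation along the own axis)."""

    label: str
    generators: list = field(default_factory=list)
    component_axes: dict = field(default_factory=dict)

    def __post_init__(self):
        for g in self.generators:
            g = np.asarray(g, dtype=float)
            if not np.allclose(g @ g.T, np.eye(3), atol=1e-9):
                raise ValueError(f"non-orthonormal generator in {self.label}")
        closed = _close_group(self.generators)
        if len(closed) != len(self.generators):
            raise ValueError(
                f"generators of {self.label} do not close at the stated order"
            )

    @property
    def order(self) -> int:
        return len(self.generators)


def get_entry(label: str) -> SymmetryEntry:
    label = label.upper()
    if label in ("C1", "IDENTITY"):
        return SymmetryEntry("C1", [np.eye(3)], {"A": np.array([0.0, 0.0, 1.0])})
    if label == "C3":
        return SymmetryEntry("C3", _c3_generators(),
                             {"A": np.array([0.0, 0.0, 1.0])})
    if label in ("T", "T33", "T:{C3}{C3}"):
        return SymmetryEntry("T", _t_generators(),
                             {"A": T33_AXIS_A, "B": T33_AXIS_B})
    raise ValueError(f"unknown symmetry entry: {label}")


def expand_point_group(asu: Structure, entry: SymmetryEntry) -> Structure:
    """Propagate an asymmetric unit to all symmetry mates of ``entry``.

    Every asu chain is copied once per group element; chain ids are
    relabelled to stay unique and entity groups carry over so that all
    copies of one asu chain share an entity.
    """
    n_out = len(asu.chain_ids) * entry.order
    if n_out > len(_CHAIN_ALPHABET):
        raise ValueError("expanded assembly exceeds available chain ids")

    atoms = []
    entities: dict[str, list] = {}
    idx = 0
    for g in entry.generators:
        tr = RigidTransform(g, np.zeros(3))
        for cid in asu.chain_ids:
            new_id = _CHAIN_ALPHABET[idx]
            idx += 1
            ent = asu.entity_of_chain(cid) or cid
            entities.setdefault(ent, []).append(new_id)
            for r in asu.chain_residues(cid):
                for a in r.atoms:
                    b = a.copy()
                    b.chain_id = new_id
                    b.xyz = tr.apply(a.xyz)
                    atoms.append(b)
    out = Structure(atoms, entities=entities, name=asu.name)
    out.renumber_serials()
    return out
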