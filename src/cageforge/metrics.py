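"""Interface metric suite: solvent accessibility, buried surface area,
residue burial classes, composition similarity, secondary structure,
hydrogen bonding, hydrophobic collapse and shape statistics."""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.spatial import cKDTree

from ._tables import (BACKBONE_ATOMS, COLLAPSE_RESIDUES, DEFAULT_RADIUS,
                      DONOR_ANTECEDENT, MAX_ASA, PROBE_RADIUS,
                      SIDECHAIN_ACCEPTORS, SIDECHAIN_ATOMS, SIDECHAIN_DONORS,
                      VDW_RADII)

log = logging.getLogger(__name__)

RASA_BURIAL_THRESHOLD = 0.25   # Levy-class core/rim/support cutoff
HBOND_DISTANCE = 3.5
BURIED_SASA_CUTOFF = 0.1
HCI_WINDOW = 9
HCI_THRESHOLD = 0.48
DEFAULT_SASA_POINTS = 960


# ---------------------------------------------------------------------------
# Solvent accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = math.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack((np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)))


def sasa(structure, probe: float = PROBE_RADIUS,
         n_points: int = DEFAULT_SASA_POINTS) -> np.ndarray:
    """Per-atom solvent accessible surface area (hydrogens excluded,
    assigned zero area)."""
    heavy = [i for i, a in enumerate(structure.atoms) if a.element != "H"]
    areas = np.zeros(len(structure.atoms))
    if not heavy:
        return areas
    coords = np.array([structure.atoms[i].xyz for i in heavy])
    radii = np.empty(len(heavy))
    for k, i in enumerate(heavy):
        el = structure.atoms[i].element
        if el not in VDW_RADII:
            log.warning("unknown element %r, default radius used", el)
        radii[k] = VDW_RADII.get(el, DEFAULT_RADIUS) + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    for k in range(len(heavy)):
        pts = coords[k] + radii[k] * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[k], radii[k] + max_r):
            if j == k:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > radii[j] ** 2
        areas[heavy[k]] = exposed.mean() * 4.0 * math.pi * radii[k] ** 2
    return areas


def residue_sasa(structure, atom_areas=None, sidechain_only: bool = False) -> dict:
    """Sum atom areas per residue key.  With ``sidechain_only`` only
    side-chain atoms count (glycine falls back to the whole residue)."""
    if atom_areas is None:
        atom_areas = sasa(structure)
    out = {}
    for r in structure.residues:
        sc_names = set(SIDECHAIN_ATOMS.get(r.name, ()))
        total = 0.0
        for idx in r.atom_indices:
            a = structure.atoms[idx]
            if sidechain_only and sc_names and a.name not in sc_names:
                continue
            total += atom_areas[idx]
        out[r.key] = total
    return out


def relative_sasa(structure, atom_areas=None, sidechain_only: bool = False) -> dict:
    """Per-residue SASA normalized by the theoretical maximum for the
    residue type."""
    per_res = residue_sasa(structure, atom_areas, sidechain_only=sidechain_only)
    out = {}
    for r in structure.residues:
        max_asa = MAX_ASA.get(r.name, 200.0)
        out[r.key] = per_res[r.key] / max_asa
    return out


# ---------------------------------------------------------------------------
# Buried surface area
# ---------------------------------------------------------------------------

def _component_chain_groups(structure, groups=None):
    if groups is None:
        groups = [list(chains) for chains in structure.entities.values()]
    if len(groups) < 2:
        raise ValueError("need two chain groups to define an interface")
    return groups


def interface_bsa(complex_structure, groups=None,
                  n_points: int = DEFAULT_SASA_POINTS) -> dict:
    """Buried surface area: SASA of components computed separately (no
    repacking) minus SASA of the complex, split by atomic polarity.

    Returns total/polar/apolar BSA plus per-atom and per-residue burial.
    """
    groups = _component_chain_groups(complex_structure, groups)
    complex_areas = sasa(complex_structure, n_points=n_points)

    separated = np.zeros_like(complex_areas)
    chain_to_atoms = {}
    for i, a in enumerate(complex_structure.atoms):
        chain_to_atoms.setdefault(a.chain_id, []).append(i)
    for group in groups:
        part = complex_structure.select_chains(group)
        part_areas = sasa(part, n_points=n_points)
        indices = [i for c in group for i in chain_to_atoms.get(c, [])]
        separated[indices] = part_areas

    per_atom = separated - complex_areas
    raw_total = float(per_atom.sum())
    per_atom = np.maximum(per_atom, 0.0)
    if raw_total < -1e-6:
        log.warning("negative raw BSA (%.3g) clamped to 0", raw_total)

    polar = sum(b for a, b in zip(complex_structure.atoms, per_atom) if a.polar)
    total = float(per_atom.sum())
    per_residue = {}
    for r in complex_structure.residues:
        per_residue[r.key] = float(sum(per_atom[i] for i in r.atom_indices))
    return {
        "total": total,
        "polar": float(polar),
        "apolar": total - float(polar),
        "per_atom": per_atom,
        "per_residue": per_residue,
        "complex_areas": complex_areas,
        "separated_areas": separated,
        "groups": groups,
    }


def interface_residue_keys(bsa_record, min_bsa: float = 1e-6) -> list:
    return [k for k, v in bsa_record["per_residue"].items() if v > min_bsa]


def classify_interface_residues(complex_structure, groups=None,
                                bsa_record=None) -> dict:
    """Partition interface residues into core / rim / support by relative
    accessibility in the complex vs the isolated component.

    core: buried in complex, exposed in the monomer; rim: still exposed in
    the complex; support: already buried in the monomer.
    """
    if bsa_record is None:
        bsa_record = interface_bsa(complex_structure, groups)
    groups = bsa_record["groups"]
    rasa_complex = relative_sasa(complex_structure, bsa_record["complex_areas"])

    rasa_monomer = {}
    for group in groups:
        part = complex_structure.select_chains(group)
        for key, val in relative_sasa(part).items():
            rasa_monomer[key] = val

    interface = interface_residue_keys(bsa_record)
    out = {"core": set(), "rim": set(), "support": set()}
    for key in interface:
        if rasa_complex[key] >= RASA_BURIAL_THRESHOLD:
            out["rim"].add(key)
        elif rasa_monomer[key] >= RASA_BURIAL_THRESHOLD:
            out["core"].add(key)
        else:
            out["support"].add(key)
    out["interface"] = set(interface)
    return out


def composition_similarity(bsa: float, core: int, rim: int, support: int) -> float:
    """Similarity of measured burial-class counts to the size-expected
    counts; 1 means exact agreement, terms are floored at 0."""
    if bsa <= 0:
        raise ValueError("BSA must be positive")
    expected = {
        "core": 0.01 * bsa + 0.6,
        "rim": 0.01 * bsa - 2.5,
        "support": 0.006 * bsa + 5.0,
    }
    measured = {"core": core, "rim": rim, "support": support}
    terms = []
    for name, exp in expected.items():
        if exp <= 0:
            log.warning("expected %s count non-positive at BSA %.1f; skipped",
                        name, bsa)
            continue
        terms.append(max(0.0, 1.0 - abs(exp - measured[name]) / exp))
    if not terms:
        raise ValueError("no positive expected class counts at this BSA")
    return float(np.mean(terms))


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def secondary_structure(structure) -> dict:
    """Dihedral-based 3-state assignment (H/E/C) per residue key.

    Termini and residues flanking chain breaks are assigned C.
    """
    out = {}
    for cid in structure.chain_ids:
        residues = structure.chain_residues(cid)
        for i, r in enumerate(residues):
            out[r.key] = "C"
            if i == 0 or i == len(residues) - 1:
                continue
            prev_r, next_r = residues[i - 1], residues[i + 1]
            needed = (prev_r.atom("C"), r.atom("N"), r.atom("CA"),
                      r.atom("C"), next_r.atom("N"))
            if any(a is None for a in needed):
                continue
            # chain-break guard: peptide C-N bonds near 1.33 A
            if (np.linalg.norm(needed[0].xyz - needed[1].xyz) > 2.5
                    or np.linalg.norm(needed[3].xyz - needed[4].xyz) > 2.5):
                continue
            phi = _dihedral(needed[0].xyz, needed[1].xyz, needed[2].xyz, needed[3].xyz)
            psi = _dihedral(needed[1].xyz, needed[2].xyz, needed[3].xyz, needed[4].xyz)
            if -100.0 <= phi <= -30.0 and -80.0 <= psi <= -5.0:
                out[r.key] = "H"
            elif -180.0 <= phi <= -45.0 and (psi >= 45.0 or psi <= -150.0):
                out[r.key] = "E"
    return out


def parse_stride(text: str) -> dict:
    """Read per-residue assignments from Stride ASG records (or a plain
    ``chain<TAB>resnum<TAB>state`` table); maps onto the 3-state alphabet."""
    collapse = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E", "b": "E"}
    out = {}
    for line in text.splitlines():
        fields = line.split()
        if line.startswith("ASG") and len(fields) >= 6:
            chain, resnum, code = fields[2], fields[3], fields[5]
        elif len(fields) == 3 and not line.startswith("#"):
            chain, resnum, code = fields
        else:
            continue
        out[(chain, int(resnum), "")] = collapse.get(code, "C")
    return out


def ss_fractions(ss_map: dict, residue_keys) -> dict:
    """Percentages of H / E / C over the given residues (the residue count
    is the denominator)."""
    keys = list(residue_keys)
    if not keys:
        return {"helix": 0.0, "strand": 0.0, "coil": 0.0}
    n = len(keys)
    counts = {"H": 0, "E": 0, "C": 0}
    for k in keys:
        counts[ss_map.get(k, "C")] += 1
    return {"helix": 100.0 * counts["H"] / n,
            "strand": 100.0 * counts["E"] / n,
            "coil": 100.0 * counts["C"] / n}


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _donors_acceptors(structure):
    donors, acceptors = [], []
    for r in structure.residues:
        for a in r.atoms:
            if a.name == "N" and r.name != "PRO":
                donors.append((r, a))
            elif a.name == "O":
                acceptors.append((r, a))
            elif a.name in SIDECHAIN_DONORS.get(r.name, ()):
                donors.append((r, a))
            if a.name in SIDECHAIN_ACCEPTORS.get(r.name, ()):
                acceptors.append((r, a))
    return donors, acceptors


def _attached_hydrogen(residue, donor):
    for a in residue.atoms:
        if a.element == "H" and np.linalg.norm(a.xyz - donor.xyz) < 1.3:
            return a
    return None


def _angle(a, b, c) -> float:
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def hydrogen_bonds(structure) -> list:
    """Geometric hydrogen-bond detection.

    Donor-acceptor heavy atoms within 3.5 A; with an explicit hydrogen the
    D-H...A angle must exceed 120 degrees, otherwise the donor antecedent
    must lie on the far side (antecedent-D-A angle > 90 degrees).
    """
    donors, acceptors = _donors_acceptors(structure)
    if not donors or not acceptors:
        return []
    acc_xyz = np.array([a.xyz for _, a in acceptors])
    tree = cKDTree(acc_xyz)
    bonds = []
    for dr, da in donors:
        for j in tree.query_ball_point(da.xyz, HBOND_DISTANCE):
            ar, aa = acceptors[j]
            if dr.chain_id == ar.chain_id and abs(dr.number - ar.number) <= 1:
                continue
            h = _attached_hydrogen(dr, da)
            if h is not None:
                if _angle(da.xyz, h.xyz, aa.xyz) <= 120.0:
                    continue
            else:
                ante = dr.atom(DONOR_ANTECEDENT.get(da.name, "CA"))
                if ante is not None and _angle(ante.xyz, da.xyz, aa.xyz) <= 90.0:
                    continue
            bonds.append((dr.key, da.name, ar.key, aa.name))
    return bonds


def _unsatisfied_buried(structure, atom_areas) -> int:
    """Count buried donor/acceptor heavy atoms not engaged in any bond."""
    bonds = hydrogen_bonds(structure)
    engaged = {(b[0], b[1]) for b in bonds} | {(b[2], b[3]) for b in bonds}
    donors, acceptors = _donors_acceptors(structure)
    atom_index = {id(a): i for i, a in enumerate(structure.atoms)}
    count = 0
    for r, a in donors + acceptors:
        if atom_areas[atom_index[id(a)]] >= BURIED_SASA_CUTOFF:
            continue
        if (r.key, a.name) in engaged:
            continue
        count += 1
    return count


def buried_unsat_density(complex_structure, groups=None, bsa_record=None):
    """Buried-unsatisfied count (complexed minus uncomplexed state) per
    1,000 square Angstrom of BSA; None when BSA is zero."""
    if bsa_record is None:
        bsa_record = interface_bsa(complex_structure, groups)
    groups = bsa_record["groups"]
    complex_count = _unsatisfied_buried(complex_structure,
                                        bsa_record["complex_areas"])
    unbound_count = 0
    for group in groups:
        part = complex_structure.select_chains(group)
        unbound_count += _unsatisfied_buried(part, sasa(part))
    diff = complex_count - unbound_count
    if bsa_record["total"] <= 0:
        return None, diff
    return diff / (bsa_record["total"] / 1000.0), diff


# ---------------------------------------------------------------------------
# Hydrophobic collapse
# ---------------------------------------------------------------------------

def hydrophobic_collapse_index(sequence: str, window: int = HCI_WINDOW) -> np.ndarray:
    """Windowed density of F/M/I/L/Y/V/W around each position (uniform
    centred window, truncated at the termini)."""
    n = len(sequence)
    indicator = np.array([1.0 if aa in COLLAPSE_RESIDUES else 0.0
                          for aa in sequence])
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = indicator[lo:hi].mean()
    return out


def hci_sites(designed_seq: str, reference_seq: str, window: int = HCI_WINDOW,
              threshold: float = HCI_THRESHOLD) -> list:
    """Positions that newly exceed the collapse threshold in the designed
    sequence but not in the reference."""
    if len(designed_seq) != len(reference_seq):
        raise ValueError("sequence length mismatch")
    hci_d = hydrophobic_collapse_index(designed_seq, window)
    hci_r = hydrophobic_collapse_index(reference_seq, window)
    return [int(i) for i in np.flatnonzero((hci_d > threshold) & (hci_r <= threshold))]


# ---------------------------------------------------------------------------
# Shape statistics
# ---------------------------------------------------------------------------

def spike_ratio(coords_a: np.ndarray, coords_b: np.ndarray, center=None) -> float:
    """1 - (nearer component center distance / farther one), measured from
    the full-assembly center of mass by default."""
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    if center is None:
        center = np.vstack([coords_a, coords_b]).mean(axis=0)
    center = np.asarray(center, dtype=float)
    d_a = float(np.linalg.norm(coords_a.mean(axis=0) - center))
    d_b = float(np.linalg.norm(coords_b.mean(axis=0) - center))
    d_max = max(d_a, d_b)
    if d_max <= 1e-12:
        raise ValueError("degenerate assembly: both components at the center")
    return 1.0 - min(d_a, d_b) / d_max


def cbeta_separation_stats(complex_structure, groups=None, bsa_record=None,
                           cutoff: float = 8.0):
    """Percent of interface residues whose minimum cross-interface C-beta
    distance exceeds ``cutoff``; None without interface residues."""
    if bsa_record is None:
        bsa_record = interface_bsa(complex_structure, groups)
    groups = bsa_record["groups"]
    interface = set(interface_residue_keys(bsa_record))
    if not interface:
        return None
    group_of_chain = {}
    for gi, group in enumerate(groups):
        for c in group:
            group_of_chain[c] = gi
    by_group = {}
    for r in complex_structure.residues:
        if r.key not in interface:
            continue
        gi = group_of_chain.get(r.chain_id)
        if gi is None:
            continue
        by_group.setdefault(gi, []).append(r)
    if len(by_group) < 2:
        return None
    counts_over = 0
    total = 0
    trees = {gi: cKDTree(np.array([r.cbeta() for r in rs]))
             for gi, rs in by_group.items()}
    for gi, rs in by_group.items():
        for r in rs:
            dmin = min(
                trees[gj].query(r.cbeta())[0]
                for gj in by_group if gj != gi
            )
            total += 1
            if dmin > cutoff:
                counts_over += 1
    return 100.0 * counts_over / total


# ---------------------------------------------------------------------------
# Aggregate record
# ---------------------------------------------------------------------------

def interface_metrics(complex_structure, groups=None, observations=None,
                      ss_map=None, n_points: int = DEFAULT_SASA_POINTS) -> dict:
    """Compute the full metric record for one two-component complex."""
    bsa_record = interface_bsa(complex_structure, groups, n_points=n_points)
    groups = bsa_record["groups"]
    classes = classify_interface_residues(complex_structure, groups, bsa_record)
    interface = classes["interface"]
    if ss_map is None:
        ss_map = secondary_structure(complex_structure)
    fractions = ss_fractions(ss_map, interface)
    density, unsat = buried_unsat_density(complex_structure, groups, bsa_record)

    record = {
        "bsa_total": bsa_record["total"],
        "bsa_polar": bsa_record["polar"],
        "bsa_apolar": bsa_record["apolar"],
        "percent_hydrophobic_bsa": (100.0 * bsa_record["apolar"] / bsa_record["total"]
                                    if bsa_record["total"] > 0 else None),
        "interface_residues": len(interface),
        "core": len(classes["core"]),
        "rim": len(classes["rim"]),
        "support": len(classes["support"]),
        "percent_helix": fractions["helix"],
        "percent_strand": fractions["strand"],
        "percent_coil": fractions["coil"],
        "hydrogen_bonds": len(hydrogen_bonds(complex_structure)),
        "buried_unsat": unsat,
        "buried_unsat_density": density,
        "cbeta_over_8": cbeta_separation_stats(complex_structure, groups,
                                               bsa_record),
    }
    if bsa_record["total"] > 0:
        record["composition_similarity"] = composition_similarity(
            bsa_record["total"], record["core"], record["rim"],
            record["support"])
    else:
        record["composition_similarity"] = None

    if observations is not None:
        frag_keys = set()
        for o in observations:
            frag_keys.add(o.residue_a)
            frag_keys.add(o.residue_b)
        record["fragment_observations"] = len(observations)
        record["percent_fragment"] = (
            100.0 * len(frag_keys & interface) / len(interface)
            if interface else None)
    return record
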