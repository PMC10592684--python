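"""Synthetic test-bed generation: ideal helical trimers, planted fragment
training sets, planted docking scenarios and perturbation utilities.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ._tables import AA_ALPHABET, AA_INDEX, ONE_TO_THREE
from .docking import DockingParams, dof_transform
from .fragdb import (FRAGMENT_LENGTH, FragmentCluster, FragmentDatabase,
                     FragmentPair)
from .fragments import extract_windows
from .geometry import RigidTransform, rotation_about_axis
from .structure import Atom, Structure

# Ideal backbone internal coordinates.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.5
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
PHI_HELIX = -57.0
PSI_HELIX = -47.0
OMEGA = 180.0


@dataclass
class ScenarioSpec:
    """Parameters of a planted docking scenario."""

    seed: int = 0
    n_res: int = 16
    helix_radius: float = 9.0
    n_contacts: int = 3
    rot_a: float = 6.0
    rot_b: float = 12.0
    cluster_rmsd: float = 0.5
    cluster_members: int = 10
    cluster_weight: float = 0.8
    continuous: bool = False
    rot_step: float = 3.0
    trans_step: float = 1.0


# ---------------------------------------------------------------------------
# Ideal backbone construction (NeRF internal-coordinate placement)
# ---------------------------------------------------------------------------

def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Position a new atom from three predecessors and internal coordinates."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(angle),
                  bond * np.sin(angle) * np.cos(torsion),
                  bond * np.sin(angle) * np.sin(torsion)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _virtual_cbeta(n, ca, c):
    """Ideal C-beta position reconstructed from backbone geometry."""
    b = ca - n
    c2 = c - ca
    a = np.cross(b, c2)
    return ca - 0.58273431 * a + 0.56802827 * b - 0.54067466 * c2


def ideal_helix_backbone(n_res: int, phi: float = PHI_HELIX,
                         psi: float = PSI_HELIX) -> np.ndarray:
    """(n_res, 4, 3) array of N, CA, C, O coordinates of an ideal helix."""
    coords = np.zeros((n_res, 4, 3))
    # seed residue
    coords[0, 0] = np.array([0.0, 0.0, 0.0])                       # N
    coords[0, 1] = np.array([BOND_N_CA, 0.0, 0.0])                 # CA
    ang = np.deg2rad(ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array(
        [-np.cos(ang), np.sin(ang), 0.0])                          # C
    for i in range(n_res):
        n, ca, c = coords[i, 0], coords[i, 1], coords[i, 2]
        if i + 1 < n_res:
            n_next = _place_atom(n, ca, c, BOND_C_N, ANGLE_CA_C_N, psi)
            ca_next = _place_atom(ca, c, n_next, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
            c_next = _place_atom(c, n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, phi)
            coords[i + 1, 0], coords[i + 1, 1], coords[i + 1, 2] = \
                n_next, ca_next, c_next
            coords[i, 3] = _place_atom(n, ca, c, BOND_C_O, ANGLE_CA_C_O,
                                       psi + 180.0)                # O
        else:
            coords[i, 3] = _place_atom(n, ca, c, BOND_C_O, ANGLE_CA_C_O,
                                       psi + 180.0)
    return coords


def _axis_align_to_z(coords: np.ndarray) -> np.ndarray:
    """Rotate a backbone so its principal (helix) axis lies along +z and
    its CA centroid sits at the origin."""
    ca = coords[:, 1, :]
    center = ca.mean(axis=0)
    centered = ca - center
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    from .geometry import align_z_to
    rot = align_z_to(axis).T   # takes `axis` onto z
    flat = (coords.reshape(-1, 3) - center) @ rot.T
    return flat.reshape(coords.shape)


def random_sequence(n: int, rng: np.random.Generator,
                    alphabet: str = None) -> str:
    alphabet = alphabet or AA_ALPHABET.replace("G", "").replace("P", "")
    return "".join(rng.choice(list(alphabet), size=n))


def _backbone_atoms(chain_id: str, sequence: str, coords: np.ndarray,
                    serial_start: int = 1) -> list:
    atoms = []
    serial = serial_start
    for i, aa in enumerate(sequence):
        res_name = ONE_TO_THREE[aa]
        res_num = i + 1
        for name, elem, xyz in (("N", "N", coords[i, 0]),
                                ("CA", "C", coords[i, 1]),
                                ("C", "C", coords[i, 2]),
                                ("O", "O", coords[i, 3])):
            atoms.append(Atom(serial, name, elem, res_name, chain_id,
                              res_num, "", np.array(xyz)))
            serial += 1
        if aa != "G":
            cb = _virtual_cbeta(coords[i, 0], coords[i, 1], coords[i, 2])
            atoms.append(Atom(serial, "CB", "C", res_name, chain_id,
                              res_num, "", cb))
            serial += 1
    return atoms


def make_helical_trimer(n_res: int = 16, radius: float = 9.0,
                        seed: int = 0) -> Structure:
    """C3-symmetric three-helix bundle with ideal backbone geometry.

    One helix is built along +z at distance ``radius`` from the symmetry
    axis; the other two chains are exact 120/240-degree copies, so the
    structure is bit-reproducible from (n_res, radius, seed).
    """
    if n_res < 10:
        raise ValueError("need at least 10 residues per chain")
    rng = np.random.default_rng(seed)
    sequence = random_sequence(n_res, rng)
    backbone = _axis_align_to_z(ideal_helix_backbone(n_res))
    backbone = backbone + np.array([radius, 0.0, 0.0])

    atoms = []
    for k, chain_id in enumerate("ABC"):
        rot = rotation_about_axis([0, 0, 1], 120.0 * k)
        flat = backbone.reshape(-1, 3) @ rot.T
        atoms.extend(_backbone_atoms(chain_id, sequence,
                                     flat.reshape(backbone.shape),
                                     serial_start=len(atoms) + 1))
    return Structure(atoms, entities={"1": ["A", "B", "C"]})


def perturb(structure: Structure, sigma: float, seed: int = 0) -> Structure:
    """Copy with i.i.d. Gaussian coordinate noise of scale ``sigma``."""
    rng = np.random.default_rng(seed)
    out = structure.copy()
    if sigma > 0:
        out.coords = out.coords + rng.normal(0.0, sigma, size=(len(out), 3))
    return out


# ---------------------------------------------------------------------------
# Planted fragment training sets
# ---------------------------------------------------------------------------

def _draw_sequence(rng, probs: np.ndarray) -> str:
    return "".join(AA_ALPHABET[rng.choice(20, p=p / p.sum())] for p in probs)


def make_fragment_training_set(n_groups: int = 2, members_per_group: int = 20,
                               noise_sigma: float = 0.05, seed: int = 0,
                               contact_fractions=None):
    """Paired fragments drawn around planted representatives.

    Groups are separated far beyond any clustering threshold; sequences are
    drawn from planted per-position distributions and pseudo side-chain
    atoms realize exact per-position contact fractions.  Returns
    ``(pairs, truth)`` where truth records the planted partition,
    distributions and weights.
    """
    rng = np.random.default_rng(seed)
    base = ideal_helix_backbone(FRAGMENT_LENGTH)
    pairs, labels = [], []
    planted_freqs, planted_weights = [], []
    for g in range(n_groups):
        # orientationally distinct paired placement per group
        rot = rotation_about_axis([0, 1, 0], 60.0 * g + 30.0)
        offset = np.array([8.0 + 25.0 * g, 0.0, 0.0])
        rep_paired = base.reshape(-1, 3) @ rot.T + offset
        rep_paired = rep_paired.reshape(base.shape)

        freqs = rng.dirichlet(np.full(20, 0.5), size=2 * FRAGMENT_LENGTH)
        planted_freqs.append(freqs)
        if contact_fractions is None:
            fractions = np.round(rng.uniform(0, 1, 2 * FRAGMENT_LENGTH) * 4) / 4
        else:
            fractions = np.asarray(contact_fractions, dtype=float)
        planted_weights.append(fractions)

        for m in range(members_per_group):
            noise = rng.normal(0, noise_sigma, size=base.shape)
            noise2 = rng.normal(0, noise_sigma, size=base.shape)
            seq = _draw_sequence(rng, freqs)
            pair = FragmentPair(
                mapped_coords=base + noise, paired_coords=rep_paired + noise2,
                mapped_seq=seq[:FRAGMENT_LENGTH],
                paired_seq=seq[FRAGMENT_LENGTH:],
                mapped_sidechains=_planted_sidechains(
                    base, rep_paired, fractions[:FRAGMENT_LENGTH]),
                paired_sidechains=_planted_sidechains(
                    rep_paired, base, fractions[FRAGMENT_LENGTH:]))
            pairs.append(pair)
            labels.append(g)
    truth = {"labels": labels, "freqs": planted_freqs,
             "weights": planted_weights, "seed": seed}
    return pairs, truth


def _planted_sidechains(own: np.ndarray, opposite: np.ndarray,
                        fractions) -> list:
    """Four pseudo side-chain atoms per residue, of which a planted
    fraction sits in contact range of the opposite fragment."""
    target = opposite.reshape(-1, 3).mean(axis=0)
    out = []
    for i, frac in enumerate(fractions):
        ca = own[i, 1]
        n_contact = int(round(frac * 4))
        atoms = []
        for k in range(4):
            if k < n_contact:
                atoms.append(target + np.array([0.3 * k, 0.0, 0.0]))
            else:
                away = ca + (ca - target) * 10.0 + np.array([0.0, 0.0, 5.0 * k])
                atoms.append(away)
        out.append(np.array(atoms))
    return out


# ---------------------------------------------------------------------------
# Planted docking scenarios
# ---------------------------------------------------------------------------

def _snap(value: float, step: float) -> float:
    return round(value / step) * step


def _min_cross_distance(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    from scipy.spatial import cKDTree
    return float(cKDTree(coords_a).query(coords_b)[0].min())


def make_docking_scenario(spec: ScenarioSpec = None, seed: int | None = None):
    """Two trimers plus a toy database realizing exact fragment-pair
    matches at a planted transform inside the tetrahedral DOF.

    Returns ``(olig_a, olig_b, truth, db)``; truth carries the planted DOF
    and the number of planted contacts.
    """
    from .fragments import type_windows
    from .symmetry import get_entry

    if spec is None:
        spec = ScenarioSpec()
    if seed is not None:
        spec = ScenarioSpec(**{**asdict(spec), "seed": seed})
    rng = np.random.default_rng(spec.seed)

    olig_a = make_helical_trimer(spec.n_res, spec.helix_radius, seed=spec.seed)
    olig_b = make_helical_trimer(spec.n_res, spec.helix_radius,
                                 seed=spec.seed + 104729)
    entry = get_entry("T")

    # choose grid-snapped translations bringing the surfaces into contact
    trans = None
    for t in np.arange(0.0, 80.0, spec.trans_step):
        ta = dof_transform(entry.component_axes["A"], spec.rot_a, t)
        tb = dof_transform(entry.component_axes["B"], spec.rot_b, t)
        d = _min_cross_distance(ta.apply(olig_a.coords), tb.apply(olig_b.coords))
        if d >= 3.8:
            trans = float(t)
            break
    if trans is None:
        raise RuntimeError("could not separate scenario components")
    dof = (spec.rot_a, trans, spec.rot_b, trans)

    placed_a = olig_a.transformed(dof_transform(entry.component_axes["A"],
                                                dof[0], dof[1]))
    placed_b = olig_b.transformed(dof_transform(entry.component_axes["B"],
                                                dof[2], dof[3]))

    windows_a = extract_windows(placed_a)
    windows_b = extract_windows(placed_b)

    # rank A-B window pairs by centre distance; keep the closest contacts
    # with distinct central residues on both sides
    dists = []
    for ia, wa in enumerate(windows_a):
        for ib, wb in enumerate(windows_b):
            dists.append((np.linalg.norm(wa.center - wb.center), ia, ib))
    dists.sort()
    chosen, used_a, used_b = [], set(), set()
    for d, ia, ib in dists:
        if windows_a[ia].central_key in used_a or \
                windows_b[ib].central_key in used_b:
            continue
        chosen.append((ia, ib))
        used_a.add(windows_a[ia].central_key)
        used_b.add(windows_b[ib].central_key)
        if len(chosen) == spec.n_contacts:
            break
    if len(chosen) < spec.n_contacts:
        raise RuntimeError("not enough contact window pairs in scenario")

    db = FragmentDatabase(typing_threshold=0.3)
    db.representatives["1"] = windows_a[0].coords.copy()
    clusters = []
    for ci, (ia, ib) in enumerate(chosen):
        freq = _planted_cluster_freq(rng, windows_a[ia].sequence,
                                     windows_b[ib].sequence)
        clusters.append(FragmentCluster(
            cluster_id=f"1_1_{ci}", type_pair=("1", "1"),
            rep_mapped=windows_a[ia].coords.copy(),
            rep_paired=windows_b[ib].coords.copy(),
            rmsd_cluster=spec.cluster_rmsd,
            member_count=spec.cluster_members,
            freq=freq,
            weights=np.full(2 * FRAGMENT_LENGTH, spec.cluster_weight)))
        if spec.continuous:
            # anchor a second cluster for the same target window at another
            # source residue so its ghost co-locates with the first
            alt = next(j for j, w in enumerate(windows_a)
                       if w.central_key not in used_a)
            used_a.add(windows_a[alt].central_key)
            clusters.append(FragmentCluster(
                cluster_id=f"1_1_{ci}c", type_pair=("1", "1"),
                rep_mapped=windows_a[alt].coords.copy(),
                rep_paired=windows_b[ib].coords.copy(),
                rmsd_cluster=spec.cluster_rmsd,
                member_count=spec.cluster_members,
                freq=freq,
                weights=np.full(2 * FRAGMENT_LENGTH, spec.cluster_weight)))
    db.clusters[("1", "1")] = clusters

    truth = {
        "dof": list(dof),
        "n_contacts": len(chosen),
        "contact_residues_a": sorted([windows_a[ia].central_key[:2]
                                      for ia, _ in chosen]),
        "contact_residues_b": sorted([windows_b[ib].central_key[:2]
                                      for _, ib in chosen]),
        "cluster_ids": [c.cluster_id for c in clusters],
        "rot_step": spec.rot_step,
        "trans_step": spec.trans_step,
        "seed": spec.seed,
    }
    return olig_a, olig_b, truth, db


def _planted_cluster_freq(rng, seq_mapped: str, seq_paired: str) -> np.ndarray:
    """Mix of the realized sequence (weight 0.6) with uniform background."""
    freq = np.full((2 * FRAGMENT_LENGTH, 20), 0.4 / 20)
    for p, aa in enumerate(seq_mapped + seq_paired):
        freq[p, AA_INDEX[aa]] += 0.6
    return freq


def write_truth(truth: dict, path):
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# hhm fixture writer
# ---------------------------------------------------------------------------

def write_hhm(freqs: np.ndarray, path=None) -> str:
    """Serialize an L x 20 frequency matrix as minimal hhm-dialect text;
    zero frequencies become '*'."""
    freqs = np.asarray(freqs, dtype=float)
    lines = ["HHsearch 1.5", "NAME  fixture", "LENG  %d" % len(freqs),
             "SEQ", ">fixture", "X" * len(freqs), "#",
             "NULL  " + " ".join(["3162"] * 20),
             "HMM    " + "\t".join(AA_ALPHABET),
             "       M->M M->I M->D", "       0 * *"]
    for i, row in enumerate(freqs, start=1):
        vals = []
        for f in row:
            if f <= 0:
                vals.append("*")
            else:
                vals.append(f"{-1000.0 * np.log2(f):.4f}")
        lines.append(f"A {i} " + " ".join(vals) + f" {i}")
        lines.append("       0 * * * * * * 0 0 0")
        lines.append("")
    lines.append("//")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
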