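"""Fragment-pair cluster database.

A cluster groups structurally similar paired fragments (5 + 5 residues of
backbone geometry) and carries, per position, the amino-acid frequency
distribution observed across members and an interaction weight measuring
how often that position's side chain contacts the opposite fragment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from ._tables import AA_ALPHABET, AA_INDEX, NONCANONICAL_MAP, THREE_TO_ONE
from .geometry import coord_rmsd, kabsch_superpose

log = logging.getLogger(__name__)

FRAGMENT_LENGTH = 5          # central residue +/- 2
BACKBONE_PER_RESIDUE = 4     # N, CA, C, O
PAIR_POSITIONS = 2 * FRAGMENT_LENGTH
CONTACT_DISTANCE = 4.5       # heavy-atom contact criterion for weights
DB_FORMAT_VERSION = 1


@dataclass
class FragmentPair:
    """One observed paired fragment: backbone geometry, sequences and
    (optionally) side-chain heavy atoms for contact counting."""

    mapped_coords: np.ndarray        # (5, 4, 3) backbone of the mapped fragment
    paired_coords: np.ndarray        # (5, 4, 3) backbone of the paired fragment
    mapped_seq: str = "A" * FRAGMENT_LENGTH
    paired_seq: str = "A" * FRAGMENT_LENGTH
    mapped_sidechains: list | None = None   # 5 arrays of (k, 3) or None
    paired_sidechains: list | None = None

    def flat_mapped(self) -> np.ndarray:
        return self.mapped_coords.reshape(-1, 3)

    def flat_paired(self) -> np.ndarray:
        return self.paired_coords.reshape(-1, 3)


def canonical_one_letter(res_name: str) -> str | None:
    """Map a residue name (3- or 1-letter) to the canonical alphabet,
    or None if it cannot be mapped."""
    if len(res_name) == 1:
        return res_name if res_name in AA_INDEX else None
    mapped = NONCANONICAL_MAP.get(res_name, res_name)
    return THREE_TO_ONE.get(mapped)


@dataclass
class FragmentCluster:
    cluster_id: str
    type_pair: tuple                  # (mapped fragment type, paired fragment type)
    rep_mapped: np.ndarray            # (5, 4, 3)
    rep_paired: np.ndarray            # (5, 4, 3)
    rmsd_cluster: float
    member_count: int
    freq: np.ndarray                  # (10, 20); positions 0-4 mapped, 5-9 paired
    weights: np.ndarray               # (10,) interaction weight t_r per position
    members: list = field(default_factory=list, repr=False)

    def validate(self):
        if self.member_count < 1:
            raise ValueError("cluster must have at least one member")
        if self.rmsd_cluster < 0:
            raise ValueError("negative cluster RMSD")
        if self.freq.shape != (PAIR_POSITIONS, len(AA_ALPHABET)):
            raise ValueError("frequency table shape mismatch")
        row_sums = self.freq.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise ValueError("frequency rows must sum to 1")
        if np.any(self.weights < -1e-12) or np.any(self.weights > 1 + 1e-12):
            raise ValueError("interaction weights outside [0, 1]")


# ---------------------------------------------------------------------------
# Clustering and per-cluster statistics
# ---------------------------------------------------------------------------

def pair_rmsd(member: FragmentPair, leader: FragmentPair) -> float:
    """RMSD between paired fragments after superposing the member's mapped
    fragment onto the leader's mapped fragment backbone."""
    t, _ = kabsch_superpose(member.flat_mapped(), leader.flat_mapped())
    return coord_rmsd(t.apply(member.flat_paired()), leader.flat_paired())


def cluster_fragment_pairs(pairs, rmsd_threshold: float,
                           type_pair=("1", "1"),
                           id_prefix: str = "") -> list:
    """Greedy leader clustering of paired fragments sharing one type pair.

    Deterministic: pairs are visited in input order and the first member of
    each cluster becomes its representative.
    """
    clusters = []
    assignments = []   # list of (leader FragmentPair, member list, rmsd list)
    for pair in pairs:
        placed = False
        for leader, members, rmsds in assignments:
            r = pair_rmsd(pair, leader)
            if r <= rmsd_threshold:
                members.append(pair)
                rmsds.append(r)
                placed = True
                break
        if not placed:
            assignments.append((pair, [pair], [0.0]))

    for i, (leader, members, rmsds) in enumerate(assignments):
        cid = f"{id_prefix}{type_pair[0]}_{type_pair[1]}_{i}"
        freq = cluster_frequencies(members)
        weights = interaction_weight(members)
        clusters.append(FragmentCluster(
            cluster_id=cid, type_pair=tuple(type_pair),
            rep_mapped=leader.mapped_coords.copy(),
            rep_paired=leader.paired_coords.copy(),
            rmsd_cluster=float(np.mean(rmsds)), member_count=len(members),
            freq=freq, weights=weights, members=list(members)))
    return clusters


def cluster_frequencies(members) -> np.ndarray:
    """Tally member amino acids into per-position frequency rows."""
    usable = []
    for m in members:
        letters = [canonical_one_letter(aa) for aa in m.mapped_seq + m.paired_seq]
        if any(l is None for l in letters):
            log.warning("dropping cluster member with non-canonical residue")
            continue
        usable.append(letters)
    if not usable:
        raise ValueError("no usable members for frequency tally")
    counts = np.zeros((PAIR_POSITIONS, len(AA_ALPHABET)))
    for letters in usable:
        for p, aa in enumerate(letters):
            counts[p, AA_INDEX[aa]] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def _member_contact_fractions(member: FragmentPair) -> np.ndarray:
    """Per-position fraction of side-chain atoms contacting the opposite
    fragment (backbone + side chains) within the contact distance."""
    out = np.zeros(PAIR_POSITIONS)
    sides = [
        (member.mapped_sidechains, member.paired_coords, member.paired_sidechains, 0),
        (member.paired_sidechains, member.mapped_coords, member.mapped_sidechains, FRAGMENT_LENGTH),
    ]
    for own_sc, opp_bb, opp_sc, offset in sides:
        opp_atoms = [opp_bb.reshape(-1, 3)]
        if opp_sc is not None:
            opp_atoms.extend(a for a in opp_sc if a is not None and len(a))
        opp = np.vstack(opp_atoms)
        tree = cKDTree(opp)
        for pos in range(FRAGMENT_LENGTH):
            sc = None if own_sc is None else own_sc[pos]
            if sc is None or len(sc) == 0:
                continue   # glycine / absent side chain -> weight 0
            hits = tree.query_ball_point(np.asarray(sc, dtype=float), CONTACT_DISTANCE)
            contacting = sum(1 for h in hits if h)
            out[offset + pos] = contacting / len(sc)
    return out


def interaction_weight(members) -> np.ndarray:
    """Mean per-position contact fraction over cluster members, in [0, 1]."""
    fractions = np.array([_member_contact_fractions(m) for m in members])
    return np.clip(fractions.mean(axis=0), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Database
# ---------------------------------------------------------------------------

@dataclass
class FragmentDatabase:
    """Single-fragment type representatives plus per-type-pair clusters."""

    fragment_length: int = FRAGMENT_LENGTH
    typing_threshold: float = 0.75
    representatives: dict = field(default_factory=dict)   # type id -> (5, 4, 3)
    clusters: dict = field(default_factory=dict)          # (ta, tb) -> [clusters]

    def all_clusters(self):
        for group in self.clusters.values():
            yield from group

    def clusters_for_type(self, type_id: str):
        """Clusters whose mapped-fragment type equals ``type_id``."""
        return [c for c in self.all_clusters() if c.type_pair[0] == type_id]

    def cluster_by_id(self, cluster_id: str):
        for c in self.all_clusters():
            if c.cluster_id == cluster_id:
                return c
        raise KeyError(cluster_id)

    def mean_match_reference(self) -> float:
        """Database-wide mean cluster RMSD, used as the match-quality
        threshold when blending profiles."""
        vals = [c.rmsd_cluster for c in self.all_clusters()]
        return float(np.mean(vals)) if vals else 0.0

    def mean_weight_reference(self) -> float:
        vals = [c.weights.mean() for c in self.all_clusters()]
        return float(np.mean(vals)) if vals else 0.0


def save_db(db: FragmentDatabase, path):
    """Write the database as a directory: a JSON manifest plus one TSV of
    coordinates/frequencies/weights per cluster."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": DB_FORMAT_VERSION,
        "fragment_length": db.fragment_length,
        "typing_threshold": db.typing_threshold,
        "representatives": {
            t: np.asarray(c).reshape(-1).tolist()
            for t, c in db.representatives.items()
        },
        "clusters": [],
    }
    for c in db.all_clusters():
        fname = f"cluster_{c.cluster_id}.tsv"
        manifest["clusters"].append({
            "id": c.cluster_id, "type_pair": list(c.type_pair),
            "rmsd_cluster": c.rmsd_cluster, "member_count": c.member_count,
            "file": fname,
        })
        lines = ["# section\tvalues"]
        for tag, arr in (("rep_mapped", c.rep_mapped), ("rep_paired", c.rep_paired),
                         ("freq", c.freq), ("weights", c.weights)):
            flat = "\t".join(repr(float(v)) for v in np.asarray(arr).reshape(-1))
            lines.append(f"{tag}\t{flat}")
        (path / fname).write_text("\n".join(lines) + "\n")
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_db(path) -> FragmentDatabase:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    version = manifest.get("format_version")
    if version != DB_FORMAT_VERSION:
        raise ValueError(
            f"database format version {version!r} unsupported "
            f"(expected {DB_FORMAT_VERSION})")
    db = FragmentDatabase(
        fragment_length=manifest["fragment_length"],
        typing_threshold=manifest["typing_threshold"],
        representatives={
            t: np.array(v).reshape(FRAGMENT_LENGTH, BACKBONE_PER_RESIDUE, 3)
            for t, v in manifest["representatives"].items()
        })
    for entry in manifest["clusters"]:
        sections = {}
        for line in (path / entry["file"]).read_text().splitlines():
            if line.startswith("#") or not line.strip():
                continue
            tag, *vals = line.split("\t")
            sections[tag] = np.array([float(v) for v in vals])
        required = ("rep_mapped", "rep_paired", "freq", "weights")
        if any(tag not in sections for tag in required):
            raise ValueError(f"truncated cluster file: {entry['file']}")
        cluster = FragmentCluster(
            cluster_id=entry["id"], type_pair=tuple(entry["type_pair"]),
            rep_mapped=sections["rep_mapped"].reshape(FRAGMENT_LENGTH, 4, 3),
            rep_paired=sections["rep_paired"].reshape(FRAGMENT_LENGTH, 4, 3),
            rmsd_cluster=entry["rmsd_cluster"],
            member_count=entry["member_count"],
            freq=sections["freq"].reshape(PAIR_POSITIONS, len(AA_ALPHABET)),
            weights=sections["weights"])
        cluster.validate()
        db.clusters.setdefault(cluster.type_pair, []).append(cluster)
    return db


def build_db(pairs_by_type_pair: dict, rmsd_threshold: float,
             typing_threshold: float = 0.75) -> FragmentDatabase:
    """Cluster raw paired fragments (grouped by type pair) into a database.

    Single-fragment representatives default to the mapped coordinates of the
    first cluster of each type.
    """
    db = FragmentDatabase(typing_threshold=typing_threshold)
    for type_pair, pairs in pairs_by_type_pair.items():
        clusters = cluster_fragment_pairs(pairs, rmsd_threshold, type_pair=type_pair)
        db.clusters[tuple(type_pair)] = clusters
        for tid, rep in ((type_pair[0], clusters[0].rep_mapped if clusters else None),
                         (type_pair[1], clusters[0].rep_paired if clusters else None)):
            if tid not in db.representatives and rep is not None:
                db.representatives[tid] = rep.copy()
    return db
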