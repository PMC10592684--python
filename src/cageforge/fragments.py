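"""Fragment typing, ghost-fragment generation, observation matching and
the normalized per-pose fragment score."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._tables import SIDECHAIN_ATOMS
from .fragdb import FRAGMENT_LENGTH, FragmentDatabase
from .geometry import coord_rmsd, kabsch_superpose

MATCH_THRESHOLD = 1.0        # max fragment-to-ghost RMSD for an observation
RMSD_CLUSTER_FLOOR = 0.01    # avoids division blowup for singleton clusters
CLASH_DISTANCE = 2.1         # ghost heavy atom vs backbone/CB
PER_RESIDUE_SCORE_CAP = 2.0
SURFACE_RASA_MIN = 0.10      # relative side-chain exposure gate for typing


def match_score(rmsd_frag: float, rmsd_cluster: float) -> float:
    """m = 1 / (1 + (RMSD_frag / RMSD_cluster)^2), in (0, 1]."""
    if rmsd_frag < 0 or rmsd_cluster < 0:
        raise ValueError("RMSD values must be non-negative")
    rc = max(rmsd_cluster, RMSD_CLUSTER_FLOOR)
    return 1.0 / (1.0 + (rmsd_frag / rc) ** 2)


@dataclass
class FragmentWindow:
    """A 5-residue backbone window centred on one surface residue."""

    central_key: tuple                 # (chain, resnum, icode)
    residue_keys: list                 # 5 keys, ordered
    coords: np.ndarray                 # (5, 4, 3)
    sequence: str
    type_id: str | None = None

    def flat(self) -> np.ndarray:
        return self.coords.reshape(-1, 3)

    @property
    def center(self) -> np.ndarray:
        return self.coords.reshape(-1, 3).mean(axis=0)


@dataclass
class GhostFragment:
    source_window: FragmentWindow
    cluster_id: str
    coords: np.ndarray                 # (5, 4, 3) hypothetical partner backbone
    rmsd_cluster: float

    @property
    def source_key(self):
        return self.source_window.central_key

    @property
    def center(self) -> np.ndarray:
        return self.coords.reshape(-1, 3).mean(axis=0)


@dataclass
class Observation:
    """A matched fragment pair between the two components of a pose."""

    residue_a: tuple
    residue_b: tuple
    cluster_id: str
    rmsd: float
    match: float
    residues_a: list = field(default_factory=list)
    residues_b: list = field(default_factory=list)
    central: bool = True


# ---------------------------------------------------------------------------
# Windows and typing
# ---------------------------------------------------------------------------

def extract_windows(structure, residue_keys=None) -> list:
    """All complete 5-residue windows (central residue +/- 2, contiguous
    author numbering, full backbone).  ``residue_keys`` optionally restricts
    the central residues considered."""
    wanted = set(residue_keys) if residue_keys is not None else None
    windows = []
    half = FRAGMENT_LENGTH // 2
    for cid in structure.chain_ids:
        residues = structure.chain_residues(cid)
        for i in range(half, len(residues) - half):
            central = residues[i]
            if wanted is not None and central.key not in wanted:
                continue
            stretch = residues[i - half:i + half + 1]
            if any(not r.has_backbone or r.atom("O") is None for r in stretch):
                continue
            numbers = [r.number for r in stretch]
            if numbers != list(range(numbers[0], numbers[0] + FRAGMENT_LENGTH)):
                continue
            coords = np.stack([r.backbone_coords() for r in stretch])
            windows.append(FragmentWindow(
                central_key=central.key,
                residue_keys=[r.key for r in stretch],
                coords=coords,
                sequence="".join(r.one_letter for r in stretch)))
    return windows


def surface_residue_keys(structure, sasa_fn=None, min_rasa: float = SURFACE_RASA_MIN):
    """Residues whose relative side-chain SASA in the isolated structure
    exceeds ``min_rasa``.  Glycine uses whole-residue exposure."""
    from .metrics import relative_sasa   # local import avoids a cycle

    if sasa_fn is None:
        sasa_fn = relative_sasa
    rasa = sasa_fn(structure, sidechain_only=True)
    return [key for key, value in rasa.items() if value > min_rasa]


def assign_fragment_type(window_coords: np.ndarray, db: FragmentDatabase):
    """Best-matching single-fragment type, or (None, inf) if no
    representative superposes below the typing threshold."""
    flat = np.asarray(window_coords).reshape(-1, 3)
    best_type, best_rmsd = None, np.inf
    for type_id in sorted(db.representatives):
        _, rmsd = kabsch_superpose(db.representatives[type_id].reshape(-1, 3), flat)
        if rmsd < best_rmsd - 1e-12:
            best_type, best_rmsd = type_id, rmsd
    if best_type is None or best_rmsd > db.typing_threshold:
        return None, best_rmsd
    return best_type, best_rmsd


def type_windows(windows, db: FragmentDatabase) -> list:
    """Assign types in place; returns only the typed windows."""
    typed = []
    for w in windows:
        type_id, _ = assign_fragment_type(w.coords, db)
        w.type_id = type_id
        if type_id is not None:
            typed.append(w)
    return typed


# ---------------------------------------------------------------------------
# Ghost fragments
# ---------------------------------------------------------------------------

def _clash_coords(structure) -> np.ndarray:
    """Backbone and C-beta coordinates used for ghost clash rejection."""
    pts = []
    for r in structure.residues:
        for name in ("N", "CA", "C", "O", "CB"):
            a = r.atom(name)
            if a is not None:
                pts.append(a.xyz)
    return np.array(pts) if pts else np.empty((0, 3))


def generate_ghosts(typed_windows, db: FragmentDatabase, clash_structure=None,
                    clash_distance: float = CLASH_DISTANCE) -> list:
    """One ghost per (typed window, compatible cluster) that survives the
    backbone/CB clash check against the source oligomer."""
    tree = None
    if clash_structure is not None:
        pts = _clash_coords(clash_structure)
        if len(pts):
            tree = cKDTree(pts)
    ghosts = []
    for w in typed_windows:
        if w.type_id is None:
            continue
        for cluster in db.clusters_for_type(w.type_id):
            t, _ = kabsch_superpose(cluster.rep_mapped.reshape(-1, 3), w.flat())
            placed = t.apply(cluster.rep_paired.reshape(-1, 3))
            if tree is not None:
                if any(len(h) for h in tree.query_ball_point(placed, clash_distance)):
                    continue
            ghosts.append(GhostFragment(
                source_window=w, cluster_id=cluster.cluster_id,
                coords=placed.reshape(FRAGMENT_LENGTH, 4, 3),
                rmsd_cluster=cluster.rmsd_cluster))
    return ghosts


def continuous_ghost_filter(ghosts, overlap_threshold: float = MATCH_THRESHOLD) -> list:
    """Keep only ghosts co-locating (backbone RMSD within the threshold)
    with a ghost from a *different* source residue of the same component."""
    if len(ghosts) < 2:
        return []
    centers = np.array([g.center for g in ghosts])
    tree = cKDTree(centers)
    keep = np.zeros(len(ghosts), dtype=bool)
    # centers of two overlapping 20-atom sets cannot differ by more than
    # the per-atom RMSD bound scaled by sqrt(n); 5 A is a safe prefilter
    for i, j in tree.query_pairs(5.0):
        if keep[i] and keep[j]:
            continue
        if ghosts[i].source_key == ghosts[j].source_key:
            continue
        if coord_rmsd(ghosts[i].coords.reshape(-1, 3),
                      ghosts[j].coords.reshape(-1, 3)) <= overlap_threshold:
            keep[i] = keep[j] = True
    return [g for g, k in zip(ghosts, keep) if k]


# ---------------------------------------------------------------------------
# Observation matching
# ---------------------------------------------------------------------------

def find_observations(ghosts, typed_windows_b, db: FragmentDatabase,
                      match_threshold: float = MATCH_THRESHOLD) -> list:
    """Match ghost placements from component A against typed windows of
    component B; both inputs must already be in the same frame."""
    observations = []
    if not ghosts or not typed_windows_b:
        return observations
    centers_b = np.array([w.center for w in typed_windows_b])
    tree = cKDTree(centers_b)
    cluster_types = {g.cluster_id: db.cluster_by_id(g.cluster_id).type_pair[1]
                     for g in {g.cluster_id: g for g in ghosts}.values()}
    prefilter = match_threshold + 4.0
    for g in ghosts:
        required_type = cluster_types[g.cluster_id]
        flat_ghost = g.coords.reshape(-1, 3)
        for bi in tree.query_ball_point(g.center, prefilter):
            w = typed_windows_b[bi]
            if w.type_id != required_type:
                continue
            rmsd = coord_rmsd(flat_ghost, w.flat())
            if rmsd <= match_threshold:
                observations.append(Observation(
                    residue_a=g.source_key, residue_b=w.central_key,
                    cluster_id=g.cluster_id, rmsd=rmsd,
                    match=match_score(rmsd, g.rmsd_cluster),
                    residues_a=list(g.source_window.residue_keys),
                    residues_b=list(w.residue_keys)))
    return observations


# ---------------------------------------------------------------------------
# Pose score
# ---------------------------------------------------------------------------

def nanohedra_score(observations) -> tuple[float, float]:
    """(total, normalized) fragment score.

    Each observation contributes its match score m to both of its central
    residues; per-residue accumulation is capped so the normalized score
    (total / number of central fragment residues) never exceeds 2.
    """
    per_residue: dict = {}
    for obs in observations:
        if not obs.central:
            continue
        for res in (("A", obs.residue_a), ("B", obs.residue_b)):
            per_residue[res] = per_residue.get(res, 0.0) + obs.match
    if not per_residue:
        return 0.0, 0.0
    total = sum(min(v, PER_RESIDUE_SCORE_CAP) for v in per_residue.values())
    return total, total / len(per_residue)


def observations_to_rows(observations) -> list:
    """Flatten observations for TSV output."""
    rows = []
    for o in observations:
        rows.append({
            "chain_a": o.residue_a[0], "residue_a": o.residue_a[1],
            "chain_b": o.residue_b[0], "residue_b": o.residue_b[1],
            "cluster": o.cluster_id, "rmsd": round(o.rmsd, 4),
            "match": round(o.match, 4), "central": int(o.central),
        })
    return rows
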