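"""Rigid-body fragment-based docking of two C3 trimers into a tetrahedral
architecture: degree-of-freedom enumeration, overlap search, transform
clustering and local grid optimization."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .fragdb import FragmentDatabase
from .fragments import (MATCH_THRESHOLD, FragmentWindow, GhostFragment,
                        continuous_ghost_filter, extract_windows,
                        find_observations, generate_ghosts, nanohedra_score,
                        surface_residue_keys, type_windows)
from .geometry import RigidTransform, align_z_to, rotation_about_axis, transform_hash
from .structure import Structure
from .symmetry import SymmetryEntry, expand_point_group, get_entry

log = logging.getLogger(__name__)

COARSE_ROT_STEP = 3.0     # degrees
COARSE_TRANS_STEP = 1.0   # Angstrom
IMPROVEMENT_STOP = 0.05   # relative score-gain stopping criterion
MIN_STEP = (0.25, 0.1)    # (degrees, Angstrom) resolution floor
ROTATION_PERIOD = 120.0   # C3 components repeat every 120 degrees


@dataclass
class DockingParams:
    minimum_matched: int = 3
    initial_z: float = 1.0
    match_value: float = 0.5
    trim_termini: bool = False
    continuous_ghosts: bool = False
    rot_step: float = COARSE_ROT_STEP
    trans_step: float = COARSE_TRANS_STEP

    @property
    def initial_rmsd_gate(self) -> float:
        """Stand-in for the published z-value gate: the maximum fragment
        RMSD admitted during the initial overlap search."""
        return self.initial_z * MATCH_THRESHOLD


@dataclass
class Pose:
    """Two oligomers plus their rigid transforms along the allowed DOF."""

    component_a: Structure
    component_b: Structure
    dof: tuple                      # (rot_a deg, trans_a A, rot_b deg, trans_b A)
    entry: SymmetryEntry
    observations: list = field(default_factory=list)
    metrics: dict = field(default_factory=dict)
    pose_id: int = 0
    score_total: float = 0.0
    score_normalized: float = 0.0

    @property
    def transform_a(self) -> RigidTransform:
        return dof_transform(self.entry.component_axes["A"], self.dof[0], self.dof[1])

    @property
    def transform_b(self) -> RigidTransform:
        return dof_transform(self.entry.component_axes["B"], self.dof[2], self.dof[3])

    def relative_transform(self) -> RigidTransform:
        return self.transform_a.inverse() @ self.transform_b

    def placed_components(self):
        return (self.component_a.transformed(self.transform_a),
                self.component_b.transformed(self.transform_b))

    def complex_structure(self) -> Structure:
        a, b = self.placed_components()
        return Structure.concatenate([a, b], entity_names=["A", "B"])

    def assembly(self) -> Structure:
        """Expand the pose to the full point-group assembly.

        The asymmetric unit is one monomer of each placed trimer; the
        internal 3-fold of each component is a subgroup of the assembly
        group, so expansion regenerates both complete trimers.
        """
        a, b = self.placed_components()
        asu = Structure.concatenate(
            [a.select_chains([a.chain_ids[0]]),
             b.select_chains([b.chain_ids[0]])],
            entity_names=["A", "B"])
        return expand_point_group(asu, self.entry)


def dof_transform(axis, rotation_deg: float, translation: float) -> RigidTransform:
    """Compose the allowed component DOF: spin about its own (z) axis,
    translate along it, then align the axis onto its assembly direction."""
    align = RigidTransform(align_z_to(axis))
    internal = RigidTransform(
        rotation_about_axis([0, 0, 1], rotation_deg),
        np.array([0.0, 0.0, float(translation)]))
    return align @ internal


# ---------------------------------------------------------------------------
# DOF grids
# ---------------------------------------------------------------------------

def _axis_samples(lo: float, hi: float, step: float, periodic: float | None):
    if step <= 0:
        raise ValueError("grid step must be positive")
    if hi < lo:
        raise ValueError("invalid range")
    if hi == lo:
        return [lo]
    if periodic is not None:
        span = min(hi - lo, periodic)
        n = max(1, int(round(span / step)))
        return [lo + i * step for i in range(n) if lo + i * step < lo + span]
    n = int(np.floor((hi - lo) / step + 1e-9))
    return [lo + i * step for i in range(n + 1)]


def enumerate_dof(entry: SymmetryEntry, rot_step: float, trans_step: float,
                  ranges: dict) -> list:
    """Deterministic combinatorial grid over the 4 allowed DOF.

    ``ranges`` maps 'rot_a', 'trans_a', 'rot_b', 'trans_b' to (lo, hi)
    tuples; rotations are periodic (120 degrees for C3 components) with a
    half-open sample range, translations include both endpoints.
    """
    axes = []
    for name in ("rot_a", "rot_b"):
        lo, hi = ranges.get(name, (0.0, ROTATION_PERIOD))
        axes.append(_axis_samples(lo, hi, rot_step, periodic=ROTATION_PERIOD))
    for name in ("trans_a", "trans_b"):
        lo, hi = ranges.get(name, (0.0, 0.0))
        axes.append(_axis_samples(lo, hi, trans_step, periodic=None))
    rot_a, rot_b, trans_a, trans_b = axes
    return [(ra, ta, rb, tb)
            for ra in rot_a for rb in rot_b for ta in trans_a for tb in trans_b]


# ---------------------------------------------------------------------------
# Surface preparation
# ---------------------------------------------------------------------------

def trim_termini_keys(structure, ss_map=None) -> set:
    """Residue keys that survive terminal loop/coil trimming: leading and
    trailing coil runs of every chain are removed."""
    from .metrics import secondary_structure

    if ss_map is None:
        ss_map = secondary_structure(structure)
    keep = set()
    for cid in structure.chain_ids:
        residues = structure.chain_residues(cid)
        states = [ss_map.get(r.key, "C") for r in residues]
        first = next((i for i, s in enumerate(states) if s != "C"), None)
        if first is None:
            continue
        last = len(states) - 1 - next(
            i for i, s in enumerate(reversed(states)) if s != "C")
        keep.update(r.key for r in residues[first:last + 1])
    return keep


@dataclass
class _PreparedComponent:
    windows: list                      # typed windows, local frame
    window_coords: np.ndarray          # (k, 20, 3)
    ghosts: list = None                # only for component A
    ghost_coords: np.ndarray = None    # (g, 20, 3)


def prepare_component(structure, db: FragmentDatabase, params: DockingParams,
                      with_ghosts: bool) -> _PreparedComponent:
    surface = set(surface_residue_keys(structure))
    if params.trim_termini:
        surface &= trim_termini_keys(structure)
    windows = extract_windows(structure, residue_keys=surface)
    typed = type_windows(windows, db)
    prepared = _PreparedComponent(
        windows=typed,
        window_coords=(np.stack([w.coords.reshape(-1, 3) for w in typed])
                       if typed else np.empty((0, 20, 3))))
    if with_ghosts and typed:
        ghosts = generate_ghosts(typed, db, clash_structure=structure)
        if params.continuous_ghosts:
            ghosts = continuous_ghost_filter(ghosts)
        prepared.ghosts = ghosts
        prepared.ghost_coords = (np.stack([g.coords.reshape(-1, 3) for g in ghosts])
                                 if ghosts else np.empty((0, 20, 3)))
    return prepared


def _transform_windows(windows, coords, transform) -> list:
    moved = coords @ transform.rotation.T + transform.translation
    out = []
    for w, c in zip(windows, moved):
        out.append(FragmentWindow(w.central_key, w.residue_keys,
                                  c.reshape(-1, 4, 3), w.sequence, w.type_id))
    return out


def _transform_ghosts(ghosts, coords, transform) -> list:
    moved = coords @ transform.rotation.T + transform.translation
    out = []
    for g, c in zip(ghosts, moved):
        out.append(GhostFragment(g.source_window, g.cluster_id,
                                 c.reshape(-1, 4, 3), g.rmsd_cluster))
    return out


def evaluate_pose(pose: Pose, prep_a: _PreparedComponent,
                  prep_b: _PreparedComponent, db: FragmentDatabase,
                  params: DockingParams) -> Pose:
    """Attach observations and scores for the pose's current DOF values."""
    ghosts = _transform_ghosts(prep_a.ghosts, prep_a.ghost_coords,
                               pose.transform_a)
    windows_b = _transform_windows(prep_b.windows, prep_b.window_coords,
                                   pose.transform_b)
    threshold = min(MATCH_THRESHOLD, params.initial_rmsd_gate)
    obs = find_observations(ghosts, windows_b, db, match_threshold=threshold)
    obs = [o for o in obs if o.match >= params.match_value]
    pose.observations = obs
    pose.score_total, pose.score_normalized = nanohedra_score(obs)
    return pose


# ---------------------------------------------------------------------------
# Docking driver
# ---------------------------------------------------------------------------

def dock(olig_a: Structure, olig_b: Structure, entry=None,
         params: DockingParams | None = None, db: FragmentDatabase = None,
         ranges: dict | None = None) -> list:
    """Grid search over the 4 allowed DOF; returns poses carrying at least
    ``minimum_matched`` observations with match score >= ``match_value``,
    sorted by normalized score (descending)."""
    if entry is None:
        entry = get_entry("T")
    if params is None:
        params = DockingParams()
    if db is None:
        raise ValueError("a fragment database is required for docking")
    prep_a = prepare_component(olig_a, db, params, with_ghosts=True)
    prep_b = prepare_component(olig_b, db, params, with_ghosts=False)
    if not prep_a.windows or prep_a.ghosts is None or not prep_a.ghosts \
            or not prep_b.windows:
        log.warning("a component lacks typeable surface fragments; no poses")
        return []

    grid = enumerate_dof(entry, params.rot_step, params.trans_step,
                         ranges or {})
    poses = []
    for i, dof in enumerate(grid):
        pose = Pose(olig_a, olig_b, dof, entry, pose_id=i)
        evaluate_pose(pose, prep_a, prep_b, db, params)
        if len(pose.observations) >= params.minimum_matched:
            poses.append(pose)
    poses.sort(key=lambda p: (-p.score_normalized, p.pose_id))
    return poses


def cluster_poses(poses, translation_bin: float = 1.0,
                  angle_bin: float = 3.0) -> list:
    """Group poses by equality of the 6-D hash of their relative transform;
    each cluster is represented by its best-scoring pose."""
    groups: dict = {}
    for pose in poses:
        key = transform_hash(pose.relative_transform(), translation_bin, angle_bin)
        groups.setdefault(key, []).append(pose)
    clusters = []
    for key in sorted(groups):
        members = sorted(groups[key],
                         key=lambda p: (-p.score_normalized, p.pose_id))
        clusters.append({"hash": key, "representative": members[0],
                         "members": members})
    return clusters


def optimize_pose(pose: Pose, prep_a, prep_b, db: FragmentDatabase,
                  params: DockingParams,
                  improvement_stop: float = IMPROVEMENT_STOP,
                  min_step=MIN_STEP) -> tuple[Pose, list]:
    """Iterative local grid refinement of the 4 DOF.

    Each round samples the +/- one-step neighborhood combinatorially,
    moves to the best scoring point and halves the steps when no move
    helps; stops when relative improvement falls below ``improvement_stop``
    or the steps drop under ``min_step``.  Returns the refined pose and the
    (monotone non-decreasing) score trace.
    """
    rot_step, trans_step = params.rot_step, params.trans_step
    min_rot, min_trans = min_step
    if not pose.observations and pose.score_normalized == 0.0:
        evaluate_pose(pose, prep_a, prep_b, db, params)
    best = pose
    trace = [best.score_normalized]
    while True:
        current = best
        for offsets in itertools.product((-1, 0, 1), repeat=4):
            if offsets == (0, 0, 0, 0):
                continue
            dof = (current.dof[0] + offsets[0] * rot_step,
                   current.dof[1] + offsets[1] * trans_step,
                   current.dof[2] + offsets[2] * rot_step,
                   current.dof[3] + offsets[3] * trans_step)
            cand = Pose(current.component_a, current.component_b, dof,
                        current.entry, pose_id=current.pose_id)
            evaluate_pose(cand, prep_a, prep_b, db, params)
            if cand.score_normalized > best.score_normalized + 1e-12:
                best = cand
        trace.append(best.score_normalized)
        previous, latest = trace[-2], trace[-1]
        rel_gain = ((latest - previous) / previous if previous > 0
                    else (1.0 if latest > 0 else 0.0))
        if rel_gain < improvement_stop:
            break
        rot_step /= 2.0
        trans_step /= 2.0
        if rot_step < min_rot and trans_step < min_trans:
            break
    return best, trace


def filter_poses(poses, min_interface_residues: int = 0,
                 min_distinct_ss_elements: int = 0,
                 per_component_ss_minimum: int = 0, ss_maps=None) -> list:
    """Keep poses meeting interface-size and fragment secondary-structure
    diversity criteria.

    Distinct SS elements are counted as maximal runs of fragment residues
    lying within one contiguous non-coil segment of a chain.
    """
    from .metrics import secondary_structure

    survivors = []
    for pose in poses:
        frag_keys = {"A": set(), "B": set()}
        for o in pose.observations:
            frag_keys["A"].update(o.residues_a)
            frag_keys["B"].update(o.residues_b)
        interface_count = len(frag_keys["A"] | frag_keys["B"])
        if interface_count < min_interface_residues:
            continue
        counts = {}
        for label, comp in (("A", pose.component_a), ("B", pose.component_b)):
            ss = (ss_maps or {}).get(label) or secondary_structure(comp)
            counts[label] = _distinct_ss_elements(comp, frag_keys[label], ss)
        if counts["A"] + counts["B"] < min_distinct_ss_elements:
            continue
        if min(counts.values()) < per_component_ss_minimum:
            continue
        survivors.append(pose)
    return survivors


def _distinct_ss_elements(structure, fragment_keys, ss_map) -> int:
    """Number of non-coil segments containing at least one fragment residue."""
    count = 0
    for cid in structure.chain_ids:
        residues = structure.chain_residues(cid)
        in_segment = False
        segment_hit = False
        for r in residues:
            state = ss_map.get(r.key, "C")
            if state == "C":
                if in_segment and segment_hit:
                    count += 1
                in_segment = segment_hit = False
                continue
            in_segment = True
            if r.key in fragment_keys:
                segment_hit = True
        if in_segment and segment_hit:
            count += 1
    return count
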