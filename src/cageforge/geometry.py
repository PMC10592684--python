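"""Rigid transforms, Kabsch superposition, LDDT, transform hashing and
C-beta neighbor queries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform ``x -> R x + t``."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix has negative determinant")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def __matmul__(self, other):
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()


def align_z_to(axis) -> np.ndarray:
    """Rotation matrix taking the +z unit vector onto ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(np.dot(z, axis))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        return rotation_about_axis([1.0, 0.0, 0.0], 180.0)
    angle = np.arccos(np.clip(c, -1.0, 1.0))
    return Rotation.from_rotvec(angle * v / np.linalg.norm(v)).as_matrix()


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

class DegenerateGeometryError(ValueError):
    pass


def kabsch_superpose(X: np.ndarray, Y: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``X`` onto ``Y``.

    Returns the proper rigid transform ``T`` minimising ``||T(X) - Y||``
    together with the minimised RMSD.  Reflections are excluded.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("coordinate sets must share shape (n, 3)")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    # collinearity check: rank of the centred cloud
    if np.linalg.matrix_rank(X0, tol=1e-8) < 2:
        raise DegenerateGeometryError("points are collinear or coincident")
    H = X0.T @ Y0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    rmsd = float(np.sqrt(np.mean(np.sum((X0 @ R.T - Y0) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


def coord_rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """RMSD without superposition (coordinates already in one frame)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    return float(np.sqrt(np.mean(np.sum((X - Y) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# LDDT
# ---------------------------------------------------------------------------

DEFAULT_LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
DEFAULT_LDDT_RADIUS = 15.0


def lddt(model, reference, inclusion_radius: float = DEFAULT_LDDT_RADIUS,
         thresholds=DEFAULT_LDDT_THRESHOLDS, chain: str | None = None) -> float:
    """Superposition-free local distance difference test in [0, 1].

    Atoms are matched between model and reference by
    (chain, residue number, insertion code, atom name); inter-residue
    distances below ``inclusion_radius`` in the reference are checked for
    preservation at each threshold.
    """
    def atom_map(s):
        out = {}
        for r in s.residues:
            if chain is not None and r.chain_id != chain:
                continue
            for a in r.atoms:
                out[(r.chain_id, r.number, r.icode, a.name)] = (a.xyz, r.key)
        return out

    m_map, r_map = atom_map(model), atom_map(reference)
    keys = [k for k in r_map if k in m_map]
    if not keys:
        raise ValueError("no atom correspondence between model and reference")
    ref_xyz = np.array([r_map[k][0] for k in keys])
    mod_xyz = np.array([m_map[k][0] for k in keys])
    res_ids = [r_map[k][1] for k in keys]
    uniq = {rid: i for i, rid in enumerate(dict.fromkeys(res_ids))}
    res_idx = np.array([uniq[rid] for rid in res_ids])

    tree = cKDTree(ref_xyz)
    pairs = tree.query_pairs(inclusion_radius, output_type="ndarray")
    if pairs.size:
        pairs = pairs[res_idx[pairs[:, 0]] != res_idx[pairs[:, 1]]]
    if pairs.size == 0:
        return 1.0
    d_ref = np.linalg.norm(ref_xyz[pairs[:, 0]] - ref_xyz[pairs[:, 1]], axis=1)
    d_mod = np.linalg.norm(mod_xyz[pairs[:, 0]] - mod_xyz[pairs[:, 1]], axis=1)
    delta = np.abs(d_ref - d_mod)
    fractions = [(delta < thr).mean() for thr in thresholds]
    return float(np.mean(fractions))


# ---------------------------------------------------------------------------
# 6-D transform hashing
# ---------------------------------------------------------------------------

def euler_zyz(rotation: np.ndarray) -> np.ndarray:
    """Intrinsic z-y-z Euler angles in degrees, canonicalized to [0, 360).

    Gimbal-lock orientations resolve deterministically (scipy places the
    full rotation in the first angle).
    """
    import warnings

    with warnings.catch_warnings():
        # gimbal lock resolves to the canonical third-angle-zero choice
        warnings.simplefilter("ignore", UserWarning)
        angles = Rotation.from_matrix(rotation).as_euler("ZYZ", degrees=True)
    return np.mod(angles, 360.0)


def transform_hash(t: RigidTransform, translation_bin: float,
                   angle_bin: float) -> tuple:
    """Bin a rigid transform into a 6-integer key
    (three translations, three intrinsic z-y-z Euler angles)."""
    if translation_bin <= 0 or angle_bin <= 0:
        raise ValueError("bin widths must be positive")
    angles = euler_zyz(t.rotation)
    key_t = np.floor(t.translation / translation_bin).astype(int)
    key_a = np.floor(angles / angle_bin).astype(int)
    return tuple(key_t) + tuple(key_a)


# ---------------------------------------------------------------------------
# C-beta neighbor search
# ---------------------------------------------------------------------------

def cbeta_neighbors(structure, query_residues, target_residues,
                    cutoff: float) -> list:
    """Residue pairs whose C-beta atoms (CA proxy for glycine) lie within
    ``cutoff`` (inclusive).  Returns a list of (query, target) residues."""
    if not query_residues or not target_residues:
        return []
    q_xyz = np.array([r.cbeta() for r in query_residues])
    t_xyz = np.array([r.cbeta() for r in target_residues])
    tree = cKDTree(t_xyz)
    pairs = []
    for qi, hits in enumerate(tree.query_ball_point(q_xyz, cutoff)):
        for ti in hits:
            if query_residues[qi].key == target_residues[ti].key:
                continue
            pairs.append((query_residues[qi], target_residues[ti]))
    return pairs
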