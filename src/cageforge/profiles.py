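"""Per-residue amino-acid profiles: fragment-derived, evolutionary (.hhm),
their quality-weighted tertiary blend, cross-entropy and likelihood losses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._tables import AA_ALPHABET, AA_INDEX
from .fragdb import FRAGMENT_LENGTH, FragmentDatabase

log = logging.getLogger(__name__)

LOG_EPSILON = 1e-9   # additive smoothing inside every logarithm


@dataclass
class Profile:
    """L x 20 frequency matrix with per-row validity flags.

    Invalid rows mark positions with no information; they are excluded
    from every loss computation.
    """

    freqs: np.ndarray
    valid: np.ndarray = None
    flavor: str = "generic"

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != len(AA_ALPHABET):
            raise ValueError("profile must be L x 20")
        if self.valid is None:
            self.valid = np.ones(len(self.freqs), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        sums = self.freqs[self.valid].sum(axis=1)
        if len(sums) and not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("valid profile rows must sum to 1")

    def __len__(self):
        return len(self.freqs)

    @classmethod
    def uniform(cls, length: int, flavor: str = "uniform") -> "Profile":
        return cls(np.full((length, 20), 1.0 / 20), flavor=flavor)

    @classmethod
    def one_hot(cls, sequence: str, flavor: str = "sequence") -> "Profile":
        freqs = np.zeros((len(sequence), 20))
        valid = np.zeros(len(sequence), dtype=bool)
        for i, aa in enumerate(sequence):
            if aa in AA_INDEX:
                freqs[i, AA_INDEX[aa]] = 1.0
                valid[i] = True
        return cls(freqs, valid, flavor=flavor)


@dataclass
class BlendParams:
    """Controls the fragment/evolutionary blend: alpha is the maximum
    fragment weight; the thresholds are quality gates reducing it."""

    alpha: float = 0.5
    match_threshold: float = 0.5
    weight_threshold: float = 0.5


# ---------------------------------------------------------------------------
# Fragment profile
# ---------------------------------------------------------------------------

def fragment_profile(observations, db: FragmentDatabase, residue_keys) -> Profile:
    """Combine observation cluster distributions into per-residue rows.

    Each observation contributes, at every residue it covers, the cluster
    frequency row for that structural position scaled by m * t; rows are
    normalized by the summed m * t at the residue.  Residues without any
    weighted contribution are invalid rows.
    """
    index = {key: i for i, key in enumerate(residue_keys)}
    length = len(residue_keys)
    weighted = np.zeros((length, 20))
    totals = np.zeros(length)
    quality_m = {i: [] for i in range(length)}
    quality_t = {i: [] for i in range(length)}

    for obs in observations:
        cluster = db.cluster_by_id(obs.cluster_id)
        sides = ((obs.residues_a, 0), (obs.residues_b, FRAGMENT_LENGTH))
        for keys, offset in sides:
            for pos, key in enumerate(keys):
                row = index.get(key)
                if row is None:
                    continue
                t = cluster.weights[offset + pos]
                w = obs.match * t
                weighted[row] += w * cluster.freq[offset + pos]
                totals[row] += w
                quality_m[row].append(obs.match)
                quality_t[row].append(t)

    freqs = np.zeros((length, 20))
    valid = totals > 0
    freqs[valid] = weighted[valid] / totals[valid, None]
    observed = np.array([len(quality_m[i]) > 0 for i in range(length)])
    for i in np.flatnonzero(observed & ~valid):
        log.warning("residue %s has observations but zero total m*t", residue_keys[i])
    profile = Profile(freqs, valid, flavor="fragment")
    profile.mean_match = np.array(
        [np.mean(quality_m[i]) if quality_m[i] else 0.0 for i in range(length)])
    profile.mean_weight = np.array(
        [np.mean(quality_t[i]) if quality_t[i] else 0.0 for i in range(length)])
    return profile


# ---------------------------------------------------------------------------
# Evolutionary profile (.hhm)
# ---------------------------------------------------------------------------

def parse_hhm(text: str) -> Profile:
    """Parse a profile-HMM in the hhm dialect into frequencies.

    Emission value v becomes 2^(-v / 1000); '*' becomes 0; rows are
    renormalized to sum to 1.
    """
    lines = text.splitlines()
    aa_order = None
    start = None
    for i, line in enumerate(lines):
        if line.startswith("HMM"):
            fields = line.split()[1:]
            if len(fields) < 20:
                raise ValueError(f"malformed HMM header at line {i + 1}")
            aa_order = fields[:20]
            start = i + 3   # skip the transition header and null-model lines
            break
    if aa_order is None:
        raise ValueError("no HMM header found in hhm text")

    rows = []
    i = start
    while i < len(lines):
        line = lines[i]
        if line.startswith("//"):
            break
        fields = line.split()
        # match-state lines: residue letter, position, 20 emissions, position
        if len(fields) >= 22 and len(fields[0]) == 1 and fields[1].isdigit():
            values = fields[2:22]
            row = np.zeros(20)
            for aa, v in zip(aa_order, values):
                if v == "*":
                    freq = 0.0
                else:
                    try:
                        freq = 2.0 ** (-float(v) / 1000.0)
                    except ValueError as exc:
                        raise ValueError(f"bad emission at line {i + 1}") from exc
                if aa in AA_INDEX:
                    row[AA_INDEX[aa]] = freq
            rows.append(row)
            i += 3   # skip the transition line and separator
        else:
            i += 1
    if not rows:
        raise ValueError("no match states parsed from hhm text")
    freqs = np.array(rows)
    sums = freqs.sum(axis=1)
    valid = sums > 0
    freqs[valid] /= sums[valid, None]
    return Profile(freqs, valid, flavor="evolutionary")


def read_hhm(path) -> Profile:
    with open(path) as fh:
        return parse_hhm(fh.read())


def read_profile_tsv(path, flavor: str = "inference") -> Profile:
    """Read an L x 20 TSV (optional trailing validity column)."""
    rows, valid = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split()
            if len(fields) not in (20, 21):
                raise ValueError("profile TSV rows need 20 (+1 validity) columns")
            rows.append([float(v) for v in fields[:20]])
            valid.append(bool(int(fields[20])) if len(fields) == 21 else True)
    return Profile(np.array(rows), np.array(valid), flavor=flavor)


def write_profile_tsv(profile: Profile, path):
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(AA_ALPHABET) + "\tvalid\n")
        for row, ok in zip(profile.freqs, profile.valid):
            fh.write("\t".join(f"{v:.6f}" for v in row) + f"\t{int(ok)}\n")


# ---------------------------------------------------------------------------
# Tertiary blend
# ---------------------------------------------------------------------------

def blend_tertiary(frag: Profile, evo: Profile, params: BlendParams,
                   mean_match=None, mean_weight=None) -> Profile:
    """Quality-weighted mix of fragment and evolutionary rows.

    The fragment coefficient is alpha scaled down proportionally wherever
    the per-residue mean match or interaction weight falls short of its
    threshold: alpha' = alpha * min(1, m/m_th) * min(1, t/t_th).
    """
    if len(frag) != len(evo):
        raise ValueError("profiles must have equal length")
    if mean_match is None:
        mean_match = getattr(frag, "mean_match", np.ones(len(frag)))
    if mean_weight is None:
        mean_weight = getattr(frag, "mean_weight", np.ones(len(frag)))

    freqs = np.zeros_like(evo.freqs)
    valid = np.zeros(len(evo), dtype=bool)
    alphas = np.zeros(len(evo))
    for i in range(len(evo)):
        has_frag, has_evo = frag.valid[i], evo.valid[i]
        if not has_frag and not has_evo:
            continue
        if not has_frag:
            freqs[i] = evo.freqs[i]
            valid[i] = True
            continue
        m_scale = 1.0 if params.match_threshold <= 0 else min(
            1.0, mean_match[i] / params.match_threshold)
        t_scale = 1.0 if params.weight_threshold <= 0 else min(
            1.0, mean_weight[i] / params.weight_threshold)
        a = params.alpha * m_scale * t_scale
        alphas[i] = a
        if has_evo:
            freqs[i] = a * frag.freqs[i] + (1.0 - a) * evo.freqs[i]
        else:
            freqs[i] = frag.freqs[i]
        valid[i] = True
    out = Profile(freqs, valid, flavor="tertiary")
    out.alphas = alphas
    return out


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def _subset_indices(profile: Profile, subset):
    if subset is None:
        idx = np.flatnonzero(profile.valid)
    else:
        idx = np.asarray(sorted(subset), dtype=int)
    if idx.size == 0:
        raise ValueError("empty position subset")
    return idx


def cross_entropy(p: Profile, q: Profile, subset=None):
    """Per-residue CE(P, Q) = -sum_aa P ln(Q + eps) and its mean over the
    subset of positions valid in both profiles."""
    if len(p) != len(q):
        raise ValueError("profiles must have equal length")
    idx = _subset_indices(p, subset)
    idx = idx[p.valid[idx] & q.valid[idx]]
    if idx.size == 0:
        raise ValueError("no jointly valid positions in subset")
    per_residue = -np.sum(p.freqs[idx] * np.log(q.freqs[idx] + LOG_EPSILON), axis=1)
    return dict(zip(idx.tolist(), per_residue)), float(per_residue.mean())


def profile_loss(sequence: str, profile: Profile, subset=None) -> float:
    """Mean negative log likelihood of the sequence under the profile.

    Serves the fragment-profile loss, the evolutionary-profile loss and
    the score arithmetic on externally supplied inference profiles alike.
    """
    if len(sequence) != len(profile):
        raise ValueError("sequence/profile length mismatch")
    idx = _subset_indices(profile, subset)
    idx = idx[profile.valid[idx]]
    vals = []
    for i in idx:
        aa = sequence[i]
        if aa not in AA_INDEX:
            continue
        vals.append(-np.log(profile.freqs[i, AA_INDEX[aa]] + LOG_EPSILON))
    if not vals:
        raise ValueError("no scorable positions in subset")
    return float(np.mean(vals))


def sequence_identity(a: str, b: str, subset=None) -> float:
    """Percent identity over the subset (all positions by default)."""
    if len(a) != len(b):
        raise ValueError("sequence length mismatch")
    idx = range(len(a)) if subset is None else sorted(subset)
    idx = list(idx)
    if not idx:
        raise ValueError("empty position subset")
    matches = sum(1 for i in idx if a[i] == b[i])
    return 100.0 * matches / len(idx)


def mutation_fraction(designed: str, reference: str, subset=None) -> float:
    return 1.0 - sequence_identity(designed, reference, subset) / 100.0
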