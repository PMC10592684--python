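import numpy as np
import pytest

from cageforge.fixtures import ideal_helix_backbone
from cageforge.fragdb import (FRAGMENT_LENGTH, FragmentCluster,
                              FragmentDatabase)
from cageforge.fragments import (FragmentWindow, GhostFragment, Observation,
                                 assign_fragment_type, continuous_ghost_filter,
                                 find_observations, generate_ghosts,
                                 match_score, nanohedra_score, type_windows)
from cageforge.geometry import coord_rmsd, kabsch_superpose, rotation_about_axis
from cageforge.structure import Atom, Structure


def _uniform_freq():
    return np.full((2 * FRAGMENT_LENGTH, 20), 1.0 / 20)


def _cluster(cid, rep_mapped, rep_paired, rmsd_cluster=0.5):
    return FragmentCluster(
        cluster_id=cid, type_pair=("1", "1"),
        rep_mapped=rep_mapped, rep_paired=rep_paired,
        rmsd_cluster=rmsd_cluster, member_count=5,
        freq=_uniform_freq(), weights=np.full(2 * FRAGMENT_LENGTH, 0.8))


def _db_with(clusters, representatives=None, typing_threshold=0.3):
    db = FragmentDatabase(typing_threshold=typing_threshold)
    db.representatives = representatives or {"1": clusters[0].rep_mapped}
    db.clusters[("1", "1")] = clusters
    return db


def _window(coords, central=("A", 3, ""), chain="A"):
    keys = [(chain, i + 1, "") for i in range(FRAGMENT_LENGTH)]
    return FragmentWindow(central_key=central, residue_keys=keys,
                          coords=coords, sequence="LLLLL", type_id="1")


class TestMatchScore:
    # closed-form anchors forced by the scoring formula
    @pytest.mark.parametrize("rmsd,expected", [
        (0.0, 1.0), (0.5, 0.5), (1.0, 0.2),
    ])
    def test_closed_form(self, rmsd, expected):
        assert match_score(rmsd, 0.5) == pytest.approx(expected)

    def test_monotone_decreasing(self):
        grid = np.linspace(0, 5, 101)
        values = [match_score(r, 0.7) for r in grid]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            match_score(-0.1, 0.5)

    def test_singleton_cluster_floor(self):
        assert 0 < match_score(1.0, 0.0) <= 1.0


class TestAssignType:
    def test_exact_representative(self):
        base = ideal_helix_backbone(FRAGMENT_LENGTH)
        db = _db_with([_cluster("1_1_0", base, base + [20, 0, 0])])
        type_id, rmsd = assign_fragment_type(base, db)
        assert type_id == "1"
        assert rmsd < 1e-9

    def test_tie_breaks_to_lowest_type_id(self):
        base = ideal_helix_backbone(FRAGMENT_LENGTH)
        db = FragmentDatabase(typing_threshold=5.0)
        db.representatives = {"2": base.copy(), "1": base.copy()}
        type_id, _ = assign_fragment_type(base, db)
        assert type_id == "1"

    def test_untypeable_returns_none(self):
        base = ideal_helix_backbone(FRAGMENT_LENGTH)
        extended = ideal_helix_backbone(FRAGMENT_LENGTH, phi=-120.0, psi=120.0)
        db = _db_with([_cluster("1_1_0", base, base + [20, 0, 0])],
                      typing_threshold=0.1)
        type_id, _ = assign_fragment_type(extended, db)
        assert type_id is None

    def test_argmin_agrees_with_exhaustive_oracle(self, rng):
        base = ideal_helix_backbone(FRAGMENT_LENGTH)
        extended = ideal_helix_backbone(FRAGMENT_LENGTH, phi=-120.0, psi=120.0)
        mixed = ideal_helix_backbone(FRAGMENT_LENGTH, phi=-80.0, psi=0.0)
        reps = {"1": base, "2": extended, "3": mixed}
        db = FragmentDatabase(typing_threshold=10.0, representatives=reps)
        for _ in range(500):
            src = list(reps.values())[rng.integers(3)]
            window = src + rng.normal(0, 0.3, size=src.shape)
            type_id, rmsd = assign_fragment_type(window, db)
            oracle = {}
            for tid, rep in reps.items():
                _, r = kabsch_superpose(rep.reshape(-1, 3),
                                        window.reshape(-1, 3))
                oracle[tid] = r
            best = min(sorted(oracle), key=lambda t: oracle[t])
            assert type_id == best
            assert rmsd == pytest.approx(oracle[best])


class TestGhosts:
    def _setup(self):
        base = ideal_helix_backbone(FRAGMENT_LENGTH)
        paired = base + np.array([12.0, 0.0, 0.0])
        cluster = _cluster("1_1_0", base, paired)
        db = _db_with([cluster])
        window = _window(base.copy())
        return base, paired, db, window

    def test_open_space_yields_one_ghost(self):
        base, paired, db, window = self._setup()
        ghosts = generate_ghosts([window], db, clash_structure=None)
        assert len(ghosts) == 1
        assert coord_rmsd(ghosts[0].coords.reshape(-1, 3),
                          paired.reshape(-1, 3)) < 1e-9

    def test_blocking_wall_removes_ghost(self):
        base, paired, db, window = self._setup()
        wall_atoms = [
            Atom(i + 1, "CA", "C", "ALA", "W", i + 1, "",
                 paired[i % FRAGMENT_LENGTH, 1].copy())
            for i in range(FRAGMENT_LENGTH)
        ]
        wall = Structure(wall_atoms)
        assert generate_ghosts([window], db, clash_structure=wall) == []

    def test_count_matches_brute_force_enumeration(self, rng):
        base = ideal_helix_backbone(FRAGMENT_LENGTH)
        clusters = [
            _cluster(f"1_1_{i}", base,
                     base + np.array([10.0 + 6 * i, 0.0, 0.0]))
            for i in range(3)
        ]
        db = _db_with(clusters)
        windows = [_window(base + np.array([0, 0, 3.0 * i]),
                           central=("A", 3 + i, ""))
                   for i in range(4)]
        blocker_atoms = [Atom(i + 1, "CA", "C", "ALA", "W", i + 1, "",
                              rng.uniform(5, 25, 3)) for i in range(30)]
        blocker = Structure(blocker_atoms)
        ghosts = generate_ghosts(windows, db, clash_structure=blocker)

        # independent enumeration with its own clash check
        expected = 0
        blocker_xyz = blocker.coords
        for w in windows:
            for c in clusters:
                t, _ = kabsch_superpose(c.rep_mapped.reshape(-1, 3), w.flat())
                placed = t.apply(c.rep_paired.reshape(-1, 3))
                clash = False
                for p in placed:
                    if np.min(np.linalg.norm(blocker_xyz - p, axis=1)) < 2.1:
                        clash = True
                        break
                if not clash:
                    expected += 1
        assert len(ghosts) == expected


class TestObservations:
    def _setup(self):
        base = ideal_helix_backbone(FRAGMENT_LENGTH)
        paired = base + np.array([12.0, 0.0, 0.0])
        cluster = _cluster("1_1_0", base, paired)
        db = _db_with([cluster])
        ghost = GhostFragment(_window(base), "1_1_0", paired.copy(), 0.5)
        return paired, db, ghost

    def test_exact_match_scores_one(self):
        paired, db, ghost = self._setup()
        window_b = _window(paired.copy(), central=("B", 3, ""), chain="B")
        obs = find_observations([ghost], [window_b], db)
        assert len(obs) == 1
        assert obs[0].match == pytest.approx(1.0)
        assert obs[0].rmsd < 1e-9

    def test_beyond_threshold_no_observation(self):
        paired, db, ghost = self._setup()
        window_b = _window(paired + np.array([1.5, 0, 0]),
                           central=("B", 3, ""), chain="B")
        assert find_observations([ghost], [window_b], db,
                                 match_threshold=1.0) == []

    def test_planted_count(self):
        paired, db, ghost = self._setup()
        windows = [
            _window(paired.copy(), central=("B", 3, ""), chain="B"),
            _window(paired + np.array([0.05, 0, 0]), central=("B", 8, ""), chain="B"),
            _window(paired + np.array([5.0, 0, 0]), central=("B", 13, ""), chain="B"),
        ]
        obs = find_observations([ghost], windows, db)
        assert len(obs) == 2


class TestContinuousGhosts:
    def _ghost(self, coords, source_res):
        w = _window(ideal_helix_backbone(FRAGMENT_LENGTH),
                    central=("A", source_res, ""))
        return GhostFragment(w, "1_1_0", coords, 0.5)

    def test_colocating_pair_kept(self):
        spot = ideal_helix_backbone(FRAGMENT_LENGTH) + np.array([15.0, 0, 0])
        g1 = self._ghost(spot.copy(), 3)
        g2 = self._ghost(spot + 0.01, 7)   # residues i and i+4
        lone = self._ghost(spot + np.array([40.0, 0, 0]), 11)
        kept = continuous_ghost_filter([g1, g2, lone])
        assert {g.source_key[1] for g in kept} == {3, 7}

    def test_same_source_not_continuous(self):
        spot = ideal_helix_backbone(FRAGMENT_LENGTH) + np.array([15.0, 0, 0])
        g1 = self._ghost(spot.copy(), 3)
        g2 = self._ghost(spot.copy(), 3)
        assert continuous_ghost_filter([g1, g2]) == []

    def test_matches_all_pairs_oracle(self, rng):
        ghosts = []
        for i in range(30):
            coords = (ideal_helix_backbone(FRAGMENT_LENGTH)
                      + rng.uniform(-4, 4, 3))
            ghosts.append(self._ghost(coords, int(rng.integers(1, 10))))
        kept = continuous_ghost_filter(ghosts, overlap_threshold=1.0)
        expected = set()
        for i in range(len(ghosts)):
            for j in range(len(ghosts)):
                if i == j or ghosts[i].source_key == ghosts[j].source_key:
                    continue
                if coord_rmsd(ghosts[i].coords.reshape(-1, 3),
                              ghosts[j].coords.reshape(-1, 3)) <= 1.0:
                    expected.add(i)
        assert {id(g) for g in kept} == {id(ghosts[i]) for i in expected}


class TestNanohedraScore:
    def test_empty(self):
        assert nanohedra_score([]) == (0.0, 0.0)

    def _obs(self, res_a, res_b, m):
        return Observation(residue_a=("A", res_a, ""), residue_b=("B", res_b, ""),
                           cluster_id="1_1_0", rmsd=0.0, match=m)

    def test_perfect_pose_reaches_two(self):
        # every central residue accumulates exactly the per-residue cap
        obs = [self._obs(1, 1, 1.0), self._obs(1, 1, 1.0),
               self._obs(2, 2, 1.0), self._obs(2, 2, 1.0)]
        total, normalized = nanohedra_score(obs)
        assert normalized == pytest.approx(2.0)
        assert total == pytest.approx(2.0 * 4)

    def test_randomized_bound(self, rng):
        for _ in range(2000):
            n = int(rng.integers(1, 25))
            obs = [self._obs(int(rng.integers(1, 6)), int(rng.integers(1, 6)),
                             float(rng.uniform(0, 1))) for _ in range(n)]
            _, normalized = nanohedra_score(obs)
            assert normalized <= 2.0 + 1e-12

    def test_symmetric_residue_pair_set(self, scenario, t_entry):
        """Swapping ghost/fragment roles preserves the matched pair set."""
        from cageforge.docking import (DockingParams, Pose, evaluate_pose,
                                       prepare_component)
        db = scenario["db"]
        params = DockingParams()
        # forward: ghosts from A
        prep_a = prepare_component(scenario["a"], db, params, with_ghosts=True)
        prep_b = prepare_component(scenario["b"], db, params, with_ghosts=False)
        pose = Pose(scenario["a"], scenario["b"],
                    tuple(scenario["truth"]["dof"]), t_entry)
        evaluate_pose(pose, prep_a, prep_b, db, params)
        forward = {(o.residue_a[:2], o.residue_b[:2]) for o in pose.observations}

        # reverse: ghosts from B using the mirrored database
        from cageforge.fragdb import FragmentDatabase
        mirrored = FragmentDatabase(typing_threshold=db.typing_threshold,
                                    representatives=db.representatives)
        mirrored.clusters[("1", "1")] = [
            type(c)(cluster_id=c.cluster_id, type_pair=c.type_pair,
                    rep_mapped=c.rep_paired, rep_paired=c.rep_mapped,
                    rmsd_cluster=c.rmsd_cluster, member_count=c.member_count,
                    freq=c.freq, weights=c.weights)
            for c in db.all_clusters()
        ]
        prep_b2 = prepare_component(scenario["b"], mirrored, params,
                                    with_ghosts=True)
        prep_a2 = prepare_component(scenario["a"], mirrored, params,
                                    with_ghosts=False)
        pose2 = Pose(scenario["b"], scenario["a"],
                     (scenario["truth"]["dof"][2], scenario["truth"]["dof"][3],
                      scenario["truth"]["dof"][0], scenario["truth"]["dof"][1]),
                     t_entry)
        # swap axes: component order reversed
        import cageforge.docking as dk
        pose2_a = dk.dof_transform(t_entry.component_axes["B"],
                                   scenario["truth"]["dof"][2],
                                   scenario["truth"]["dof"][3])
        pose2_b = dk.dof_transform(t_entry.component_axes["A"],
                                   scenario["truth"]["dof"][0],
                                   scenario["truth"]["dof"][1])
        ghosts = dk._transform_ghosts(prep_b2.ghosts, prep_b2.ghost_coords,
                                      pose2_a)
        windows = dk._transform_windows(prep_a2.windows, prep_a2.window_coords,
                                        pose2_b)
        obs = find_observations(ghosts, windows, mirrored)
        obs = [o for o in obs if o.match >= params.match_value]
        reverse = {(o.residue_b[:2], o.residue_a[:2]) for o in obs}
        assert forward == reverse
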