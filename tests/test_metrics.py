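import math

import numpy as np
import pytest

from cageforge.geometry import RigidTransform, rotation_about_axis
from cageforge.metrics import (RASA_BURIAL_THRESHOLD, cbeta_separation_stats,
                               classify_interface_residues,
                               composition_similarity, hci_sites,
                               hydrogen_bonds, hydrophobic_collapse_index,
                               buried_unsat_density, interface_bsa,
                               interface_metrics, interface_residue_keys,
                               parse_stride, relative_sasa, residue_sasa,
                               sasa, secondary_structure, spike_ratio,
                               ss_fractions)
from cageforge.structure import Atom, Structure
from cageforge._tables import PROBE_RADIUS, VDW_RADII


def _atom(serial, name, element, xyz, res=1, chain="A", res_name="ALA"):
    return Atom(serial, name, element, res_name, chain, res, "",
                np.array(xyz, dtype=float))


@pytest.fixture(scope="module")
def pose_complex(request):
    docked = request.getfixturevalue("docked")
    return docked["poses"][0].complex_structure()


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        s = Structure([_atom(1, "O", "O", [0, 0, 0])])
        area = sasa(s, n_points=960)[0]
        exact = 4 * math.pi * (VDW_RADII["O"] + PROBE_RADIUS) ** 2
        assert abs(area - exact) / exact < 0.01

    def test_two_overlapping_atoms_grid_oracle(self):
        d = 2.0
        s = Structure([_atom(1, "C", "C", [0, 0, 0]),
                       _atom(2, "C", "C", [d, 0, 0], res=2)])
        areas = sasa(s, n_points=960)
        # independent dense-grid oracle
        r = VDW_RADII["C"] + PROBE_RADIUS
        n = 20000
        i = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        theta = math.pi * (1 + 5 ** 0.5) * i
        pts = np.column_stack((np.sin(phi) * np.cos(theta),
                               np.sin(phi) * np.sin(theta), np.cos(phi))) * r
        exposed0 = np.sum(np.linalg.norm(pts - [d, 0, 0], axis=1) > r) / n
        oracle = exposed0 * 4 * math.pi * r ** 2
        assert areas[0] == pytest.approx(oracle, rel=0.02)
        assert areas[0] == pytest.approx(areas[1], rel=0.02)

    def test_caged_atom_zero(self):
        atoms = [_atom(1, "C", "C", [0, 0, 0])]
        k = 2
        for i in range(50):
            phi = math.acos(1 - 2 * (i + 0.5) / 50)
            theta = math.pi * (1 + 5 ** 0.5) * (i + 0.5)
            xyz = 2.0 * np.array([math.sin(phi) * math.cos(theta),
                                  math.sin(phi) * math.sin(theta),
                                  math.cos(phi)])
            atoms.append(_atom(k, "C", "C", xyz, res=k))
            k += 1
        s = Structure(atoms)
        assert sasa(s)[0] == pytest.approx(0.0, abs=1e-9)

    def test_quadrature_convergence(self, trimer):
        total_960 = sasa(trimer, n_points=960).sum()
        total_1920 = sasa(trimer, n_points=1920).sum()
        assert abs(total_1920 - total_960) / total_960 < 0.005


class TestBsa:
    def test_separated_components_zero_bsa(self, trimer):
        from cageforge.fixtures import make_helical_trimer
        far = make_helical_trimer(16, seed=5).transformed(
            RigidTransform(np.eye(3), np.array([500.0, 0, 0])))
        merged = Structure.concatenate([trimer, far], entity_names=["A", "B"])
        record = interface_bsa(merged)
        assert record["total"] == pytest.approx(0.0, abs=1e-6)

    def test_two_atom_contact_closed_form(self):
        d = 3.0
        merged = Structure([_atom(1, "C", "C", [0, 0, 0], chain="A"),
                            _atom(2, "C", "C", [d, 0, 0], chain="B")])
        merged.entities = {"A": ["A"], "B": ["B"]}
        record = interface_bsa(merged)
        # closed form: each sphere loses a cap of area 2*pi*r*h
        r = VDW_RADII["C"] + PROBE_RADIUS
        h = r - d / 2.0
        expected = 2 * (2 * math.pi * r * h)
        assert record["total"] == pytest.approx(expected, rel=0.01)

    def test_polarity_partition(self, pose_complex):
        record = interface_bsa(pose_complex)
        assert record["polar"] + record["apolar"] == \
            pytest.approx(record["total"], abs=1e-6)
        assert record["polar"] >= 0 and record["apolar"] >= 0


class TestResidueClasses:
    def test_classes_cover_and_disjoint(self, pose_complex):
        classes = classify_interface_residues(pose_complex)
        union = classes["core"] | classes["rim"] | classes["support"]
        assert union == classes["interface"]
        assert not (classes["core"] & classes["rim"])
        assert not (classes["core"] & classes["support"])
        assert not (classes["rim"] & classes["support"])

    def test_matches_brute_force_thresholding(self, pose_complex):
        record = interface_bsa(pose_complex)
        classes = classify_interface_residues(pose_complex,
                                              bsa_record=record)
        rasa_cx = relative_sasa(pose_complex, record["complex_areas"])
        rasa_mono = {}
        for group in record["groups"]:
            part = pose_complex.select_chains(group)
            rasa_mono.update(relative_sasa(part))
        for key in interface_residue_keys(record):
            if rasa_cx[key] >= RASA_BURIAL_THRESHOLD:
                expected = "rim"
            elif rasa_mono[key] >= RASA_BURIAL_THRESHOLD:
                expected = "core"
            else:
                expected = "support"
            assert key in classes[expected]


class TestCompositionSimilarity:
    def test_exact_expectation_scores_one(self):
        bsa = 2000.0
        core, rim, support = 0.01 * bsa + 0.6, 0.01 * bsa - 2.5, 0.006 * bsa + 5
        assert composition_similarity(bsa, core, rim, support) == \
            pytest.approx(1.0)

    def test_all_zero_counts_score_zero(self):
        assert composition_similarity(2000.0, 0, 0, 0) == pytest.approx(0.0)

    def test_hand_evaluated_counts(self):
        # expected at BSA 2000: core 20.6, rim 17.5, support 17
        value = composition_similarity(2000.0, 15, 10, 17)
        hand = ((1 - abs(20.6 - 15) / 20.6)
                + (1 - abs(17.5 - 10) / 17.5)
                + (1 - abs(17.0 - 17) / 17.0)) / 3.0
        assert value == pytest.approx(hand)
        assert value == pytest.approx(0.76652797, abs=1e-6)

    def test_bounded_after_clamping(self, rng):
        for _ in range(500):
            v = composition_similarity(float(rng.uniform(300, 5000)),
                                       int(rng.integers(0, 200)),
                                       int(rng.integers(0, 200)),
                                       int(rng.integers(0, 200)))
            assert 0.0 <= v <= 1.0

    def test_nonpositive_bsa_rejected(self):
        with pytest.raises(ValueError):
            composition_similarity(0.0, 1, 1, 1)


class TestSecondaryStructure:
    def test_ideal_helix_assigned_h(self, trimer):
        ss = secondary_structure(trimer)
        interior = [r.key for r in trimer.chain_residues("A")][1:-1]
        assert all(ss[k] == "H" for k in interior)

    def test_extended_chain_assigned_e(self):
        from cageforge.fixtures import ideal_helix_backbone, _backbone_atoms
        bb = ideal_helix_backbone(8, phi=-120.0, psi=120.0)
        s = Structure(_backbone_atoms("A", "AAAAAAAA", bb))
        ss = secondary_structure(s)
        interior = [r.key for r in s.residues][1:-1]
        assert all(ss[k] == "E" for k in interior)

    def test_stride_file_overrides(self):
        text = ("ASG  ALA A    1    1    H   AlphaHelix    -57.0    -47.0  100.0\n"
                "ASG  ALA A    2    2    E   Strand        -120.0   120.0  100.0\n"
                "ASG  ALA A    3    3    T   Turn          -60.0    -30.0  100.0\n")
        ss = parse_stride(text)
        assert ss[("A", 1, "")] == "H"
        assert ss[("A", 2, "")] == "E"
        assert ss[("A", 3, "")] == "C"

    def test_fractions_denominator(self):
        ss = {("A", 1, ""): "H", ("A", 2, ""): "H", ("A", 3, ""): "C",
              ("A", 4, ""): "E"}
        fr = ss_fractions(ss, list(ss))
        assert fr["helix"] == pytest.approx(50.0)
        assert fr["strand"] == pytest.approx(25.0)
        assert fr["coil"] == pytest.approx(25.0)
        assert fr["helix"] + fr["strand"] + fr["coil"] == pytest.approx(100.0)


def _hbond_toy(distance, angle_deg):
    """Backbone N-H donor (chain A) vs carbonyl O acceptor (chain B)."""
    n = np.array([0.0, 0, 0])
    h = np.array([1.0, 0, 0])
    # acceptor placed so the N-H...O angle equals angle_deg
    theta = math.radians(180.0 - angle_deg)
    o = h + (distance - 1.0) * np.array([math.cos(theta), math.sin(theta), 0])
    atoms = [
        _atom(1, "N", "N", n, res=1, chain="A"),
        _atom(2, "H", "H", h, res=1, chain="A"),
        _atom(3, "CA", "C", [-1.0, -1.0, 0], res=1, chain="A"),
        _atom(4, "O", "O", o, res=5, chain="B"),
        _atom(5, "C", "C", o + [1.2, 0, 0], res=5, chain="B"),
    ]
    s = Structure(atoms)
    s.entities = {"A": ["A"], "B": ["B"]}
    return s


class TestHydrogenBonds:
    def test_ideal_geometry_detected(self):
        bonds = hydrogen_bonds(_hbond_toy(2.9, 165.0))
        assert len(bonds) == 1

    def test_long_distance_rejected(self):
        assert hydrogen_bonds(_hbond_toy(4.5, 165.0)) == []

    def test_bad_angle_rejected(self):
        assert hydrogen_bonds(_hbond_toy(2.9, 90.0)) == []

    def test_buried_unsat_density_hand_computed(self):
        # one donor N from chain A encased by a carbon shell from chain B
        atoms = [_atom(1, "N", "N", [0, 0, 0], res=1, chain="A")]
        k = 2
        for i in range(60):
            phi = math.acos(1 - 2 * (i + 0.5) / 60)
            theta = math.pi * (1 + 5 ** 0.5) * (i + 0.5)
            xyz = 4.0 * np.array([math.sin(phi) * math.cos(theta),
                                  math.sin(phi) * math.sin(theta),
                                  math.cos(phi)])
            atoms.append(_atom(k, "CB", "C", xyz, res=k, chain="B"))
            k += 1
        s = Structure(atoms)
        s.entities = {"A": ["A"], "B": ["B"]}
        record = interface_bsa(s)
        density, count = buried_unsat_density(s, bsa_record=record)
        assert count == 1
        assert density == pytest.approx(1.0 / (record["total"] / 1000.0))


class TestHci:
    def test_poly_hydrophobic_over_poly_serine(self):
        designed = "L" * 30
        reference = "S" * 30
        sites = hci_sites(designed, reference)
        assert sites == list(range(30))   # every window fully hydrophobic

    def test_identical_sequences_no_sites(self):
        seq = "LLLLSSSSLLLL"
        assert hci_sites(seq, seq) == []

    def test_hand_windowed_cluster(self):
        reference = "S" * 10 + "LLLL" + "S" * 16
        designed = "S" * 10 + "WWWWFF" + "S" * 14
        sites = hci_sites(designed, reference)
        hci_d = hydrophobic_collapse_index(designed)
        hci_r = hydrophobic_collapse_index(reference)
        expected = [i for i in range(30)
                    if hci_d[i] > 0.48 and hci_r[i] <= 0.48]
        assert sites == expected
        assert sites   # the planted W/F cluster creates new sites

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hci_sites("AA", "AAA")


class TestSpikeRatio:
    def test_equidistant_components_zero(self):
        a = np.array([[-1.0, 0, 0], [-1.0, 0, 0]])
        b = np.array([[1.0, 0, 0], [1.0, 0, 0]])
        assert spike_ratio(a, b) == pytest.approx(0.0)

    def test_twice_distance_half(self):
        a = np.array([[0.0, 0, 0], [0.0, 0, 0]])
        b = np.array([[3.0, 0, 0]])
        # combined centre of mass sits at x=1: d_a=1, d_b=2
        assert spike_ratio(a, b) == pytest.approx(0.5)

    def test_four_times_distance(self):
        a = np.array([[1.0, 0, 0]])
        b = np.array([[4.0, 0, 0]])
        assert spike_ratio(a, b, center=np.zeros(3)) == pytest.approx(0.75)

    def test_rigid_transform_invariance(self, rng):
        a = rng.normal(size=(30, 3)) + [5, 0, 0]
        b = rng.normal(size=(20, 3)) - [9, 2, 1]
        base = spike_ratio(a, b)
        rot = rotation_about_axis(rng.normal(size=3), 77.0)
        shift = rng.uniform(-30, 30, 3)
        assert spike_ratio(a @ rot.T + shift, b @ rot.T + shift) == \
            pytest.approx(base)

    def test_degenerate_rejected(self):
        z = np.zeros((2, 3))
        with pytest.raises(ValueError):
            spike_ratio(z, z)


class TestCbetaSeparation:
    def test_matches_exhaustive_oracle(self, pose_complex):
        record = interface_bsa(pose_complex)
        value = cbeta_separation_stats(pose_complex, bsa_record=record)
        interface = set(interface_residue_keys(record))
        groups = record["groups"]
        group_of = {c: gi for gi, g in enumerate(groups) for c in g}
        residues = [r for r in pose_complex.residues if r.key in interface]
        over = total = 0
        for r in residues:
            others = [q for q in residues
                      if group_of[q.chain_id] != group_of[r.chain_id]]
            if not others:
                continue
            dmin = min(np.linalg.norm(r.cbeta() - q.cbeta()) for q in others)
            total += 1
            if dmin > 8.0:
                over += 1
        assert value == pytest.approx(100.0 * over / total)

    def test_all_close_contacts_zero(self):
        atoms = []
        for i in range(3):
            atoms.append(_atom(2 * i + 1, "CA", "C", [i * 3.0, 0, 0],
                               res=i + 1, chain="A"))
            atoms.append(_atom(2 * i + 2, "CB", "C", [i * 3.0, 1.0, 0],
                               res=i + 1, chain="A"))
        for i in range(3):
            atoms.append(_atom(100 + 2 * i, "CA", "C", [i * 3.0, 5.0, 0],
                               res=i + 1, chain="B"))
            atoms.append(_atom(101 + 2 * i, "CB", "C", [i * 3.0, 4.0, 0],
                               res=i + 1, chain="B"))
        s = Structure(atoms)
        s.entities = {"A": ["A"], "B": ["B"]}
        assert cbeta_separation_stats(s) == pytest.approx(0.0)


def test_interface_metrics_record(pose_complex, docked):
    record = interface_metrics(pose_complex,
                               observations=docked["poses"][0].observations)
    assert record["bsa_polar"] + record["bsa_apolar"] == \
        pytest.approx(record["bsa_total"], abs=1e-6)
    assert record["interface_residues"] == \
        record["core"] + record["rim"] + record["support"]
    assert record["percent_helix"] + record["percent_strand"] + \
        record["percent_coil"] == pytest.approx(100.0)
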