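"""Structure I/O, helix-axis fitting, crossing angles, VDW distances."""

import numpy as np
import pytest

import oracles
from muklock import (
    AtomRecord,
    BONDI,
    StructureModel,
    crossing_angle,
    fit_duplex_axis,
    min_backbone_vdw_distance,
    read_structure,
    write_structure,
)
from muklock import synthetic
from muklock.errors import DataError
from muklock.structgeom import HelixAxisFit, parse_selection

MINIMAL_PDB = """\
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       4.000   5.000   6.500  1.00  0.00           C
END
"""

# synthetic 5-atom interface built for an exhaustive hand-checked pair table
FIVE_ATOM_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  N   ALA A   1       1.500   0.000   0.000  1.00  0.00           N
ATOM      3  CA  GLY B   1       0.000   0.000   4.000  1.00  0.00           C
ATOM      4  O   GLY B   1       1.500   0.500   3.500  1.00  0.00           O
ATOM      5  C   GLY B   2       3.000   0.000   1.000  1.00  0.00           C
END
"""


def rigid_transform(model, rng):
    """Random rotation + translation of all atoms."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    shift = rng.uniform(-50, 50, 3)
    atoms = []
    for a in model.atoms:
        p = rot @ a.pos + shift
        atoms.append(AtomRecord(a.chain_id, a.residue_number, a.residue_name,
                                a.atom_name, a.element,
                                float(p[0]), float(p[1]), float(p[2])))
    return StructureModel(atoms=tuple(atoms), source_format=model.source_format)


class TestStructureIO:
    def test_minimal_pdb_coordinates_exact(self, tmp_path):
        p = tmp_path / "two.pdb"
        p.write_text(MINIMAL_PDB)
        model = read_structure(p)
        assert len(model.atoms) == 2
        assert model.atoms[0].pos == pytest.approx([1.0, 2.0, 3.0])
        assert model.atoms[1].pos == pytest.approx([4.0, 5.0, 6.5])

    def test_pdb_and_mmcif_round_trip_identical_atoms(self, tmp_path):
        scene = synthetic.gen_helix_scene(30.0, 10, seed=1).scene
        pdb, cif = tmp_path / "s.pdb", tmp_path / "s.cif"
        write_structure(scene, pdb)
        write_structure(scene, cif)
        m1, m2 = read_structure(pdb), read_structure(cif)

        def key(model):
            return sorted((a.chain_id, a.residue_number, a.atom_name,
                           round(a.x, 3), round(a.y, 3), round(a.z, 3))
                          for a in model.atoms)

        assert key(m1) == key(m2)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(DataError):
            read_structure(p)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(DataError):
            read_structure(tmp_path / "nope.pdb")

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30"
            "  0.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.70"
            "  0.00           C\nEND\n")
        model = read_structure(p)
        assert len(model.atoms) == 1
        assert model.atoms[0].x == pytest.approx(9.0)


class TestDuplexAxis:
    def test_axis_of_upright_duplex_points_along_z(self):
        truth = synthetic.gen_helix_scene(0.0, 16, seed=2)
        fit = fit_duplex_axis(truth.scene, "A", "B")
        angle = np.degrees(np.arccos(abs(fit.direction @ [0, 0, 1])))
        assert angle <= 0.5

    def test_short_duplex_rejected(self):
        truth = synthetic.gen_helix_scene(0.0, 16, seed=2)
        with pytest.raises(DataError):
            fit_duplex_axis(truth.scene, "A:1-3", "B:1-3")

    def test_selection_without_atoms_rejected(self):
        truth = synthetic.gen_helix_scene(0.0, 16, seed=2)
        with pytest.raises(DataError):
            fit_duplex_axis(truth.scene, "Z", "B")

    @pytest.mark.parametrize("angle", [0.0, 37.5, 60.0, 90.0])
    def test_scene_round_trip_recovers_angle(self, angle):
        truth = synthetic.gen_helix_scene(angle, 20, seed=7)
        f1 = fit_duplex_axis(truth.scene, "A", "B")
        f2 = fit_duplex_axis(truth.scene, "C", "D")
        assert crossing_angle(f1, f2) == pytest.approx(angle, abs=1.0)

    def test_recovery_within_one_degree_across_seeds(self):
        errs = []
        for seed in range(50):
            truth = synthetic.gen_helix_scene(60.0, 14, seed=seed)
            f1 = fit_duplex_axis(truth.scene, "A", "B")
            f2 = fit_duplex_axis(truth.scene, "C", "D")
            errs.append(abs(crossing_angle(f1, f2) - 60.0))
        assert max(errs) <= 1.0


class TestCrossingAngle:
    @staticmethod
    def _fit(direction, point=(0, 0, 0)):
        return HelixAxisFit(direction=np.asarray(direction, float),
                            point=np.asarray(point, float),
                            n_basepairs_used=10, rms_axial_deviation=0.0)

    def test_parallel_axes(self):
        assert crossing_angle(self._fit([0, 0, 1]), self._fit([0, 0, 1])) == 0.0

    def test_orthogonal_axes(self):
        assert crossing_angle(self._fit([1, 0, 0]),
                              self._fit([0, 1, 0])) == pytest.approx(90.0)

    def test_acute_mode_flip_invariance_and_symmetry(self):
        a, b = self._fit([0.2, 0.3, 0.93]), self._fit([0.7, -0.1, 0.7])
        t = crossing_angle(a, b)
        assert crossing_angle(b, a) == pytest.approx(t)
        assert crossing_angle(self._fit(-a.direction), b) == pytest.approx(t)

    def test_zero_direction_rejected(self):
        with pytest.raises(DataError):
            crossing_angle(self._fit([0, 0, 0]), self._fit([0, 0, 1]))

    def test_signed_mode_magnitude_matches_acute(self):
        a = self._fit([0, 0, 1], point=(0, 0, 0))
        b = self._fit([0, np.sin(0.5), np.cos(0.5)], point=(10, 0, 0))
        assert abs(crossing_angle(a, b, "signed")) == pytest.approx(
            crossing_angle(a, b, "acute"))


class TestVdwDistance:
    def test_touching_carbons_give_zero(self, tmp_path):
        p = tmp_path / "touch.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00"
            "  0.00           C\n"
            "ATOM      2  CA  ALA B   1       3.400   0.000   0.000  1.00"
            "  0.00           C\nEND\n")
        model = read_structure(p)
        dist, _ = min_backbone_vdw_distance(model, "A", "B")
        assert dist == pytest.approx(0.0, abs=1e-6)

    def test_five_atom_fixture_matches_hand_table(self, tmp_path):
        p = tmp_path / "five.pdb"
        p.write_text(FIVE_ATOM_PDB)
        model = read_structure(p)
        dist, (a, b) = min_backbone_vdw_distance(model, "A", "B")
        ga = [x for x in model.atoms if x.chain_id == "A"]
        gb = [x for x in model.atoms if x.chain_id == "B"]
        assert dist == pytest.approx(
            oracles.all_pairs_min_vdw(ga, gb, BONDI.radii), abs=1e-12)
        # hand check: N(1.5,0,0)-C(3,0,1) pair: sqrt(2.25+1)=1.803,
        # gap = 1.803 - 1.55 - 1.70 = -1.447, the global minimum
        assert dist == pytest.approx(np.sqrt(3.25) - 3.25, abs=1e-3)
        assert (a.atom_name, b.atom_name) == ("N", "C")

    def test_matches_all_pairs_oracle_on_scene(self):
        model = synthetic.gen_helix_scene(45.0, 12, seed=3).scene
        dist, _ = min_backbone_vdw_distance(model, "A", "C")
        ga = [x for x in model.atoms
              if x.chain_id == "A" and x.atom_name in {"P"}]
        gb = [x for x in model.atoms
              if x.chain_id == "C" and x.atom_name in {"P"}]
        # nucleic backbone here is P only (pseudo-atoms); C1' is sugar
        expected = oracles.all_pairs_min_vdw(ga, gb, BONDI.radii)
        assert dist == pytest.approx(expected, abs=1e-12)

    def test_empty_backbone_selection_rejected(self, tmp_path):
        p = tmp_path / "five.pdb"
        p.write_text(FIVE_ATOM_PDB)
        model = read_structure(p)
        with pytest.raises(DataError):
            min_backbone_vdw_distance(model, "A", "Q")


class TestRigidMotionInvariance:
    def test_all_measurements_invariant(self):
        rng = np.random.default_rng(123)
        truth = synthetic.gen_helix_scene(60.0, 16, seed=5)
        model = truth.scene
        f1 = fit_duplex_axis(model, "A", "B")
        f2 = fit_duplex_axis(model, "C", "D")
        theta0 = crossing_angle(f1, f2)
        vdw0, _ = min_backbone_vdw_distance(model, "A", "C")
        for _ in range(5):
            moved = rigid_transform(model, rng)
            g1 = fit_duplex_axis(moved, "A", "B")
            g2 = fit_duplex_axis(moved, "C", "D")
            assert crossing_angle(g1, g2) == pytest.approx(theta0, abs=1e-6)
            vdw, _ = min_backbone_vdw_distance(moved, "A", "C")
            assert vdw == pytest.approx(vdw0, abs=1e-6)


class TestSelections:
    def test_parse_chain_and_range(self):
        assert parse_selection("A") == ("A", None, None)
        assert parse_selection("B:5-20") == ("B", 5, 20)

    def test_bad_selection_rejected(self):
        with pytest.raises(DataError):
            parse_selection("A:5-")
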