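"""Per-detector geometric criteria on minimal hand-built systems, plus
full-sweep equivalence with the brute-force oracle."""

import numpy as np
import pytest

from trajfp.config import DetectionConfig
from trajfp.detection import (detect_halogen, detect_hbonds,
                              detect_hydrophobic, detect_metal,
                              detect_pi_cation, detect_pi_stacking,
                              detect_salt_bridges, detect_water_bridges,
                              sweep_trajectory)
from trajfp.perception import perceive

from _oracles import ORACLES, _angle, record_set
from conftest import build_system, randomized_frames

CFG = DetectionConfig()


def _frame(system, det):
    return det(0, system, perceive(system), CFG)


def _leu(tip, resid=1):
    """LEU-like residue whose CD1 sits at ``tip`` (backbone parked 8 Å
    further out along +x)."""
    tip = np.asarray(tip, float)
    out = [("CD1", "C", "A", "LEU", resid, "protein", tip)]
    for i, name in enumerate(("CG", "CB", "CA", "N", "C")):
        out.append((name, "C" if name not in ("N",) else "N", "A", "LEU",
                    resid, "protein", tip + np.array([8 + 1.6 * i, 0, 0])))
    return out


class TestHydrophobic:
    def test_methyl_near_leu_cd1(self):
        system = build_system(
            [("C1", "C", "L", "LIG", 9, "ligand", np.zeros(3))]
            + _leu([3.5, 0, 0]))
        recs = _frame(system, detect_hydrophobic)
        assert len(recs) == 1
        assert recs[0].geometry["dist"] == pytest.approx(3.5)
        assert recs[0].ligand_atom_ids == (0,)

    def test_beyond_cutoff_silent(self):
        system = build_system(
            [("C1", "C", "L", "LIG", 9, "ligand", np.zeros(3))]
            + _leu([4.5, 0, 0]))
        assert _frame(system, detect_hydrophobic) == []

    def test_polar_carbon_excluded(self):
        # ligand C bonded to O is not apolar even at 3.0 Å
        system = build_system(
            [("C1", "C", "L", "LIG", 9, "ligand", np.zeros(3)),
             ("O1", "O", "L", "LIG", 9, "ligand", np.array([-1.3, 0, 0]))]
            + _leu([3.0, 0, 0]))
        assert _frame(system, detect_hydrophobic) == []

    def test_one_record_per_ligand_atom_residue_pair(self):
        # two receptor carbons of one residue in range: keep the closest
        system = build_system(
            [("C1", "C", "L", "LIG", 9, "ligand", np.zeros(3)),
             ("CD1", "C", "A", "LEU", 1, "protein", np.array([3.5, 0, 0])),
             ("CD2", "C", "A", "LEU", 1, "protein", np.array([0, 3.2, 0]))])
        recs = _frame(system, detect_hydrophobic)
        assert len(recs) == 1
        assert recs[0].geometry["dist"] == pytest.approx(3.2)


def _ser_acceptor(pos, resid=2):
    """Carbonyl-style receptor acceptor (backbone O) without hydrogens."""
    pos = np.asarray(pos, float)
    return [("O", "O", "A", "GLY", resid, "protein", pos),
            ("C", "C", "A", "GLY", resid, "protein",
             pos + np.array([0, 1.23, 0])),
            ("CA", "C", "A", "GLY", resid, "protein",
             pos + np.array([1.3, 2.0, 0])),
            ("N", "N", "A", "GLY", resid, "protein",
             pos + np.array([2.7, 1.9, 0]))]


class TestHbonds:
    def _donor_system(self, da_dist, angle_deg):
        """Ligand hydroxyl donating toward a receptor carbonyl O; the
        hydrogen direction sets the D-H...A angle."""
        a = np.radians(180.0 - angle_deg)
        h = np.array([0.96 * np.cos(a), 0.96 * np.sin(a), 0])
        return build_system(
            [("O1", "O", "L", "LIG", 9, "ligand", np.zeros(3)),
             ("HO1", "H", "L", "LIG", 9, "ligand", h),
             ("C1", "C", "L", "LIG", 9, "ligand",
              np.array([-1.4, 0, 0]))]
            + _ser_acceptor([da_dist, 0, 0]))

    def test_good_geometry_is_ligand_donor(self):
        system = self._donor_system(2.9, 170.0)
        recs = _frame(system, detect_hbonds)
        assert [r.itype for r in recs] == ["hbond_donor"]
        # recorded angle equals an explicit independent computation
        x = system.frames[0]
        assert recs[0].geometry["don_angle"] == pytest.approx(
            _angle(x[0], x[1], x[3]), abs=1e-9)
        assert recs[0].geometry["don_angle"] > 160.0

    def test_right_angle_rejected(self):
        assert _frame(self._donor_system(2.9, 90.0), detect_hbonds) == []

    def test_long_distance_rejected(self):
        assert _frame(self._donor_system(5.0, 170.0), detect_hbonds) == []

    def test_receptor_donor_is_ligand_acceptor(self):
        system = build_system(
            [("O2", "O", "L", "LIG", 9, "ligand", np.zeros(3)),
             ("C8", "C", "L", "LIG", 9, "ligand", np.array([0, -1.23, 0])),
             ("ND2", "N", "A", "ASN", 3, "protein", np.array([2.9, 0, 0])),
             ("HD21", "H", "A", "ASN", 3, "protein",
              np.array([1.89, 0, 0])),
             ("CG", "C", "A", "ASN", 3, "protein", np.array([4.2, 0.3, 0])),
             ("CA", "C", "A", "ASN", 3, "protein", np.array([5.6, 0.9, 0])),
             ("N", "N", "A", "ASN", 3, "protein", np.array([6.9, 1.7, 0])),
             ("C", "C", "A", "ASN", 3, "protein", np.array([7.9, 2.8, 0]))])
        recs = _frame(system, detect_hbonds)
        assert [r.itype for r in recs] == ["hbond_acceptor"]
        assert recs[0].ligand_atom_ids == (0,)


class TestWaterBridges:
    def _bridge(self, omega_deg, leg=2.8, second_water=False):
        lig_o = np.zeros(3)
        w_o = lig_o + np.array([leg, 0, 0])
        a = np.radians(180.0 - omega_deg)
        rec_o = w_o + leg * np.array([np.cos(a), np.sin(a), 0])
        specs = [
            ("O1", "O", "L", "LIG", 9, "ligand", lig_o),
            ("C1", "C", "L", "LIG", 9, "ligand", lig_o - [1.4, 0, 0]),
            ("O", "O", "W", "HOH", 50, "water", w_o),
            ("H1", "H", "W", "HOH", 50, "water",
             w_o + 0.96 * (lig_o - w_o) / leg),
            ("H2", "H", "W", "HOH", 50, "water",
             w_o + 0.96 * (rec_o - w_o) / leg),
        ] + _ser_acceptor(rec_o)
        if second_water:
            # second water = first one rotated 90 deg about the
            # ligand-receptor axis, so both legs stay at ``leg`` exactly
            from scipy.spatial.transform import Rotation
            axis = rec_o - lig_o
            axis = axis / np.linalg.norm(axis)
            rot = Rotation.from_rotvec(np.radians(90) * axis)
            w2 = rot.apply(w_o - lig_o) + lig_o
            specs += [
                ("O", "O", "W", "HOH", 51, "water", w2),
                ("H1", "H", "W", "HOH", 51, "water",
                 w2 + 0.96 * (lig_o - w2) / leg),
                ("H2", "H", "W", "HOH", 51, "water",
                 w2 + 0.96 * (rec_o - w2) / np.linalg.norm(rec_o - w2)),
            ]
        return build_system(specs)

    def test_good_bridge_carries_water_identity(self):
        recs = _frame(self._bridge(110.0), detect_water_bridges)
        assert len(recs) == 1
        assert recs[0].water_residue.resid == 50
        assert recs[0].geometry["omega"] == pytest.approx(110.0, abs=1e-6)

    def test_distant_water_silent(self):
        recs = _frame(self._bridge(110.0, leg=6.0), detect_water_bridges)
        assert recs == []

    def test_omega_outside_window_silent(self):
        assert _frame(self._bridge(60.0), detect_water_bridges) == []
        assert _frame(self._bridge(160.0), detect_water_bridges) == []

    def test_two_waters_two_records(self):
        recs = _frame(self._bridge(110.0, second_water=True),
                      detect_water_bridges)
        waters = sorted(r.water_residue.resid for r in recs)
        assert len(recs) >= 2 and 50 in waters and 51 in waters
        # same trajectory-wide key despite different waters
        assert len({r.key() for r in recs}) == 1


def _asp(centroid, resid=5):
    centroid = np.asarray(centroid, float)
    od1 = centroid + np.array([0, 0, 1.1])
    od2 = centroid - np.array([0, 0, 1.1])
    return [("OD1", "O", "A", "ASP", resid, "protein", od1),
            ("OD2", "O", "A", "ASP", resid, "protein", od2),
            ("CG", "C", "A", "ASP", resid, "protein",
             centroid + np.array([0.75, 0, 0])),
            ("CB", "C", "A", "ASP", resid, "protein",
             centroid + np.array([2.3, 0, 0])),
            ("CA", "C", "A", "ASP", resid, "protein",
             centroid + np.array([3.8, 0, 0])),
            ("N", "N", "A", "ASP", resid, "protein",
             centroid + np.array([4.6, 1.2, 0])),
            ("C", "C", "A", "ASP", resid, "protein",
             centroid + np.array([4.9, -1.3, 0]))]


class TestSaltBridges:
    def _system(self, dist):
        return build_system(
            [("N1", "N", "L", "LIG", 9, "ligand", np.zeros(3), 1),
             ("C9", "C", "L", "LIG", 9, "ligand", np.array([-1.5, 0, 0]))]
            + _asp([-dist, 0, 0]))

    def test_ammonium_near_carboxylate(self):
        recs = _frame(self._system(4.0), detect_salt_bridges)
        assert len(recs) == 1
        assert recs[0].geometry["dist"] == pytest.approx(4.0)

    def test_beyond_cutoff_silent(self):
        assert _frame(self._system(6.0), detect_salt_bridges) == []

    def test_like_charges_silent(self):
        # two positive groups: ligand ammonium vs LYS ammonium
        system = build_system(
            [("N1", "N", "L", "LIG", 9, "ligand", np.zeros(3), 1),
             ("NZ", "N", "A", "LYS", 4, "protein", np.array([3.0, 0, 0])),
             ("CE", "C", "A", "LYS", 4, "protein", np.array([4.5, 0, 0]))])
        assert _frame(system, detect_salt_bridges) == []


def _hexagon(center, normal_axis="z", radius=1.39, phase=0.0):
    ang = np.radians(np.arange(6) * 60.0 + phase)
    flat = np.stack([radius * np.cos(ang), radius * np.sin(ang),
                     np.zeros(6)], axis=1)
    if normal_axis == "x":   # ring lying in the yz plane
        flat = flat[:, [2, 0, 1]]
    return flat + np.asarray(center, float)


def _phe(center, normal_axis="z", resid=6, phase=0.0):
    pts = _hexagon(center, normal_axis, phase=phase)
    names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    out = [(n, "C", "A", "PHE", resid, "protein", p)
           for n, p in zip(names, pts)]
    far = np.asarray(center, float) + np.array([0, 0, 9.0])
    out += [("CB", "C", "A", "PHE", resid, "protein", far),
            ("CA", "C", "A", "PHE", resid, "protein", far + [1.5, 0, 0]),
            ("N", "N", "A", "PHE", resid, "protein", far + [2.4, 1.1, 0]),
            ("C", "C", "A", "PHE", resid, "protein", far + [2.9, -1.2, 0])]
    return out


def _lig_ring():
    pts = _hexagon([0, 0, 0])
    return [(f"C{i+1}", "C", "L", "LIG", 9, "ligand", p)
            for i, p in enumerate(pts)]


class TestPiStacking:
    def _system(self, center, axis="z", phase=0.0):
        specs = _lig_ring() + _phe(center, axis, phase=phase)
        return build_system(specs, ligand_rings=[[0, 1, 2, 3, 4, 5]])

    def test_parallel_stack(self):
        recs = _frame(self._system([0, 0, 3.8], phase=30.0),
                      detect_pi_stacking)
        assert len(recs) == 1
        assert recs[0].geometry["style"] == "parallel"
        assert recs[0].geometry["angle"] == pytest.approx(0.0, abs=1e-6)

    def test_t_shaped_stack(self):
        recs = _frame(self._system([0, 0, 5.0], axis="x"),
                      detect_pi_stacking)
        assert len(recs) == 1
        assert recs[0].geometry["style"] == "tshaped"
        assert recs[0].geometry["angle"] == pytest.approx(90.0, abs=1e-6)

    def test_distant_rings_silent(self):
        assert _frame(self._system([0, 0, 7.0]), detect_pi_stacking) == []

    def test_offset_rule(self):
        assert _frame(self._system([3.0, 0, 3.8]), detect_pi_stacking) == []


class TestPiCation:
    def _system(self, nz):
        specs = _lig_ring() + [
            ("NZ", "N", "A", "LYS", 4, "protein", np.asarray(nz, float)),
            ("HZ1", "H", "A", "LYS", 4, "protein",
             np.asarray(nz, float) + [0, 0, 1.0]),
            ("CE", "C", "A", "LYS", 4, "protein",
             np.asarray(nz, float) + [1.48, 0, 0])]
        return build_system(specs, ligand_rings=[[0, 1, 2, 3, 4, 5]])

    def test_cation_above_ring(self):
        recs = _frame(self._system([0, 0, 4.5]), detect_pi_cation)
        assert len(recs) == 1
        assert recs[0].geometry["dist"] == pytest.approx(4.5)

    def test_distant_cation_silent(self):
        assert _frame(self._system([0, 0, 7.0]), detect_pi_cation) == []

    def test_lateral_offset_rule(self):
        assert _frame(self._system([3.0, 0, 4.0]), detect_pi_cation) == []


class TestHalogen:
    def _system(self, dist=3.3, don_angle=170.0, halogen="Cl"):
        c = np.array([-1.75, 0, 0])
        x = np.zeros(3)
        a = np.radians(180.0 - don_angle)
        y = x + dist * np.array([np.cos(a), np.sin(a), 0])
        # carbonyl C neighbour of Y at 120 deg to the halogen
        toward_x = (x - y) / np.linalg.norm(x - y)
        perp = np.cross(toward_x, [0, 0, 1.0])
        m = np.cos(np.radians(120)) * toward_x + \
            np.sin(np.radians(120)) * perp
        specs = [
            ("CL1", halogen, "L", "LIG", 9, "ligand", x),
            ("C2", "C", "L", "LIG", 9, "ligand", c),
            ("O", "O", "A", "GLY", 8, "protein", y),
            ("C", "C", "A", "GLY", 8, "protein", y + 1.23 * m),
            ("CA", "C", "A", "GLY", 8, "protein", y + 1.23 * m
             + np.array([0, 1.5, 0])),
            ("N", "N", "A", "GLY", 8, "protein", y + 1.23 * m
             + np.array([1.2, 2.4, 0]))]
        return build_system(specs)

    def test_textbook_geometry(self):
        recs = _frame(self._system(), detect_halogen)
        assert len(recs) == 1
        assert recs[0].geometry["dist"] == pytest.approx(3.3)
        assert recs[0].geometry["acc_angle"] == pytest.approx(120.0, abs=1e-5)

    def test_perpendicular_donor_angle_silent(self):
        assert _frame(self._system(don_angle=90.0), detect_halogen) == []

    def test_fluorine_never_a_halogen_donor(self):
        assert _frame(self._system(halogen="F"), detect_halogen) == []


class TestMetal:
    def _system(self, dist, target="ligand"):
        specs = [("FE", "Fe", "I", "FE", 20, "ion", np.zeros(3), 2)]
        if target == "ligand":
            specs += [("N2", "N", "L", "LIG", 9, "ligand",
                       np.array([dist, 0, 0])),
                      ("C4", "C", "L", "LIG", 9, "ligand",
                       np.array([dist + 1.35, 0, 0]))]
        else:
            specs += [("C1", "C", "L", "LIG", 9, "ligand",
                       np.array([15.0, 0, 0])),
                      ("O", "O", "W", "HOH", 30, "water",
                       np.array([dist, 0, 0])),
                      ("H1", "H", "W", "HOH", 30, "water",
                       np.array([dist + 0.6, 0.75, 0])),
                      ("H2", "H", "W", "HOH", 30, "water",
                       np.array([dist + 0.6, -0.75, 0]))]
        return build_system(specs)

    def test_triazole_like_nitrogen_coordination(self):
        recs = _frame(self._system(2.2), detect_metal)
        assert len(recs) == 1
        assert recs[0].key() is not None
        assert recs[0].geometry["dist"] == pytest.approx(2.2)

    def test_beyond_cutoff_silent(self):
        assert _frame(self._system(4.0), detect_metal) == []

    def test_water_coordination_flagged_not_keyed(self):
        recs = _frame(self._system(2.1, target="water"), detect_metal)
        assert len(recs) == 1
        assert "water_coordination" in recs[0].flags
        assert recs[0].key() is None
        assert recs[0].water_residue.resid == 30


class TestSweep:
    def test_scheduled_hbond_recovered_exactly(self, toy_system):
        system, truth = toy_system
        table = sweep_trajectory(system)
        key = next(k for k in truth.expected_keys if k.itype == "hbond_donor")
        assert table.frames_of(key) == set(truth.expected_keys[key])

    def test_empty_schedule_gives_empty_table(self, tmp_path):
        from trajfp.fixtures import generate_system
        from trajfp.system import load_system
        from conftest import full_spec
        spec = full_spec(seed=9, schedule=[], waters=[])
        paths, _ = generate_system(spec, tmp_path)
        system = load_system(paths["topology"], paths["trajectory"],
                             paths["ligand_sdf"])
        assert len(sweep_trajectory(system).keyed_records()) == 0

    def test_no_record_pairs_two_same_side_atom_sets(self, toy_system):
        system, _ = toy_system
        lig = set(system.ligand_atom_ids)
        for r in sweep_trajectory(system):
            assert set(r.ligand_atom_ids) <= lig
            for j in r.receptor_atom_ids:
                assert j not in lig

    def test_deterministic_ordering(self, toy_system):
        system, _ = toy_system
        t1 = sweep_trajectory(system).to_dataframe()
        t2 = sweep_trajectory(system).to_dataframe()
        assert t1.equals(t2)


class TestOracleEquivalence:
    """Detector output equals a brute-force all-pairs oracle on randomized
    geometry crossing every threshold region."""

    def _system(self, toy_system, n_random, seed):
        base, _ = toy_system
        frames = randomized_frames(base, n_random, seed)
        from trajfp.system import MolecularSystem
        return MolecularSystem(
            atoms=base.atoms, frames=frames,
            ligand_atom_ids=base.ligand_atom_ids,
            water_residues=base.water_residues,
            special_residues=base.special_residues,
            nucleic_mode=base.nucleic_mode,
            ligand_rings=base.ligand_rings)

    def test_every_detector_matches_oracle(self, toy_system):
        system = self._system(toy_system, 30, seed=11)
        p = perceive(system)
        pairs = [
            ("hydrophobic", detect_hydrophobic),
            ("hbond", detect_hbonds),
            ("water_bridge", detect_water_bridges),
            ("salt_bridge", detect_salt_bridges),
            ("pi_stacking", detect_pi_stacking),
            ("pi_cation", detect_pi_cation),
            ("halogen", detect_halogen),
            ("metal", detect_metal),
        ]
        for f in range(system.n_frames):
            for name, det in pairs:
                got = record_set(det(f, system, p, CFG))
                want = ORACLES[name](f, system, p, CFG)
                assert got == want, f"{name} disagrees at frame {f}"


class TestRigidInvariance:
    def test_sweep_identical_after_global_rigid_motion(self, toy_system):
        from scipy.spatial.transform import Rotation
        from trajfp.system import MolecularSystem
        system, _ = toy_system
        rot = Rotation.from_euler("zyx", [17, -42, 131],
                                  degrees=True).as_matrix()
        trans = np.array([12.0, -7.0, 31.0])
        moved = MolecularSystem(
            atoms=system.atoms,
            frames=system.frames @ rot.T + trans,
            ligand_atom_ids=system.ligand_atom_ids,
            water_residues=system.water_residues,
            special_residues=system.special_residues,
            nucleic_mode=system.nucleic_mode,
            ligand_rings=system.ligand_rings)
        t0 = sweep_trajectory(system)
        t1 = sweep_trajectory(moved)
        assert record_set(t0.records) == record_set(t1.records)
        assert [r.frame for r in t0] == [r.frame for r in t1]


class TestNucleicMode:
    def test_base_ring_stacks_only_in_nucleic_mode(self):
        pts = _hexagon([0, 0, 3.8], phase=30.0)
        names = ("N1", "C2", "N3", "C4", "C5", "C6")
        base = [(n, n[0], "A", "U", 7, "nucleic", p)
                for n, p in zip(names, pts)]
        specs = _lig_ring() + base
        on = build_system(specs, nucleic_mode=True,
                          ligand_rings=[[0, 1, 2, 3, 4, 5]])
        off = build_system(specs, nucleic_mode=False,
                           ligand_rings=[[0, 1, 2, 3, 4, 5]])
        assert len(_frame(on, detect_pi_stacking)) == 1
        assert _frame(off, detect_pi_stacking) == []
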