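import numpy as np
import pytest

from conftest import atom, hexagon, make_pose, make_receptor, rec_atom
from empiriscore.interactions import (
    FingerprintConfig,
    detect_hbonds,
    detect_hydrophobic,
    detect_pi_pi,
    detect_salt_bridges,
    filter_poses_by_salt_bridge,
    fingerprint,
)
from empiriscore.structio import MoleculePose, ReceptorModel, assign_atom_types


class TestSaltBridges:
    def test_detects_at_contact_distance(self, glu_receptor, salt_bridge_pose):
        events = detect_salt_bridges(salt_bridge_pose, glu_receptor)
        assert len(events) == 1
        ev = events[0]
        assert (ev.residue_name, ev.residue_number) == ("GLU", 172)
        assert ev.distance == pytest.approx(3.2, abs=1e-9)

    def test_rejects_beyond_cutoff(self, glu_receptor):
        n = atom("N", (1.2 + 8.0, 0, 0), formal_charge=1)
        pose = make_pose([n])
        assert detect_salt_bridges(pose, glu_receptor) == []

    def test_neutral_amine_rejected(self, glu_receptor):
        n = atom("N", (1.2 + 3.2, 0, 0), formal_charge=0)
        pose = make_pose([n])
        assert detect_salt_bridges(pose, glu_receptor) == []

    def test_closest_oxygen_reported(self, glu_receptor, salt_bridge_pose):
        ev = detect_salt_bridges(salt_bridge_pose, glu_receptor)[0]
        oe1 = next(a for a in glu_receptor.atoms if a.atom_name == "OE1")
        d = np.linalg.norm(salt_bridge_pose.atoms[0].position - oe1.position)
        assert ev.distance == pytest.approx(float(d))


class TestHbonds:
    def test_hydroxyl_to_backbone_oxygen(self):
        rec = make_receptor([rec_atom(1, "O", (0, 0, 0), "ALA", 5, "O")])
        o = atom("O", (3.0, 0, 0), serial=1)
        h = atom("H", (2.1, 0, 0), serial=2)
        pose = make_pose([o, h], bonds=[(0, 1, 1)])
        events = detect_hbonds(pose, rec)
        assert len(events) == 1
        assert events[0].kind == "hbond"
        assert events[0].distance == pytest.approx(2.1, abs=1e-9)
        assert events[0].geometry["distance_type"] == "H-acceptor"

    def test_out_of_range_heavy_pair(self):
        rec = make_receptor([rec_atom(1, "O", (0, 0, 0), "ALA", 5, "O")])
        o = atom("O", (5.0, 0, 0), serial=1)
        h = atom("H", (4.1, 0, 0), serial=2)
        pose = make_pose([o, h], bonds=[(0, 1, 1)])
        assert detect_hbonds(pose, rec) == []

    def test_aromatic_ch_donor(self, glu_receptor):
        oe1 = next(a for a in glu_receptor.atoms if a.atom_name == "OE1")
        c = atom("C", oe1.position + np.array([3.3, 0, 0]), serial=1, aromatic=True)
        h = atom("H", oe1.position + np.array([2.3, 0, 0]), serial=2)
        pose = make_pose([c, h], bonds=[(0, 1, 1)])
        events = [e for e in detect_hbonds(pose, glu_receptor) if e.kind == "ch_hbond"]
        assert len(events) >= 1
        assert events[0].distance == pytest.approx(2.3, abs=1e-9)

    def test_ch_disabled(self, glu_receptor):
        oe1 = next(a for a in glu_receptor.atoms if a.atom_name == "OE1")
        c = atom("C", oe1.position + np.array([3.3, 0, 0]), serial=1, aromatic=True)
        h = atom("H", oe1.position + np.array([2.3, 0, 0]), serial=2)
        pose = make_pose([c, h], bonds=[(0, 1, 1)])
        events = detect_hbonds(pose, glu_receptor, ch_enabled=False)
        assert all(e.kind != "ch_hbond" for e in events)


def _benzene_pose(center, normal_axis=2):
    pts = hexagon(center, normal_axis=normal_axis)
    atoms = [atom("C", p, serial=i + 1, aromatic=True) for i, p in enumerate(pts)]
    bonds = [(i, (i + 1) % 6, 1) for i in range(6)]
    return make_pose(atoms, bonds=bonds)


def _phe_receptor(center, normal_axis=2):
    names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    pts = hexagon(center, normal_axis=normal_axis)
    return make_receptor(
        [rec_atom(i + 1, "C", p, "PHE", 133, n) for i, (p, n) in enumerate(zip(pts, names))]
    )


class TestPiPi:
    def test_parallel_stack(self):
        pose = _benzene_pose((0, 0, 3.8))
        rec = _phe_receptor((0, 0, 0))
        events = detect_pi_pi(pose, rec)
        assert len(events) == 1
        assert events[0].geometry["orientation"] == "parallel"
        assert events[0].distance == pytest.approx(3.8, abs=1e-9)

    def test_far_rings_rejected(self):
        pose = _benzene_pose((0, 0, 9.0))
        rec = _phe_receptor((0, 0, 0))
        assert detect_pi_pi(pose, rec) == []

    def test_perpendicular_t_shaped(self):
        pose = _benzene_pose((0, 0, 5.0), normal_axis=0)
        rec = _phe_receptor((0, 0, 0), normal_axis=2)
        events = detect_pi_pi(pose, rec)
        assert len(events) == 1
        assert events[0].geometry["orientation"] == "t_shaped"


class TestHydrophobic:
    def test_leucine_contact(self):
        rec = make_receptor([rec_atom(1, "C", (0, 0, 0), "LEU", 20, "CD1")])
        pose = make_pose([atom("C", (4.0, 0, 0))])
        events = detect_hydrophobic(pose, rec)
        assert len(events) == 1
        assert events[0].distance == pytest.approx(4.0)

    def test_polar_contact_ignored(self):
        rec = make_receptor([rec_atom(1, "O", (0, 0, 0), "SER", 20, "OG")])
        pose = make_pose([atom("C", (4.0, 0, 0))])
        assert detect_hydrophobic(pose, rec) == []

    def test_residue_deduplication(self):
        rec = make_receptor(
            [
                rec_atom(1, "C", (0, 0, 0), "LEU", 20, "CD1"),
                rec_atom(2, "C", (1.5, 0, 0), "LEU", 20, "CD2"),
            ]
        )
        pose = make_pose([atom("C", (4.0, 0, 0))])
        assert len(detect_hydrophobic(pose, rec)) == 1


class TestFingerprint:
    def test_distant_ligand_empty(self, glu_receptor):
        pose = make_pose([atom("C", (30.0, 0, 0))])
        fp = fingerprint(pose, glu_receptor)
        assert fp.events == []
        assert all(v == 0 for v in fp.counts.values())

    def test_composed_counts(self, glu_receptor, salt_bridge_pose):
        fp = fingerprint(salt_bridge_pose, glu_receptor)
        assert fp.counts["salt_bridge"] == 1

    def test_detector_toggle(self):
        pose = _benzene_pose((0, 0, 3.8))
        rec = _phe_receptor((0, 0, 0))
        cfg = FingerprintConfig(enabled=("salt_bridge", "hbond"))
        fp = fingerprint(pose, rec, cfg)
        assert fp.counts["pi_pi"] == 0

    def test_superset_of_detectors(self, glu_receptor, salt_bridge_pose):
        fp = fingerprint(salt_bridge_pose, glu_receptor)
        solo = detect_salt_bridges(salt_bridge_pose, glu_receptor)
        fp_sb = [e for e in fp.events if e.kind == "salt_bridge"]
        assert len(fp_sb) == len(solo)


class TestFilterPoses:
    def test_subset_in_order(self, glu_receptor):
        def pose_at(d):
            return make_pose([atom("N", (1.2 + d, 0, 0), formal_charge=1)])

        poses = [pose_at(3.0), pose_at(9.0), pose_at(3.5), pose_at(12.0), pose_at(2.8)]
        kept = filter_poses_by_salt_bridge(poses, glu_receptor, residue_number=172)
        assert kept == [poses[0], poses[2], poses[4]]

    def test_all_and_none(self, glu_receptor):
        near = make_pose([atom("N", (1.2 + 3.0, 0, 0), formal_charge=1)])
        far = make_pose([atom("N", (1.2 + 9.0, 0, 0), formal_charge=1)])
        assert filter_poses_by_salt_bridge([near, near], glu_receptor, 172) == [near, near]
        assert filter_poses_by_salt_bridge([far], glu_receptor, 172) == []

    def test_unknown_residue_rejected(self, glu_receptor, salt_bridge_pose):
        with pytest.raises(KeyError):
            filter_poses_by_salt_bridge([salt_bridge_pose], glu_receptor, 999)


def _rigid_transform(seed=0):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(A)
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.uniform(-20, 20, 3)
    return q, t


def _transform_pose(pose, R, t):
    atoms = []
    for a in pose.atoms:
        import copy

        b = copy.deepcopy(a)
        b.position = R @ a.position + t
        atoms.append(b)
    out = MoleculePose(pose.compound_id, atoms, list(pose.bonds), pose.n_rotatable)
    return out


def _transform_receptor(rec, R, t):
    import copy

    atoms = []
    for a in rec.atoms:
        b = copy.deepcopy(a)
        b.position = R @ a.position + t
        atoms.append(b)
    return ReceptorModel(atoms)


@pytest.mark.parametrize("seed", [0, 1])
def test_detectors_rigid_motion_invariant(glu_receptor, salt_bridge_pose, seed):
    R, t = _rigid_transform(seed)
    pose2 = _transform_pose(salt_bridge_pose, R, t)
    rec2 = _transform_receptor(glu_receptor, R, t)
    before = fingerprint(salt_bridge_pose, glu_receptor)
    after = fingerprint(pose2, rec2)
    assert [e.kind for e in after.events] == [e.kind for e in before.events]
    for e1, e2 in zip(before.events, after.events):
        assert e2.distance == pytest.approx(e1.distance, abs=1e-9)


@pytest.mark.parametrize("seed", [2, 3])
def test_pi_pi_rigid_motion_invariant(seed):
    pose = _benzene_pose((0.3, -0.2, 3.8))
    rec = _phe_receptor((0, 0, 0))
    R, t = _rigid_transform(seed)
    ev1 = detect_pi_pi(pose, rec)
    ev2 = detect_pi_pi(_transform_pose(pose, R, t), _transform_receptor(rec, R, t))
    assert len(ev1) == len(ev2) == 1
    assert ev2[0].distance == pytest.approx(ev1[0].distance, abs=1e-9)
    assert ev2[0].geometry["orientation"] == ev1[0].geometry["orientation"]
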