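import math
import warnings

import numpy as np
import pytest

import oracles
from conftest import atom, make_pose, make_receptor, rec_atom
from empiriscore import fixtures as fx
from empiriscore.scoring import (
    SaltBridgeReward,
    ScoringProfile,
    TermSpec,
    default_profile,
    evaluate_terms,
    score_pose,
    surface_distance,
    term_value,
    torsion_divisor,
)


def _pair(r, left=("C", {}), right=("C", {})):
    """Two typed atoms separated by r along x."""
    a = atom(left[0], (0, 0, 0), serial=1, **left[1])
    b = atom(right[0], (r, 0, 0), serial=2, **right[1])
    pa = make_pose([a])
    pb = make_pose([b])
    return pa.atoms[0], pb.atoms[0]


class TestSurfaceDistance:
    @pytest.mark.parametrize("r,expected", [(4.0, 0.0), (3.0, -1.0), (6.5, 2.5)])
    def test_two_carbons(self, r, expected):
        a, b = _pair(r)  # carbon vdW radius 2.0
        assert surface_distance(a, b) == pytest.approx(expected, abs=1e-12)


class TestTermValue:
    def test_cutoff_zeroes_every_kind(self, profile):
        a, b = _pair(9.0)
        for spec in profile.terms:
            assert term_value(spec, a, b, 9.0) == 0.0

    def test_hydrophobic_midpoint(self):
        spec = TermSpec("hydrophobic", {"g": 0.5, "b": 1.5, "c": 8.0}, 1.0)
        a, b = _pair(5.0)  # d = 1.0: midpoint of the slide
        assert a.is_hydrophobic and b.is_hydrophobic
        assert term_value(spec, a, b, 5.0) == pytest.approx(0.5)

    def test_hbond_midpoint(self):
        spec = TermSpec("non_dir_h_bond", {"g": -0.7, "b": 0.0, "c": 8.0}, 1.0)
        nplus = atom("N", (0, 0, 0), formal_charge=1, serial=1)
        h = atom("H", (0.5, 0.8, 0), serial=2)
        donor = make_pose([nplus, h], bonds=[(0, 1, 1)]).atoms[0]
        acc = make_pose([atom("O", (0, 0, 0))]).atoms[0]
        # d = -0.35 => r = R_N + R_O - 0.35 = 1.75 + 1.6 - 0.35 = 3.0
        assert term_value(spec, donor, acc, 3.0) == pytest.approx(0.5)

    def test_gauss_formula(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec = TermSpec("gauss", {"o": 0.0, "w": 0.0, "c": 8.0}, 1.0)
        assert spec.params["w"] == 0.5  # degenerate zero width normalized
        a, b = _pair(4.5)  # d = 0.5
        assert term_value(spec, a, b, 4.5) == pytest.approx(math.exp(-1.0))

    def test_repulsion_piecewise(self):
        spec = TermSpec("repulsion", {"o": 0.0, "c": 8.0}, 1.0)
        a, b = _pair(3.5)
        assert term_value(spec, a, b, 3.5) == pytest.approx(0.25)  # d = -0.5
        assert term_value(spec, a, b, 4.3) == 0.0  # d = +0.3

    def test_slide_continuous_at_breakpoints(self):
        spec = TermSpec("hydrophobic", {"g": 0.5, "b": 1.5, "c": 8.0}, 1.0)
        a, b = _pair(4.0)
        eps = 1e-9
        for d0 in (0.5, 1.5):
            r0 = d0 + 4.0  # R_i + R_j = 4.0
            lo = term_value(spec, a, b, r0 - eps)
            hi = term_value(spec, a, b, r0 + eps)
            assert abs(lo - hi) < 1e-6

    def test_symmetry_all_kinds(self, profile):
        rng = np.random.default_rng(11)
        elems = ["C", "N", "O", "S"]
        for _ in range(25):
            e1, e2 = rng.choice(elems, 2)
            a, b = _pair(
                float(rng.uniform(1.0, 9.0)),
                (e1, {"formal_charge": int(rng.integers(0, 2))}),
                (e2, {}),
            )
            r = float(rng.uniform(1.0, 9.0))
            for spec in profile.terms:
                assert term_value(spec, a, b, r) == pytest.approx(
                    term_value(spec, b, a, r), abs=1e-14
                )

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            TermSpec("london_dispersion", {}, 1.0)


class TestEvaluateTerms:
    def test_far_ligand_zero_vector(self, profile):
        pose, rec = fx.make_toy_complex(seed=5, min_separation=20.0)
        tv = evaluate_terms(pose, rec, profile)
        assert np.all(tv.values == 0.0)

    def test_single_pair_reduction(self, profile):
        rec = make_receptor([rec_atom(1, "C", (0, 0, 0), "ALA", 1, "CB")])
        pose = make_pose([atom("C", (4.5, 0, 0))])
        tv = evaluate_terms(pose, rec, profile)
        for spec, v in zip(profile.terms, tv.values):
            assert v == pytest.approx(
                oracles.pair_term(spec.kind, spec.params, pose.atoms[0], rec.atoms[0], 4.5),
                abs=1e-12,
            )

    @pytest.mark.parametrize("seed", range(3))
    def test_oracle_equivalence(self, profile, seed):
        pose, rec = fx.make_toy_complex(
            seed=seed, n_ligand_atoms=20, n_receptor_atoms=80, min_separation=2.0
        )
        tv = evaluate_terms(pose, rec, profile)
        expected = oracles.brute_force_term_vector(pose, rec, profile)
        np.testing.assert_allclose(tv.values, expected, atol=1e-10)

    def test_additivity_over_fragments(self, profile):
        pose, rec = fx.make_toy_complex(seed=9, n_ligand_atoms=10, min_separation=2.5)
        half = len(pose.atoms) // 2
        from empiriscore.structio import MoleculePose

        frag1 = MoleculePose("f1", pose.atoms[:half], [], 0)
        frag2 = MoleculePose("f2", pose.atoms[half:], [], 0)
        total = evaluate_terms(pose, rec, profile).values
        parts = (
            evaluate_terms(frag1, rec, profile).values
            + evaluate_terms(frag2, rec, profile).values
        )
        np.testing.assert_allclose(total, parts, atol=1e-10)

    def test_untyped_atoms_rejected(self, profile):
        from empiriscore.structio import MoleculePose, TypedAtom

        pose = MoleculePose("raw", [TypedAtom(1, "C", np.zeros(3))])
        _, rec = fx.make_toy_complex(seed=1)
        with pytest.raises(TypeError):
            evaluate_terms(pose, rec, profile)


class TestScorePose:
    def test_zero_weights_give_zero_dg_and_molar_ki(self):
        pose, rec = fx.make_toy_complex(seed=2, min_separation=2.5)
        prof = default_profile()
        for t in prof.terms:
            t.weight = 0.0
        res = score_pose(pose, rec, prof)
        assert res.delta_g == 0.0
        assert res.ki_nM == pytest.approx(1e9)  # 1 M

    def test_zero_rotatable_no_divisor(self, profile):
        pose, rec = fx.make_toy_complex(seed=3, min_separation=2.5)
        pose.n_rotatable = 0
        res = score_pose(pose, rec, profile)
        tv = evaluate_terms(pose, rec, profile)
        assert res.delta_g == pytest.approx(float(profile.weights @ tv.values), abs=1e-12)

    def test_two_atom_hand_calculation(self):
        rec = make_receptor([rec_atom(1, "C", (0, 0, 0), "ALA", 1, "CB")])
        pose = make_pose([atom("C", (4.5, 0, 0))])
        prof = ScoringProfile(
            terms=[TermSpec("gauss", {"o": 0.0, "w": 0.5, "c": 8.0}, -0.0356)],
            torsion_weight=1.923,
        )
        res = score_pose(pose, rec, prof)
        assert res.delta_g == pytest.approx(-0.0356 * math.exp(-1.0), abs=1e-10)

    def test_torsion_divisor_shrinks_magnitude(self, profile):
        pose, rec = fx.make_toy_complex(seed=4, min_separation=2.5)
        base = None
        mags = []
        for n_rot in (0, 2, 5, 8):
            pose.n_rotatable = n_rot
            res = score_pose(pose, rec, profile)
            mags.append(abs(res.delta_g))
        assert mags == sorted(mags, reverse=True)

    def test_salt_bridge_reward_applied_once(self, glu_receptor, salt_bridge_pose):
        prof = default_profile()
        base = score_pose(salt_bridge_pose, glu_receptor, prof).delta_g
        prof.salt_bridge_reward = SaltBridgeReward(residue_number=172, bonus=-1.0)
        res = score_pose(salt_bridge_pose, glu_receptor, prof)
        assert res.salt_bridge_applied
        assert res.delta_g == pytest.approx(base - 1.0, abs=1e-12)


class TestDefaultProfile:
    def test_published_coefficients(self, profile):
        assert [t.weight for t in profile.terms] == [
            -0.035579, -0.005156, 0.840245, -0.035069, -0.587439,
            0.0003, -1.5, -2.0, 0.01148,
        ]
        assert len(profile.terms) == 9
        assert profile.torsion_weight == 1.923
        assert profile.temperature_K == 298.0
        assert profile.salt_bridge_reward is None

    def test_profile_json_roundtrip(self, profile):
        prof2 = ScoringProfile.from_json(profile.to_json())
        assert [t.kind for t in prof2.terms] == [t.kind for t in profile.terms]
        assert prof2.terms[0].params["w"] == 0.5
        np.testing.assert_allclose(prof2.weights, profile.weights)


def test_torsion_divisor_value():
    assert torsion_divisor(1.923, 5) == pytest.approx(1 + 1.923)
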