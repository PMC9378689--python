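"""Superposition, rotation extraction, and swivel-angle measurement."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import putec
from putec.rigid_geometry import (
    GeometryError,
    RigidTransform,
    fit_line_axis,
    kabsch_superpose,
    rotation_angle,
    rotation_axis,
)
from putec.structure_io import SelectionExpr

RNG = np.random.default_rng(42)


def _rot(deg, axis):
    return Rotation.from_rotvec(np.radians(deg) * np.asarray(axis, float)
                                / np.linalg.norm(axis)).as_matrix()


class TestKabsch:
    def test_identity_case(self):
        pts = RNG.normal(size=(4, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.transform.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(res.transform.translation, 0.0, atol=1e-10)

    def test_constructed_transform_recovered(self):
        pts = RNG.normal(size=(20, 3)) * 10
        r = _rot(30, [0, 0, 1])
        t = np.array([1.0, 2.0, 3.0])
        moved = pts @ r.T + t
        res = kabsch_superpose(pts, moved)
        assert res.rmsd < 1e-9
        assert np.allclose(res.transform.apply(pts), moved, atol=1e-9)

    def test_against_biotite_superimpose(self):
        """Independent cross-check of the fit against biotite's Kabsch."""
        import biotite.structure as bst
        pts = RNG.normal(size=(30, 3)) * 8
        moved = pts @ _rot(25, [1, 2, 3]).T + np.array([4.0, -2.0, 1.0]) \
            + RNG.normal(0, 0.2, size=pts.shape)
        _, transform = bst.superimpose(pts, moved)
        ours = kabsch_superpose(moved, pts)
        theirs = transform.apply(moved) if hasattr(transform, "apply") else None
        fitted = ours.transform.apply(moved)
        if theirs is not None:
            assert np.allclose(fitted, theirs, atol=1e-6)
        rmsd_direct = float(np.sqrt(np.mean(np.sum((fitted - pts) ** 2, axis=1))))
        assert ours.rmsd == pytest.approx(rmsd_direct, abs=1e-9)

    def test_rmsd_invariant_under_joint_rigid_motion(self):
        a = RNG.normal(size=(15, 3)) * 5
        b = a + RNG.normal(0, 0.3, size=a.shape)
        base = kabsch_superpose(a, b).rmsd
        r = _rot(77, [1, 1, 0])
        t = np.array([5.0, -3.0, 2.0])
        moved = kabsch_superpose(a @ r.T + t, b @ r.T + t).rmsd
        assert moved == pytest.approx(base, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(GeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(GeometryError):
            kabsch_superpose(line, line)

    def test_identity_pairing_mismatch_reported(self, toy_protein_model):
        atoms = putec.select_atoms(toy_protein_model, SelectionExpr(chain_id="A"))
        with pytest.raises(GeometryError, match="identity pairing"):
            kabsch_superpose(atoms[:10], atoms[5:], pairing="by_identity")


class TestRotationExtraction:
    def test_identity_and_half_turn(self):
        assert rotation_angle(np.eye(3)) == pytest.approx(0.0)
        assert rotation_angle(_rot(180, [0, 1, 0])) == pytest.approx(180.0)

    def test_composition_matches_quaternion_oracle(self):
        r = _rot(10, [1, 0, 0]) @ _rot(20, [0, 1, 0])
        q = (Rotation.from_matrix(_rot(10, [1, 0, 0]))
             * Rotation.from_matrix(_rot(20, [0, 1, 0])))
        expected = math.degrees(np.linalg.norm(q.as_rotvec()))
        assert rotation_angle(r) == pytest.approx(expected, abs=1e-9)

    def test_axis_and_sign_convention(self):
        axis, ang = rotation_axis(_rot(2.5, [0, 0, 1]))
        assert ang == pytest.approx(2.5, abs=1e-9)
        assert np.allclose(axis, [0, 0, 1], atol=1e-9)
        axis2, ang2 = rotation_axis(_rot(2.5, [0, 0, 1]),
                                    reference_direction=[0, 0, -1])
        assert ang2 == pytest.approx(2.5, abs=1e-9)
        assert np.allclose(axis2, [0, 0, -1], atol=1e-9)

    def test_axis_angle_round_trip_sweep(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            ax = rng.normal(size=3)
            ax /= np.linalg.norm(ax)
            ang = rng.uniform(0.01, 179.9)
            r = _rot(ang, ax)
            got_ax, got_ang = rotation_axis(r)
            assert got_ang == pytest.approx(ang, abs=1e-9)
            assert np.allclose(got_ax, ax, atol=1e-8) or np.allclose(got_ax, -ax, atol=1e-8)

    def test_non_rotation_rejected(self):
        with pytest.raises(GeometryError):
            rotation_angle(np.diag([1.0, 1.0, -1.0]))
        with pytest.raises(GeometryError):
            rotation_axis(np.eye(3))  # angle ~ 0: axis undefined

    def test_rigid_transform_invariants(self):
        with pytest.raises(GeometryError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestSwivelAngle:
    def test_self_comparison_is_zero(self, swivel_fixture):
        rep = putec.swivel_angle(swivel_fixture.reference, swivel_fixture.reference,
                                 swivel_fixture.domain_set)
        assert rep.angle_deg == pytest.approx(0.0, abs=1e-9)
        assert all(v == pytest.approx(0.0, abs=1e-12)
                   for v in rep.per_domain_rmsd.values())

    def test_noiseless_recovery_and_axis(self, swivel_fixture):
        rep = putec.swivel_angle(swivel_fixture.reference, swivel_fixture.target,
                                 swivel_fixture.domain_set)
        assert rep.angle_deg == pytest.approx(swivel_fixture.true_angle, abs=1e-6)
        assert rep.bridge_helix_axis_angle == pytest.approx(0.0, abs=1e-6)
        assert rep.n_core_atoms >= 50 and rep.n_swivel_atoms >= 50

    def test_direction_symmetry(self):
        fx = putec.make_two_module_model(angle=3.0, noise_sigma=0.0, seed=5)
        fwd = putec.swivel_angle(fx.reference, fx.target, fx.domain_set)
        rev = putec.swivel_angle(fx.target, fx.reference, fx.domain_set)
        assert fwd.angle_deg == pytest.approx(rev.angle_deg, abs=1e-6)

    @pytest.mark.parametrize("angle", [0.5, 1.0, 2.0, 3.0, 5.0])
    def test_recovery_under_noise(self, angle):
        """Across applied angles with up to 0.3 A coordinate noise."""
        errs = []
        for sigma in (0.0, 0.1, 0.3):
            fx = putec.make_two_module_model(
                n_core=300, n_swivel=500, angle=angle,
                noise_sigma=sigma, seed=int(angle * 10) + int(sigma * 100))
            rep = putec.swivel_angle(fx.reference, fx.target, fx.domain_set)
            errs.append(abs(rep.angle_deg - angle))
        assert np.mean(errs) < 0.1

    def test_per_domain_rmsd_reflects_motion(self, swivel_fixture):
        rep = putec.swivel_angle(swivel_fixture.reference, swivel_fixture.target,
                                 swivel_fixture.domain_set)
        assert rep.per_domain_rmsd["core"] == pytest.approx(0.0, abs=1e-9)
        for dom in ("clamp", "shelf", "jaw", "si3", "betaprime_cterm"):
            assert rep.per_domain_rmsd[dom] > 0.1


class TestDisplacementAndDistance:
    def test_identical_structures_zero(self, swivel_fixture):
        d = putec.atom_displacement(
            swivel_fixture.reference, swivel_fixture.reference,
            [SelectionExpr(chain_id="C")],
            SelectionExpr(chain_id="S", residue_ranges=((1, 1),),
                          atom_names=frozenset({"CA"})))
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_marked_tip_displacement_recovered(self):
        fx = putec.make_two_module_model(angle=2.5, noise_sigma=0.0, seed=2)
        chain, resnum, _, name = fx.marked_tip
        d = putec.atom_displacement(
            fx.reference, fx.target,
            [SelectionExpr(chain_id="C"), SelectionExpr(chain_id="H")],
            SelectionExpr(chain_id=chain, residue_ranges=((resnum, resnum),),
                          atom_names=frozenset({name})))
        assert d == pytest.approx(fx.marked_tip_displacement, abs=1e-6)

    def test_pairwise_distance_and_symmetry(self, toy_protein_model):
        a = SelectionExpr(chain_id="A", residue_ranges=((1, 1),),
                          atom_names=frozenset({"N"}))
        b = SelectionExpr(chain_id="A", residue_ranges=((2, 2),),
                          atom_names=frozenset({"N"}))
        d1 = putec.pairwise_distance(toy_protein_model, a, b)
        d2 = putec.pairwise_distance(toy_protein_model, b, a)
        assert d1 == pytest.approx(3.8)
        assert d1 == d2

    def test_three_four_five(self):
        from conftest import make_atom
        m = putec.StructureModel("pythagoras", [
            make_atom(1, "MG", "MG", "MG", "A", 1, [0, 0, 0], is_hetero=True),
            make_atom(2, "ZN", "ZN", "ZN", "A", 2, [3, 4, 0], is_hetero=True),
        ])
        d = putec.pairwise_distance(
            m, SelectionExpr(chain_id="A", residue_ranges=((1, 1),)),
            SelectionExpr(chain_id="A", residue_ranges=((2, 2),)))
        assert d == pytest.approx(5.0)

    def test_probe_multiplicity_error(self, toy_protein_model):
        with pytest.raises(putec.structure_io.SelectionError):
            putec.pairwise_distance(
                toy_protein_model,
                SelectionExpr(chain_id="A"),  # many atoms
                SelectionExpr(chain_id="A", residue_ranges=((1, 1),),
                              atom_names=frozenset({"N"})))


class TestAxisFit:
    def test_line_recovered_with_orientation(self):
        t = np.linspace(-10, 10, 25)
        d = np.array([2.0, 1.0, 0.5])
        d /= np.linalg.norm(d)
        pts = np.array([0.0, 1.0, 2.0]) + t[:, None] * d
        axis = fit_line_axis(pts)
        assert np.allclose(axis, d, atol=1e-9)
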