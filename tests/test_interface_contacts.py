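"""Accessible surface area, buried interfaces, polar contacts, base substitution."""

import math

import numpy as np
import pytest

import putec
from putec.interface_contacts import (
    count_pocket_hbonds,
    golden_spiral_points,
    shrake_rupley_sasa,
)
from putec.structure_io import SelectionError, SelectionExpr

from conftest import make_atom


def two_sphere_buried_area(r1, r2, d, probe):
    """Closed-form lens-cap area lost by two intersecting extended spheres."""
    e1, e2 = r1 + probe, r2 + probe
    if d >= e1 + e2:
        return 0.0, 0.0
    # spherical cap heights of the mutual occlusion
    h1 = e1 - (d * d + e1 * e1 - e2 * e2) / (2 * d)
    h2 = e2 - (d * d + e2 * e2 - e1 * e1) / (2 * d)
    return 2 * math.pi * e1 * h1, 2 * math.pi * e2 * h2


class TestSasa:
    def test_isolated_atom_matches_analytic_sphere(self):
        atom = make_atom(1, "C", "C", "LIG", "A", 1, [0, 0, 0])
        res = shrake_rupley_sasa([atom], n_points=960)
        analytic = 4 * math.pi * (1.7 + 1.4) ** 2
        assert res.total == pytest.approx(analytic, rel=0.01)

    def test_fully_buried_atom_has_zero_area(self):
        # a carbon at the centre of a tight dodecahedral shell of carbons
        pts = golden_spiral_points(20) * 2.0
        atoms = [make_atom(1, "C", "C", "LIG", "A", 1, [0, 0, 0])]
        atoms += [make_atom(i + 2, "C", "C", "LIG", "A", i + 2, p)
                  for i, p in enumerate(pts)]
        res = shrake_rupley_sasa(atoms)
        assert res.per_atom_area[atoms[0].atom_key] == 0.0

    def test_agrees_with_brute_force_sampler(self):
        """High-density independent sampler agrees per atom within 2 %."""
        rng = np.random.default_rng(3)
        xyz = rng.uniform(-4, 4, size=(20, 3))
        atoms = [make_atom(i + 1, "C", "C", "LIG", "A", i + 1, p)
                 for i, p in enumerate(xyz)]
        res = shrake_rupley_sasa(atoms, n_points=5000)

        # brute force with an independent (random, not spiral) point set
        n_brute = 100_000
        u = rng.normal(size=(n_brute, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        ext = 1.7 + 1.4
        ref_total = 0.0
        for i in range(len(atoms)):
            pts = xyz[i] + ext * u
            others = np.delete(np.arange(len(atoms)), i)
            d2 = np.min(np.sum((pts[:, None, :] - xyz[others][None, :, :]) ** 2,
                               axis=2), axis=1)
            acc = np.count_nonzero(d2 >= ext * ext) / n_brute
            area = acc * 4 * math.pi * ext ** 2
            got = res.per_atom_area[atoms[i].atom_key]
            assert got == pytest.approx(area, rel=0.02, abs=0.5)
            ref_total += area
        assert res.total == pytest.approx(ref_total, rel=0.02)

    def test_agrees_with_biotite_sasa(self, duplex10):
        """Cross-check the whole-molecule total against biotite's Shrake-Rupley."""
        import biotite.structure as bst
        model = duplex10.model
        n = len(model)
        arr = bst.AtomArray(n)
        arr.coord = np.array([a.position for a in model.atoms], dtype=np.float32)
        arr.set_annotation("chain_id", np.array([a.chain_id for a in model.atoms]))
        arr.set_annotation("res_id", np.array([a.residue_number for a in model.atoms]))
        arr.set_annotation("res_name", np.array([a.residue_name for a in model.atoms]))
        arr.set_annotation("atom_name", np.array([a.name for a in model.atoms]))
        arr.set_annotation("element", np.array([a.element for a in model.atoms]))
        arr.set_annotation("hetero", np.zeros(n, dtype=bool))
        _, radii, _ = putec.interface_contacts.load_radii()
        their = float(np.nansum(bst.sasa(
            arr, probe_radius=1.4, point_number=400,
            vdw_radii=np.array([radii[a.element.upper()] for a in model.atoms]))))
        ours = shrake_rupley_sasa(model, n_points=400).total
        assert ours == pytest.approx(their, rel=0.02)

    def test_point_count_convergence(self):
        rng = np.random.default_rng(5)
        xyz = rng.uniform(-4, 4, size=(20, 3))
        atoms = [make_atom(i + 1, "C", "C", "LIG", "A", i + 1, p)
                 for i, p in enumerate(xyz)]
        t1 = shrake_rupley_sasa(atoms, n_points=960).total
        t2 = shrake_rupley_sasa(atoms, n_points=1920).total
        assert abs(t2 - t1) / t1 < 0.005

    def test_monotone_under_added_neighbour(self):
        a = make_atom(1, "C", "C", "LIG", "A", 1, [0, 0, 0])
        b = make_atom(2, "C", "C", "LIG", "A", 2, [3.0, 0, 0])
        alone = shrake_rupley_sasa([a]).per_atom_area[a.atom_key]
        with_nb = shrake_rupley_sasa([a, b]).per_atom_area[a.atom_key]
        assert with_nb <= alone

    def test_unknown_element_without_default_errors(self):
        a = make_atom(1, "X1", "XX", "LIG", "A", 1, [0, 0, 0])
        with pytest.raises(ValueError, match="XX"):
            shrake_rupley_sasa([a], radii={"C": 1.7})


class TestBuriedSurfaceArea:
    def _two_chain_model(self, d):
        return putec.StructureModel("pair", [
            make_atom(1, "C1", "C", "LIG", "A", 1, [0, 0, 0]),
            make_atom(2, "C1", "C", "LIG", "B", 1, [d, 0, 0]),
        ])

    def test_distant_partners_bury_nothing(self):
        m = self._two_chain_model(10.0)  # > 2 * (1.7 + 1.4)
        rep = putec.buried_surface_area(m, SelectionExpr(chain_id="A"),
                                        SelectionExpr(chain_id="B"))
        assert rep.bsa == 0.0

    @pytest.mark.parametrize("d", [3.0, 4.5, 5.5])
    def test_two_sphere_closed_form(self, d):
        m = self._two_chain_model(d)
        rep = putec.buried_surface_area(m, SelectionExpr(chain_id="A"),
                                        SelectionExpr(chain_id="B"),
                                        n_points=4000)
        cap1, cap2 = two_sphere_buried_area(1.7, 1.7, d, 1.4)
        expected = (cap1 + cap2) / 2.0
        assert rep.bsa == pytest.approx(expected, rel=0.02)

    def test_symmetric_in_partners(self, duplex10):
        a = SelectionExpr(chain_id="R")
        b = SelectionExpr(chain_id="S")
        r1 = putec.buried_surface_area(duplex10.model, a, b, n_points=240)
        r2 = putec.buried_surface_area(duplex10.model, b, a, n_points=240)
        assert r1.bsa == pytest.approx(r2.bsa, abs=1e-9)
        assert r1.bsa > 0

    def test_overlapping_selections_rejected(self, duplex10):
        with pytest.raises(SelectionError):
            putec.buried_surface_area(duplex10.model,
                                      SelectionExpr(chain_id="R"),
                                      SelectionExpr(chain_id="R"))


class TestPolarContacts:
    def test_constructed_hbond(self):
        m = putec.StructureModel("hb", [
            make_atom(1, "N", "N", "GLY", "A", 1, [0, 5, 0]),
            make_atom(2, "OG", "O", "SER", "A", 2, [0, 0, 0]),
            make_atom(3, "CB", "C", "SER", "A", 2, [0, 1.4, 0]),
            make_atom(4, "O", "O", "GLY", "B", 1, [2.9, 0, 0]),
            make_atom(5, "C", "C", "GLY", "B", 1, [3.6, 1.2, 0]),
        ])
        contacts = putec.detect_polar_contacts(
            m, SelectionExpr(chain_id="A"), SelectionExpr(chain_id="B"))
        hbonds = [c for c in contacts if c.kind == "hbond"]
        assert len(hbonds) == 1
        assert hbonds[0].distance == pytest.approx(2.9)

    def test_salt_bridge_priority_over_hbond(self):
        # Arg NH1 donor at 3.2 A from a phosphate O1P: both criteria hold,
        # reported once as a salt bridge
        m = putec.StructureModel("sb", [
            make_atom(1, "NH1", "N", "ARG", "A", 1, [0, 0, 0]),
            make_atom(2, "CZ", "C", "ARG", "A", 1, [-1.3, 0, 0]),
            make_atom(3, "O1P", "O", "G", "B", 1, [3.2, 0, 0]),
            make_atom(4, "P", "P", "G", "B", 1, [4.2, 1.0, 0]),
            make_atom(5, "C1'", "C", "G", "B", 1, [6.0, 3.0, 0]),
        ])
        contacts = putec.detect_polar_contacts(
            m, SelectionExpr(chain_id="A"), SelectionExpr(chain_id="B"))
        kinds = [c.kind for c in contacts]
        assert kinds.count("salt_bridge") == 1
        assert "hbond" not in kinds

    def test_cation_pi_geometry(self):
        # Lys NZ placed 4.5 A along the ring normal of a Phe ring
        ring_r = 1.39
        ring = []
        names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        for i, nm in enumerate(names):
            ang = math.radians(60 * i)
            ring.append(make_atom(i + 1, nm, "C", "PHE", "B", 1,
                                  [ring_r * math.cos(ang), ring_r * math.sin(ang), 0]))
        m = putec.StructureModel("cpi", ring + [
            make_atom(7, "NZ", "N", "LYS", "A", 1, [0, 0, 4.5]),
        ])
        contacts = putec.detect_polar_contacts(
            m, SelectionExpr(chain_id="A"), SelectionExpr(chain_id="B"))
        cpi = [c for c in contacts if c.kind == "cation_pi"]
        assert len(cpi) == 1
        assert cpi[0].distance == pytest.approx(4.5, abs=1e-6)
        assert cpi[0].angle == pytest.approx(0.0, abs=1e-6)

    def test_cation_pi_rejected_off_axis(self):
        ring_r = 1.39
        names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        ring = [make_atom(i + 1, nm, "C", "PHE", "B", 1,
                          [ring_r * math.cos(math.radians(60 * i)),
                           ring_r * math.sin(math.radians(60 * i)), 0])
                for i, nm in enumerate(names)]
        # in-plane approach: angle to normal is 90 degrees
        m = putec.StructureModel("cpi2", ring + [
            make_atom(7, "NZ", "N", "LYS", "A", 1, [5.0, 0, 0]),
        ])
        contacts = putec.detect_polar_contacts(
            m, SelectionExpr(chain_id="A"), SelectionExpr(chain_id="B"))
        assert not [c for c in contacts if c.kind == "cation_pi"]

    def test_rigid_motion_invariance(self, duplex10):
        from scipy.spatial.transform import Rotation
        a = SelectionExpr(chain_id="R")
        b = SelectionExpr(chain_id="S")
        before = putec.detect_polar_contacts(duplex10.model, a, b)
        rot = Rotation.from_rotvec([0.3, -0.7, 1.1]).as_matrix()
        moved = duplex10.model.transformed(rot, np.array([11.0, -4.0, 6.0]))
        after = putec.detect_polar_contacts(moved, a, b)
        assert [(c.kind, c.atom_a, c.atom_b) for c in before] == \
            [(c.kind, c.atom_a, c.atom_b) for c in after]
        for x, y in zip(before, after):
            assert x.distance == pytest.approx(y.distance, abs=1e-9)


class TestMutateBase:
    def test_same_base_substitution_is_identity(self, duplex10):
        model = duplex10.model
        base0 = duplex10.sequence[0]
        mutated = putec.mutate_base(model, ("R", 1), base0)
        orig = {a.name: a.position for a in model.atoms
                if a.chain_id == "R" and a.residue_number == 1}
        new = {a.name: a.position for a in mutated.atoms
               if a.chain_id == "R" and a.residue_number == 1}
        assert set(orig) == set(new)
        rmsd = np.sqrt(np.mean([np.sum((orig[n] - new[n]) ** 2) for n in orig]))
        assert rmsd < 0.05

    def test_backbone_untouched_and_base_renamed(self, duplex10):
        mutated = putec.mutate_base(duplex10.model, ("R", 2), "G")
        for a in mutated.atoms:
            if a.chain_id == "R" and a.residue_number == 2:
                assert a.residue_name == "G"
        orig_sugar = {a.name: a.position for a in duplex10.model.atoms
                      if a.chain_id == "R" and a.residue_number == 2
                      and ("'" in a.name or a.name.startswith(("P", "OP")))}
        new_sugar = {a.name: a.position for a in mutated.atoms
                     if a.chain_id == "R" and a.residue_number == 2
                     and ("'" in a.name or a.name.startswith(("P", "OP")))}
        assert set(orig_sugar) == set(new_sugar)
        for nm in orig_sugar:
            assert np.allclose(orig_sugar[nm], new_sugar[nm])

    def test_non_rna_residue_rejected(self, toy_protein_model):
        with pytest.raises(SelectionError):
            putec.mutate_base(toy_protein_model, ("A", 1), "G")

    def test_substituted_base_hbond_count_in_constructed_pocket(self, duplex10):
        """A pocket built around a G's donor/acceptor sites yields 3 hbonds
        for G and fewer for the pyrimidines, mirroring the logic of scoring
        base substitutions in a protein pocket."""
        model = putec.mutate_base(duplex10.model, ("R", 3), "G")
        res = {a.name: a for a in model.atoms
               if a.chain_id == "R" and a.residue_number == 3}
        ring = [res[nm].position for nm in ("N1", "C2", "N3", "C4", "C5", "C6")]
        ctr = np.mean(ring, axis=0)

        def outward(nm, dist=2.9):
            v = res[nm].position - ctr
            v = v / np.linalg.norm(v)
            return res[nm].position + v * dist

        pocket = [
            # backbone N donating into O6; backbone O accepting from N1, N2
            make_atom(900, "N", "N", "GLY", "Z", 1, outward("O6")),
            make_atom(901, "O", "O", "GLY", "Z", 2, outward("N1")),
            make_atom(902, "O", "O", "GLY", "Z", 3, outward("N2")),
        ]
        pocket_model = putec.StructureModel(
            "pocket", list(model.atoms) + pocket)
        sel_pocket = SelectionExpr(chain_id="Z")
        counts = {}
        for base in ("G", "A", "C", "U"):
            mm = putec.mutate_base(pocket_model, ("R", 3), base)
            counts[base] = count_pocket_hbonds(mm, ("R", 3), sel_pocket)
        assert counts["G"] == 3
        assert counts["C"] < counts["G"]
        assert counts["U"] < counts["G"]
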