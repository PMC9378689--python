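"""Structure reading/writing, altloc resolution, selections, domain configs."""

import textwrap

import numpy as np
import pytest

import putec
from putec.structure_io import (
    DomainConfigError,
    SelectionError,
    SelectionExpr,
    StructureError,
    load_domain_config,
    default_domain_config_path,
)

from conftest import make_atom

MINIMAL_PDB = """\
ATOM      1  N   GLY A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  GLY A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   GLY A   1      12.342   7.364  -4.749  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BGLY A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA AGLY A   2       0.000   2.000   0.000  0.50  0.00           C
ATOM      4  CA BGLY A   2       0.000   3.000   0.000  0.50  0.00           C
HETATM    5 ZN    ZN A 101       5.000   5.000   5.000  1.00  0.00          ZN
END
"""


class TestReadStructure:
    def test_minimal_three_atom_model(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        model = putec.read_structure(p)
        assert len(model) == 3
        assert list(model.chains) == ["A"]
        assert len(model.chains["A"]) == 1
        assert [a.name for a in model.atoms] == ["N", "CA", "C"]

    def test_pdb_and_mmcif_give_identical_models(self, tmp_path, duplex10):
        """The same in-memory model written as PDB and mmCIF reads back the same."""
        pdb = tmp_path / "m.pdb"
        cif = tmp_path / "m.cif"
        putec.write_structure(duplex10.model, pdb, format="pdb")
        putec.write_structure(duplex10.model, cif, format="mmcif")
        m1 = putec.read_structure(pdb)
        m2 = putec.read_structure(cif)
        assert len(m1) == len(m2) == len(duplex10.model)
        a1 = sorted(m1.atoms, key=lambda a: a.atom_key)
        a2 = sorted(m2.atoms, key=lambda a: a.atom_key)
        for x, y in zip(a1, a2):
            assert x.atom_key == y.atom_key
            assert x.residue_name == y.residue_name
            # PDB fixed-width coordinates carry 3 decimals
            assert np.allclose(x.position, y.position, atol=1.5e-3)

    def test_round_trip_preserves_coordinates(self, tmp_path, duplex10):
        for fmt, name in (("pdb", "a.pdb"), ("mmcif", "a.cif")):
            p = tmp_path / name
            putec.write_structure(duplex10.model, p, format=fmt)
            back = putec.read_structure(p)
            orig = {a.atom_key: a for a in duplex10.model.atoms}
            assert set(orig) == {a.atom_key for a in back.atoms}
            for a in back.atoms:
                assert np.allclose(a.position, orig[a.atom_key].position, atol=1e-3)

    def test_altloc_highest_occupancy_kept_tie_first_alpha(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        model = putec.read_structure(p)
        res1 = model.get_atom("A", 1, "CA")
        res2 = model.get_atom("A", 2, "CA")
        assert res1.position[0] == pytest.approx(1.0)  # occupancy 0.6 wins
        assert res2.position[1] == pytest.approx(2.0)  # tie -> altloc A

    def test_altloc_resolution_idempotent(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        m1 = putec.read_structure(p)
        q = tmp_path / "alt2.pdb"
        putec.write_structure(m1, q)
        m2 = putec.read_structure(q)
        assert [a.atom_key for a in m1.atoms] == [a.atom_key for a in m2.atoms]

    def test_metal_ion_flagged(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        model = putec.read_structure(p)
        assert len(model.ions) == 1
        assert model.ions[0].element.upper() == "ZN"

    def test_missing_file_and_garbage_raise(self, tmp_path):
        with pytest.raises(StructureError):
            putec.read_structure(tmp_path / "nope.pdb")
        bad = tmp_path / "bad.cif"
        bad.write_text("this is not a structure file at all\n")
        with pytest.raises(StructureError):
            putec.read_structure(bad, format="mmcif")


class TestSelection:
    def test_chain_range_atom_name(self, toy_protein_model):
        sel = SelectionExpr(chain_id="A", residue_ranges=((1, 3),),
                            atom_names=frozenset({"CA"}))
        atoms = putec.select_atoms(toy_protein_model, sel)
        assert len(atoms) == 3
        assert all(a.name == "CA" for a in atoms)

    def test_overlapping_ranges_set_semantics(self, toy_protein_model):
        sel = SelectionExpr(chain_id="A", residue_ranges=((1, 3), (2, 5)),
                            atom_names=frozenset({"CA"}))
        atoms = putec.select_atoms(toy_protein_model, sel)
        assert [a.residue_number for a in atoms] == [1, 2, 3, 4, 5]

    def test_empty_selection_is_an_error(self, toy_protein_model):
        with pytest.raises(SelectionError):
            putec.select_atoms(toy_protein_model,
                               SelectionExpr(chain_id="Z"))

    def test_selection_monotone_under_range_growth(self, toy_protein_model):
        small = putec.select_atoms(toy_protein_model,
                                   SelectionExpr(chain_id="A", residue_ranges=((2, 3),)))
        large = putec.select_atoms(toy_protein_model,
                                   SelectionExpr(chain_id="A", residue_ranges=((1, 4),)))
        assert {a.atom_key for a in small} <= {a.atom_key for a in large}

    def test_string_parsing(self, toy_protein_model):
        atoms = putec.select_atoms(toy_protein_model, "A:1-3:CA")
        assert len(atoms) == 3
        with pytest.raises(SelectionError):
            SelectionExpr.parse("")

    def test_invalid_range_rejected(self):
        with pytest.raises(SelectionError):
            SelectionExpr(residue_ranges=((5, 2),))

    def test_synthetic_selection_matches_generator_count(self, swivel_fixture):
        """Selecting one swivel block returns exactly the generator's atoms."""
        dom = swivel_fixture.domain_set
        atoms = dom.resolve(swivel_fixture.reference, "clamp")
        expr = dom.domains["clamp"][0]
        lo, hi = expr.residue_ranges[0]
        assert len(atoms) == hi - lo + 1


class TestDomainConfig:
    def test_default_config_has_all_swivel_members(self):
        ds = load_domain_config(default_domain_config_path())
        assert set(ds.swivel_members()) == {"clamp", "shelf", "jaw", "si3",
                                            "betaprime_cterm"}
        assert "core" in ds
        assert "bridge_helix" in ds

    def test_overlapping_swivel_ranges_rejected(self, tmp_path):
        cfg = tmp_path / "bad.toml"
        cfg.write_text(textwrap.dedent("""\
            name = "bad"
            [domain.core]
            C = [[1, 100]]
            [domain.clamp]
            D = [[1, 100]]
            [domain.shelf]
            D = [[90, 200]]
            [domain.jaw]
            D = [[300, 400]]
            [domain.si3]
            D = [[500, 600]]
            [domain.betaprime_cterm]
            D = [[700, 800]]
        """))
        with pytest.raises(DomainConfigError, match="overlap"):
            load_domain_config(cfg)

    def test_missing_mandatory_domain_rejected(self, tmp_path):
        cfg = tmp_path / "missing.toml"
        cfg.write_text("name='x'\n[domain.core]\nC = [[1, 10]]\n")
        with pytest.raises(DomainConfigError, match="missing mandatory"):
            load_domain_config(cfg)

    def test_absent_chain_reported_on_resolve(self, toy_protein_model, tmp_path):
        cfg = tmp_path / "chain.toml"
        cfg.write_text(textwrap.dedent("""\
            name = "chain-test"
            [domain.core]
            Q = [[1, 5]]
            [domain.clamp]
            A = [[1, 1]]
            [domain.shelf]
            A = [[2, 2]]
            [domain.jaw]
            A = [[3, 3]]
            [domain.si3]
            A = [[4, 4]]
            [domain.betaprime_cterm]
            A = [[5, 5]]
        """))
        ds = load_domain_config(cfg)
        with pytest.raises(SelectionError, match="Q"):
            ds.resolve(toy_protein_model, "core")


class TestAtomInvariants:
    def test_nonfinite_position_rejected(self):
        with pytest.raises(ValueError):
            make_atom(1, "CA", "C", "GLY", "A", 1, [np.nan, 0, 0])

    def test_occupancy_bounds(self):
        with pytest.raises(ValueError):
            make_atom(1, "CA", "C", "GLY", "A", 1, [0, 0, 0], occupancy=1.5)

    def test_duplicate_atom_key_rejected(self):
        a = make_atom(1, "CA", "C", "GLY", "A", 1, [0, 0, 0])
        b = make_atom(2, "CA", "C", "GLY", "A", 1, [1, 0, 0])
        with pytest.raises(StructureError):
            putec.StructureModel("dup", [a, b])
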