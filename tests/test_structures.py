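"""Structure reading, cleanup and active-site selection."""

import numpy as np
import pytest

from kemlead import (
    Atom,
    ComplexStructure,
    ResidueUnit,
    SyntheticSpec,
    make_complex,
    read_pdb,
    select_active_site,
    select_major_conformer,
    strip_solvent,
    write_pdb,
)


def _atom(name, x, y, z, element="C", occ=1.0, altloc=""):
    return Atom(element=element, name=name, coords=np.array([x, y, z]), occupancy=occ, altloc=altloc)


def _res(chain, resnum, atoms, resname="ALA", role="protein"):
    return ResidueUnit(chain=chain, resname=resname, resnum=resnum, atoms=atoms, role=role)


MINIMAL_PDB = """ATOM      1  CA  ALA A   1      10.000  10.000  10.000  1.00 10.00           C
HETATM    2  C1  LIG A   2      13.000  10.000  10.000  1.00 10.00           C
"""

ALTLOC_PDB = """ATOM      1  CA AALA A   1      10.000  10.000  10.000  0.60 10.00           C
ATOM      2  CA BALA A   1      11.000  10.000  10.000  0.40 10.00           C
ATOM      3  CB ASER A   2      12.000  10.000  10.000  0.50 10.00           C
ATOM      4  CB BSER A   2      13.000  10.000  10.000  0.50 10.00           C
HETATM    5  O   HOH A   3      20.000  10.000  10.000  1.00 10.00           O
"""


class TestReadPdb:
    def test_minimal_two_records(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(MINIMAL_PDB)
        s = read_pdb(p)
        assert len(s.units) == 2
        assert s.ligand.resname == "LIG"

    def test_water_becomes_solvent(self, tmp_path):
        p = tmp_path / "w.pdb"
        p.write_text(MINIMAL_PDB + "HETATM    3  O   HOH A   3      20.000  10.000  10.000  1.00 10.00           O\n")
        s = read_pdb(p)
        assert [u.role for u in s.units if u.resname == "HOH"] == ["solvent"]

    def test_malformed_record_names_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM      1  CA  ALA A   1      10.000  xx.000  10.000  1.00 10.00           C\n")
        with pytest.raises(ValueError, match=":1:"):
            read_pdb(p)

    def test_empty_structure_errors(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("REMARK nothing here\n")
        with pytest.raises(ValueError):
            read_pdb(p)

    def test_synthetic_roundtrip_coordinates(self, tmp_path):
        sc = make_complex(SyntheticSpec(seed=5, n_residues=3))
        out = tmp_path / "rt.pdb"
        write_pdb(sc.structure, out)
        back = read_pdb(out)
        assert len(back.units) == len(sc.structure.units)
        assert back.ligand_id == sc.structure.ligand_id
        for u in sc.structure.units:
            b = back.unit(u.uid)
            np.testing.assert_allclose(b.coords_array(), u.coords_array(), atol=5e-4)


class TestMajorConformer:
    def test_higher_occupancy_wins(self, tmp_path):
        p = tmp_path / "a.pdb"
        p.write_text(ALTLOC_PDB)
        s = select_major_conformer(read_pdb(p))
        ala = s.unit("A:1")
        assert len(ala.atoms) == 1
        assert ala.atoms[0].coords[0] == pytest.approx(10.0)  # occupancy 0.6 conformer
        assert ala.atoms[0].altloc == ""

    def test_tie_takes_alphabetically_first(self, tmp_path):
        p = tmp_path / "a.pdb"
        p.write_text(ALTLOC_PDB)
        s = select_major_conformer(read_pdb(p))
        ser = s.unit("A:2")
        assert ser.atoms[0].coords[0] == pytest.approx(12.0)  # altloc A of the 0.5/0.5 pair

    def test_identity_without_altlocs_and_idempotent(self):
        s = ComplexStructure(units=[_res("A", 1, [_atom("CA", 0, 0, 0)])])
        once = select_major_conformer(s)
        twice = select_major_conformer(once)
        assert [a.name for a in once.units[0].atoms] == ["CA"]
        np.testing.assert_array_equal(once.units[0].coords_array(), twice.units[0].coords_array())


class TestStripSolvent:
    def _with_solvent(self):
        units = [
            _res("A", 1, [_atom("CA", 0, 0, 0)]),
            _res("A", 2, [_atom("O", 5, 0, 0, element="O")], resname="HOH", role="solvent"),
            _res("A", 3, [_atom("O", 6, 0, 0, element="O")], resname="HOH", role="solvent"),
            _res("A", 4, [_atom("NA", 7, 0, 0, element="Na")], resname="NA", role="ion"),
        ]
        return ComplexStructure(units=units)

    def test_removes_solvent_and_ions(self):
        s = strip_solvent(self._with_solvent())
        assert len(s.units) == 1
        assert s.units[0].role == "protein"

    def test_no_solvent_is_identity(self):
        s = ComplexStructure(units=[_res("A", 1, [_atom("CA", 0, 0, 0)])])
        assert len(strip_solvent(s).units) == 1

    def test_count_drops_by_removed_units(self):
        before = self._with_solvent()
        after = strip_solvent(before)
        assert len(before.units) - len(after.units) == 3


class TestActiveSite:
    def _structure(self):
        lig = _res("L", 1, [_atom("C1", 0, 0, 0)], resname="LIG", role="ligand")
        r1 = _res("A", 1, [_atom("CA", 3, 0, 0)])
        r2 = _res("A", 2, [_atom("CA", 4.9, 0, 0)])
        r3 = _res("A", 3, [_atom("CA", 6, 0, 0)])
        return ComplexStructure(units=[lig, r1, r2, r3], ligand_id="L:1")

    def test_constructed_distances(self):
        site = select_active_site(self._structure(), center="ligand", radius=5.0)
        assert [u.uid for u in site] == ["A:1", "A:2"]

    def test_closed_boundary_includes_exact_radius(self):
        site = select_active_site(self._structure(), center="ligand", radius=4.9)
        assert "A:2" in [u.uid for u in site]

    def test_tiny_radius_empty(self):
        assert select_active_site(self._structure(), center="A:3", radius=0.1) == []

    def test_unknown_center_errors(self):
        with pytest.raises(KeyError):
            select_active_site(self._structure(), center="B:9", radius=5.0)

    def test_ligand_never_in_site(self):
        site = select_active_site(self._structure(), center="A:1", radius=50.0)
        assert all(u.role != "ligand" for u in site)

    @pytest.mark.parametrize("r_small,r_large", [(2.0, 5.0), (4.9, 6.0), (1.0, 100.0)])
    def test_radius_monotonicity(self, r_small, r_large):
        s = self._structure()
        small = {u.uid for u in select_active_site(s, "ligand", r_small)}
        large = {u.uid for u in select_active_site(s, "ligand", r_large)}
        assert small <= large

    def test_strip_then_site_never_returns_solvent(self):
        units = self._structure().units + [
            _res("A", 9, [_atom("O", 1, 0, 0, element="O")], resname="HOH", role="solvent")
        ]
        s = strip_solvent(ComplexStructure(units=units, ligand_id="L:1"))
        site = select_active_site(s, center="ligand", radius=50.0)
        assert all(u.role == "protein" for u in site)
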