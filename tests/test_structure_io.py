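"""Parsing, symmetry operators and coordinate-frame transforms."""

import gemmi
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metalloscan.structure_io import (
    StructureParseError,
    UnitCell,
    frac_to_orth,
    orth_to_frac,
    parse_structure,
    parse_symop_string,
    space_group_from_name,
    write_structure,
)

from conftest import make_atom, make_structure


class TestSymOpParser:
    @pytest.mark.parametrize(
        "text, rotation, translation",
        [
            ("X,Y,Z", np.eye(3), (0, 0, 0)),
            ("-X,-Y,Z+1/2", np.diag([-1, -1, 1]), (0, 0, 0.5)),
            ("Y+1/2,X+1/2,-Z+1/4", [[0, 1, 0], [1, 0, 0], [0, 0, -1]], (0.5, 0.5, 0.25)),
        ],
    )
    def test_hand_evaluated_triplets(self, text, rotation, translation):
        op = parse_symop_string(text)
        assert np.array_equal(op.rot, np.asarray(rotation, dtype=float))
        assert np.allclose(op.trans, translation)

    def test_case_and_whitespace_tolerant(self):
        a = parse_symop_string(" -y , x + 1/2 , z+3/4 ")
        b = parse_symop_string("-Y,X+1/2,Z+3/4")
        assert a == b

    def test_unparseable_token_is_echoed(self):
        with pytest.raises(ValueError, match="Q"):
            parse_symop_string("X,Q,Z")


class TestSpaceGroup:
    def test_p43212_has_eight_ops_closed_under_composition(self):
        sg = space_group_from_name("P 43 21 2")
        assert len(sg.ops) == 8
        mats = [(op.rot, op.trans) for op in sg.ops]

        def canon(rot, trans):
            return (tuple(map(tuple, rot.astype(int))), tuple(np.round(trans % 1, 9)))

        group = {canon(r, t) for r, t in mats}
        for ra, ta in mats:
            for rb, tb in mats:
                r = ra @ rb
                t = ra @ tb + ta
                assert canon(r, t) in group  # closure mod lattice
        assert canon(np.eye(3), np.zeros(3)) in group

    def test_each_op_has_an_inverse_in_the_set(self):
        sg = space_group_from_name("P 43 21 2")

        def canon(rot, trans):
            return (tuple(map(tuple, rot.astype(int))), tuple(np.round(trans % 1, 9)))

        group = {canon(op.rot, op.trans) for op in sg.ops}
        for op in sg.ops:
            rinv = np.linalg.inv(op.rot)
            tinv = -rinv @ op.trans
            assert canon(rinv, tinv) in group

    def test_matches_gemmi_operator_table(self):
        ours = {
            (tuple(map(tuple, op.rot.astype(int))), tuple(np.round(op.trans * 24).astype(int)))
            for op in space_group_from_name("P 43 21 2").ops
        }
        theirs = set()
        for op in gemmi.SpaceGroup("P 43 21 2").operations():
            rot = np.array(op.rot) // 24
            theirs.add((tuple(map(tuple, rot)), tuple(np.array(op.tran) % 24)))
        assert ours == theirs

    def test_unknown_group_lists_supported_names(self):
        with pytest.raises(StructureParseError, match="P 43 21 2"):
            space_group_from_name("I 41 3 2")

    def test_ops_are_isometries(self):
        cell = UnitCell(81.12, 81.12, 37.19)
        rng = np.random.default_rng(7)
        a, b = rng.uniform(0, 30, (2, 3))
        d0 = np.linalg.norm(a - b)
        for op in space_group_from_name("P 43 21 2").ops:
            fa, fb = orth_to_frac(cell, a), orth_to_frac(cell, b)
            da = frac_to_orth(cell, op.apply(fa))
            db = frac_to_orth(cell, op.apply(fb))
            assert np.linalg.norm(da - db) == pytest.approx(d0, abs=1e-9)


class TestTransforms:
    def test_axis_vector_maps_to_unit_fraction(self, p43212_cell):
        frac = orth_to_frac(p43212_cell, [81.12, 0.0, 0.0])
        assert np.allclose(frac, [1.0, 0.0, 0.0], atol=1e-12)
        assert np.allclose(orth_to_frac(p43212_cell, [0, 0, 0]), 0.0)

    def test_orthorhombic_transform_is_componentwise_division(self):
        cell = UnitCell(10.0, 20.0, 40.0)
        assert np.allclose(orth_to_frac(cell, [5.0, 5.0, 5.0]), [0.5, 0.25, 0.125])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=3))
    def test_round_trip_identity(self, xyz):
        cell = UnitCell(81.12, 81.12, 37.19)
        back = frac_to_orth(cell, orth_to_frac(cell, xyz))
        assert np.allclose(back, xyz, rtol=1e-9, atol=1e-9)

    def test_matches_gemmi_fractionalization(self):
        cell = UnitCell(27.0, 31.0, 44.0, 88.0, 97.0, 112.0)
        gcell = gemmi.UnitCell(27.0, 31.0, 44.0, 88.0, 97.0, 112.0)
        rng = np.random.default_rng(3)
        for xyz in rng.uniform(-20, 20, (5, 3)):
            ours = orth_to_frac(cell, xyz)
            theirs = gcell.fractionalize(gemmi.Position(*xyz))
            assert np.allclose(ours, [theirs.x, theirs.y, theirs.z], atol=1e-9)


class TestParser:
    def test_cryst1_and_atoms_round_trip(self, pdb_file):
        atoms = [
            make_atom(1, (10.0, 11.5, 5.25), name="NE2", element="N", res_name="HIS", res_seq=15),
            make_atom(2, (12.0, 11.5, 5.25), name="RE", element="Re", res_name="REI",
                      res_seq=201, occupancy=0.68, b=30.0),
        ]
        path = pdb_file(atoms, cell=UnitCell(81.12, 81.12, 37.19))
        st = parse_structure(path, meta={"wavelength": 0.976, "week_label": 9})
        assert st.cell.a == pytest.approx(81.12)
        assert st.cell.c == pytest.approx(37.19)
        assert len(st.space_group.ops) == 8
        assert len(st.atoms) == 2
        re = [a for a in st.atoms if a.element == "Re"][0]
        assert re.occupancy == pytest.approx(0.68)
        assert np.allclose(re.pos, (12.0, 11.5, 5.25), atol=1e-3)

    def test_write_then_parse_preserves_coordinates(self, pdb_file, tmp_path):
        rng = np.random.default_rng(11)
        atoms = [make_atom(i + 1, rng.uniform(0, 30, 3), name=f"C{i+1}", res_seq=i + 1)
                 for i in range(12)]
        path = pdb_file(atoms)
        st = parse_structure(path)
        assert len(st.atoms) == 12
        again = tmp_path / "again.pdb"
        write_structure(st, again)
        st2 = parse_structure(again)
        assert np.allclose(st.coords(), st2.coords(), atol=1e-3)

    def test_missing_cryst1_names_file(self, tmp_path):
        p = tmp_path / "nocell.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A   1      10.000  10.000  10.000  1.00 20.00           C\n"
        )
        with pytest.raises(StructureParseError, match="nocell.pdb.*CRYST1"):
            parse_structure(p)

    def test_zero_atoms_is_an_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("CRYST1   81.120   81.120   37.190  90.00  90.00  90.00 P 43 21 2   1\nEND\n")
        with pytest.raises(StructureParseError, match="no ATOM"):
            parse_structure(p)

    def test_malformed_atom_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(
            "CRYST1   81.120   81.120   37.190  90.00  90.00  90.00 P 43 21 2   1\n"
            "ATOM      1  CA  ALA A   1      10.000  10.000  10.000  1.00 20.00           C\n"
            "ATOM      2  CB  ALA A   1      xx.xxx  10.000  10.000  1.00 20.00           C\n"
        )
        with pytest.raises(StructureParseError, match="line 3"):
            parse_structure(p)

    def test_tetragonal_group_requires_square_cell(self):
        with pytest.raises(StructureParseError, match="tetragonal"):
            make_structure([make_atom(1, (0, 0, 0))], cell=UnitCell(80.0, 81.0, 37.0))
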