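import numpy as np
import pytest

from metalloscan.structure_io import (
    Atom,
    Structure,
    UnitCell,
    space_group_from_name,
    write_structure,
)


def make_atom(serial, xyz, name="C1", element="C", res_name="LIG", res_seq=1,
              chain="A", occupancy=1.0, b=20.0, altloc=""):
    return Atom(serial, name, element, altloc, res_name, chain, res_seq,
                tuple(np.asarray(xyz, dtype=float)), occupancy, b)


def make_structure(atoms, cell=None, space_group="P 43 21 2", meta=None):
    return Structure(
        cell=cell or UnitCell(81.1, 81.1, 37.2),
        space_group=space_group_from_name(space_group),
        atoms=list(atoms),
        meta=meta or {},
    )


@pytest.fixture
def p43212_cell():
    return UnitCell(81.12, 81.12, 37.19)


@pytest.fixture
def pdb_file(tmp_path):
    """Write a tiny but valid PDB fixture and return its path."""

    def _write(atoms, cell=None, space_group="P 43 21 2", name="fixture.pdb"):
        st = make_structure(atoms, cell=cell, space_group=space_group)
        path = tmp_path / name
        write_structure(st, path)
        return path

    return _write


@pytest.fixture
def random_small_structure():
    """Factory for random few-atom structures used by oracle-equivalence tests."""

    def _make(rng, n_atoms=4, cell=None, space_group="P 43 21 2"):
        cell = cell or UnitCell(20.0, 20.0, 12.0)
        atoms = [
            make_atom(i + 1, rng.uniform([0, 0, 0], [cell.a, cell.b, cell.c]),
                      name=f"C{i+1}", res_seq=i + 1)
            for i in range(n_atoms)
        ]
        return make_structure(atoms, cell=cell, space_group=space_group)

    return _make
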