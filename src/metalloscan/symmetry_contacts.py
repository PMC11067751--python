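"""Symmetry-mate generation and crystal-contact detection.

A crystal contact is an intermolecular contact that exists only because of
crystal packing: an atom of the reference molecule within a cutoff of an
atom of a symmetry-related copy (space-group operator plus lattice
translation). The default 4.0 Angstrom heavy-atom cutoff is the
conventional crystal-contact threshold.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Atom, Structure, frac_to_orth, transform_atoms

__all__ = ["SymMate", "Contact", "symmetry_mates", "crystal_contacts", "brute_force_contacts"]


@dataclass
class SymMate:
    """One symmetry-related copy of the asymmetric unit near the reference."""

    op_index: int
    lattice_shift: tuple
    atoms: list

    @property
    def descriptor(self) -> str:
        s = self.lattice_shift
        return f"op{self.op_index}_{s[0]}{s[1]}{s[2]}"


@dataclass(frozen=True)
class Contact:
    atom_ref: Atom
    atom_sym: Atom
    distance: float
    op_index: int
    lattice_shift: tuple


def _shift_ranges(frac_ref: np.ndarray, frac_op: np.ndarray, cell, radius: float) -> list:
    """Per-axis lattice-shift ranges that can bring the op image near the reference.

    Derived from the fractional bounding boxes of both copies, so screw
    translations that push images past one cell are handled exactly. A
    one-cell margin is added for non-orthogonal cells, where the per-axis
    fractional bound is not tight.
    """
    edges = (cell.a, cell.b, cell.c)
    margin = 0
    if any(abs(ang - 90.0) > 1e-6 for ang in (cell.alpha, cell.beta, cell.gamma)):
        margin = 1
    ranges = []
    for axis in range(3):
        r_frac = radius / edges[axis]
        lo = math.floor(frac_ref[:, axis].min() - frac_op[:, axis].max() - r_frac) - margin
        hi = math.ceil(frac_ref[:, axis].max() - frac_op[:, axis].min() + r_frac) + margin
        ranges.append(range(lo, hi + 1))
    return ranges


def symmetry_mates(structure: Structure, radius: float) -> List[SymMate]:
    """All symmetry copies with at least one atom within ``radius`` of the reference.

    Enumerates every space-group operator over all lattice shifts that can
    bring the image near the reference (at least the 3x3x3 neighbourhood,
    wider when screw translations or a small cell require it); the identity
    with zero shift is excluded. Each qualifying copy is returned exactly
    once.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    ref_xyz = structure.coords()
    tree = cKDTree(ref_xyz)
    frac = structure.frac_coords()
    cell = structure.cell
    mates = []
    for op_index, op in enumerate(structure.space_group.ops):
        frac_op = op.apply(frac)
        for shift in itertools.product(*_shift_ranges(frac, frac_op, cell, radius)):
            if op_index == 0 and shift == (0, 0, 0):
                continue
            xyz = frac_to_orth(cell, frac_op + np.asarray(shift, dtype=float))
            dmin, _ = tree.query(xyz, k=1)
            if float(np.min(dmin)) <= radius:
                mates.append(
                    SymMate(
                        op_index=op_index,
                        lattice_shift=tuple(shift),
                        atoms=transform_atoms(structure.atoms, cell, op, shift),
                    )
                )
    return mates


def _atom_mask(atoms, heavy_only: bool, exclude_water: bool) -> np.ndarray:
    keep = np.ones(len(atoms), dtype=bool)
    for i, a in enumerate(atoms):
        if heavy_only and a.element == "H":
            keep[i] = False
        if exclude_water and a.is_water:
            keep[i] = False
    return keep


def crystal_contacts(
    structure: Structure,
    cutoff: float = 4.0,
    heavy_only: bool = True,
    exclude_water: bool = False,
    mates: Optional[List[SymMate]] = None,
) -> List[Contact]:
    """All reference-to-symmetry-mate atom pairs within ``cutoff``.

    Pairs are reported once each, in canonical order (op index, lattice
    shift, then the two atom serials), so the output is independent of the
    atom ordering of the input file.
    """
    if mates is None:
        mates = symmetry_mates(structure, cutoff)
    ref_atoms = structure.atoms
    ref_keep = _atom_mask(ref_atoms, heavy_only, exclude_water)
    ref_idx = np.flatnonzero(ref_keep)
    if len(ref_idx) == 0:
        return []
    tree = cKDTree(structure.coords()[ref_idx])
    contacts = []
    for mate in mates:
        sym_keep = _atom_mask(mate.atoms, heavy_only, exclude_water)
        sym_idx = np.flatnonzero(sym_keep)
        if len(sym_idx) == 0:
            continue
        sym_xyz = np.array([mate.atoms[i].xyz for i in sym_idx])
        for j_local, neighbours in enumerate(tree.query_ball_point(sym_xyz, cutoff)):
            a_sym = mate.atoms[sym_idx[j_local]]
            for i_local in neighbours:
                a_ref = ref_atoms[ref_idx[i_local]]
                d = float(np.linalg.norm(a_ref.pos - a_sym.pos))
                contacts.append(
                    Contact(a_ref, a_sym, d, mate.op_index, mate.lattice_shift)
                )
    contacts.sort(
        key=lambda c: (c.op_index, c.lattice_shift, c.atom_ref.serial, c.atom_sym.serial)
    )
    return contacts


def brute_force_contacts(
    structure: Structure,
    cutoff: float,
    heavy_only: bool = True,
    exclude_water: bool = False,
    n_shells: int = 1,
) -> List[Contact]:
    """Reference oracle: plain double loop over ops x lattice shifts.

    Kept deliberately naive (no spatial index) so it can validate the
    production path on small fixtures.
    """
    cell = structure.cell
    ref_atoms = [a for a in structure.atoms if _keep(a, heavy_only, exclude_water)]
    contacts = []
    for op_index, op in enumerate(structure.space_group.ops):
        for shift in itertools.product(*[range(-n_shells, n_shells + 1)] * 3):
            if op_index == 0 and shift == (0, 0, 0):
                continue
            sym_atoms = [
                a
                for a in transform_atoms(structure.atoms, cell, op, shift)
                if _keep(a, heavy_only, exclude_water)
            ]
            for a_ref in ref_atoms:
                for a_sym in sym_atoms:
                    d = float(np.linalg.norm(a_ref.pos - a_sym.pos))
                    if d <= cutoff:
                        contacts.append(Contact(a_ref, a_sym, d, op_index, tuple(shift)))
    contacts.sort(
        key=lambda c: (c.op_index, c.lattice_shift, c.atom_ref.serial, c.atom_sym.serial)
    )
    return contacts


def _keep(a: Atom, heavy_only: bool, exclude_water: bool) -> bool:
    if heavy_only and a.element == "H":
        return False
    if exclude_water and a.is_water:
        return False
    return True


def contacts_to_records(contacts: List[Contact]) -> list:
    """Flatten contacts for CSV export."""
    return [
        {
            "ref_chain": c.atom_ref.chain,
            "ref_res": c.atom_ref.res_seq,
            "ref_res_name": c.atom_ref.res_name,
            "ref_atom": c.atom_ref.name,
            "sym_chain": c.atom_sym.chain,
            "sym_res": c.atom_sym.res_seq,
            "sym_res_name": c.atom_sym.res_name,
            "sym_atom": c.atom_sym.name,
            "distance": round(c.distance, 3),
            "op_index": c.op_index,
            "shift": "{} {} {}".format(*c.lattice_shift),
        }
        for c in contacts
    ]
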