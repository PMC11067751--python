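"""Crystal-structure input/output and coordinate-frame transforms.

Structures are read from PDB-format files (CRYST1 cell + space group,
ATOM/HETATM records) into lightweight domain objects. Parsing is delegated
to :mod:`gemmi`; the symmetry-operator tables for the space groups used in
practice (P1 and the tetragonal P43212 of hen egg-white lysozyme) are
bundled as xyz-style triplets and expanded by :func:`parse_symop_string`,
so any other group can be supplied as a list of operator strings.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "UnitCell",
    "SymOp",
    "SpaceGroup",
    "Atom",
    "Structure",
    "parse_structure",
    "parse_symop_string",
    "orth_to_frac",
    "frac_to_orth",
    "write_structure",
    "space_group_from_name",
    "AMINO_ACIDS",
    "WATER_NAMES",
]

AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


class StructureParseError(ValueError):
    """Raised for unreadable or physically inconsistent structure files."""


@dataclass(frozen=True)
class UnitCell:
    """Crystal unit cell: edge lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError(f"cell lengths must be positive: {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angles must lie in (0, 180): {self}")

    @property
    def orth_matrix(self) -> np.ndarray:
        """Fractional -> orthogonal (Angstrom) matrix, PDB convention."""
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        ca, cb, cg, sg = math.cos(al), math.cos(be), math.cos(ga), math.sin(ga)
        v = math.sqrt(1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg)
        if v <= 0:
            raise ValueError(f"degenerate cell (volume <= 0): {self}")
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def frac_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orth_matrix)

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.orth_matrix))


@dataclass(frozen=True)
class SymOp:
    """Space-group operator in the fractional basis: x' = R x + t."""

    rotation: tuple  # 3x3 nested tuple of ints in {-1, 0, 1}
    translation: tuple  # 3-tuple of Fractions in [0, 1)

    def __post_init__(self):
        r = np.asarray(self.rotation)
        if r.shape != (3, 3) or not np.isin(r, (-1, 0, 1)).all():
            raise ValueError(f"rotation entries must be in {{-1,0,1}}: {r}")
        if round(float(np.linalg.det(r))) != 1:
            raise ValueError(f"rotation must be proper (det +1): {r}")
        for t in self.translation:
            if not 0 <= t < 1:
                raise ValueError(f"translation components must lie in [0,1): {self.translation}")

    @property
    def rot(self) -> np.ndarray:
        return np.asarray(self.rotation, dtype=float)

    @property
    def trans(self) -> np.ndarray:
        return np.asarray([float(t) for t in self.translation])

    def apply(self, frac: np.ndarray) -> np.ndarray:
        """Apply to fractional coordinates (single vector or (n,3) array)."""
        frac = np.asarray(frac, dtype=float)
        return frac @ self.rot.T + self.trans

    def is_identity(self) -> bool:
        return np.array_equal(self.rot, np.eye(3)) and not any(self.translation)

    def triplet(self) -> str:
        axes = "XYZ"
        parts = []
        for i in range(3):
            term = ""
            for j in range(3):
                r = self.rotation[i][j]
                if r == 1:
                    term += ("+" if term else "") + axes[j]
                elif r == -1:
                    term += "-" + axes[j]
            t = self.translation[i]
            if t:
                term += f"+{t}"
            parts.append(term)
        return ",".join(parts)


_TOKEN_RE = re.compile(r"([+-]?)(\d+/\d+|\d*\.?\d+|[XYZ])")


def parse_symop_string(text: str) -> SymOp:
    """Parse an xyz-style operator string such as ``-Y,X+1/2,Z+3/4``.

    Case-insensitive and whitespace-tolerant. Translations are reduced
    modulo 1 into [0, 1).
    """
    parts = text.upper().replace(" ", "").split(",")
    if len(parts) != 3:
        raise ValueError(f"operator must have three comma-separated components: {text!r}")
    rotation = []
    translation = []
    for comp in parts:
        row = [0, 0, 0]
        trans = Fraction(0)
        pos = 0
        for m in _TOKEN_RE.finditer(comp):
            if m.start() != pos:
                raise ValueError(f"unparseable token {comp[pos:m.start()]!r} in {text!r}")
            pos = m.end()
            sign = -1 if m.group(1) == "-" else 1
            tok = m.group(2)
            if tok in "XYZ":
                row["XYZ".index(tok)] += sign
            elif "/" in tok:
                num, den = tok.split("/")
                trans += sign * Fraction(int(num), int(den))
            else:
                trans += sign * Fraction(tok)
        if pos != len(comp):
            raise ValueError(f"unparseable token {comp[pos:]!r} in {text!r}")
        rotation.append(tuple(row))
        translation.append(trans % 1)
    return SymOp(tuple(rotation), tuple(translation))


# Operator triplets per Hermann-Mauguin name (International Tables settings).
_BUNDLED_GROUPS = {
    "P 1": ["X,Y,Z"],
    "P 43 21 2": [
        "X,Y,Z",
        "-X,-Y,Z+1/2",
        "-Y+1/2,X+1/2,Z+3/4",
        "Y+1/2,-X+1/2,Z+1/4",
        "-X+1/2,Y+1/2,-Z+3/4",
        "X+1/2,-Y+1/2,-Z+1/4",
        "Y,X,-Z",
        "-Y,-X,-Z+1/2",
    ],
}


@dataclass(frozen=True)
class SpaceGroup:
    hermann_mauguin_name: str
    ops: tuple  # tuple of SymOp, identity first

    def __post_init__(self):
        if not any(op.is_identity() for op in self.ops):
            raise ValueError(f"space group {self.hermann_mauguin_name!r} lacks the identity op")

    def __len__(self) -> int:
        return len(self.ops)


def _normalize_hm(name: str) -> str:
    return " ".join(name.strip().split()).upper()


def space_group_from_name(name: str, extra_ops: Optional[Sequence[str]] = None) -> SpaceGroup:
    """Build a :class:`SpaceGroup` from a Hermann-Mauguin name.

    ``extra_ops`` (xyz triplets) overrides the lookup, so arbitrary groups
    can be supplied in configuration.
    """
    if extra_ops is not None:
        return SpaceGroup(name, tuple(parse_symop_string(s) for s in extra_ops))
    norm = _normalize_hm(name)
    for hm, triplets in _BUNDLED_GROUPS.items():
        if _normalize_hm(hm) == norm:
            return SpaceGroup(hm, tuple(parse_symop_string(s) for s in triplets))
    raise StructureParseError(
        f"unknown space group {name!r}; bundled groups: {sorted(_BUNDLED_GROUPS)} "
        "(supply operator triplets explicitly for other groups)"
    )


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    altloc: str
    res_name: str
    chain: str
    res_seq: int
    xyz: tuple  # orthogonal Angstrom frame
    occupancy: float
    b_factor: float

    def __post_init__(self):
        if not self.element:
            raise ValueError(f"atom {self.serial} ({self.name}) has empty element symbol")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(
                f"atom {self.serial} ({self.name}) occupancy {self.occupancy} outside [0,1]"
            )

    @property
    def pos(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)

    @property
    def residue_key(self) -> tuple:
        return (self.chain, self.res_seq, self.res_name)

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    @property
    def is_amino_acid(self) -> bool:
        return self.res_name in AMINO_ACIDS


@dataclass
class Structure:
    cell: UnitCell
    space_group: SpaceGroup
    atoms: list
    meta: dict = field(default_factory=dict)
    stats: Optional[object] = None  # RefinementStats, attached by the precision layer

    def __post_init__(self):
        if not self.atoms:
            raise StructureParseError("structure contains no atoms")
        wl = self.meta.get("wavelength")
        if wl is not None and wl <= 0:
            raise ValueError(f"meta.wavelength must be positive, got {wl}")
        if self.space_group.hermann_mauguin_name.upper().startswith("P 4"):
            if not math.isclose(self.cell.a, self.cell.b, rel_tol=1e-6) or any(
                not math.isclose(ang, 90.0, abs_tol=1e-6)
                for ang in (self.cell.alpha, self.cell.beta, self.cell.gamma)
            ):
                raise StructureParseError(
                    f"tetragonal space group requires a == b and 90-degree angles: {self.cell}"
                )

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def frac_coords(self) -> np.ndarray:
        return orth_to_frac(self.cell, self.coords())

    def atoms_of_residue(self, key: tuple) -> list:
        return [a for a in self.atoms if a.residue_key == key]


def orth_to_frac(cell: UnitCell, xyz) -> np.ndarray:
    """Orthogonal Angstrom coordinates -> fractional (vector or (n,3))."""
    return np.asarray(xyz, dtype=float) @ cell.frac_matrix.T


def frac_to_orth(cell: UnitCell, frac) -> np.ndarray:
    """Fractional coordinates -> orthogonal Angstrom (vector or (n,3))."""
    return np.asarray(frac, dtype=float) @ cell.orth_matrix.T


def _prescan_pdb(path: Path) -> None:
    """Cheap sanity pass giving line-number diagnostics for malformed records."""
    has_cryst1 = False
    n_atoms = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "CRYST1":
                has_cryst1 = True
            elif rec in ("ATOM", "HETATM"):
                n_atoms += 1
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                    float(line[54:60])
                    float(line[60:66])
                except (ValueError, IndexError):
                    raise StructureParseError(
                        f"{path}: malformed {rec} record at line {lineno}: {line.rstrip()!r}"
                    ) from None
    if not has_cryst1:
        raise StructureParseError(f"{path}: missing CRYST1 record")
    if n_atoms == 0:
        raise StructureParseError(f"{path}: no ATOM/HETATM records")


def parse_structure(
    path,
    meta: Optional[dict] = None,
    space_group_ops: Optional[Sequence[str]] = None,
) -> Structure:
    """Parse a PDB-format file into a :class:`Structure`.

    Only the first model is read; all altlocs, waters and ligands are kept.
    Coordinates stay in the file's orthogonal Angstrom frame.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_pdb(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    cell = UnitCell(st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma)
    sg = space_group_from_name(st.spacegroup_hm or "P 1", extra_ops=space_group_ops)
    atoms = []
    model = st[0]
    for chain in model:
        for res in chain:
            for at in res:
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name,
                        altloc="" if at.altloc in ("\0", " ", "") else at.altloc,
                        res_name=res.name,
                        chain=chain.name,
                        res_seq=res.seqid.num,
                        xyz=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=round(float(at.occ), 4),
                        b_factor=round(float(at.b_iso), 3),
                    )
                )
    return Structure(cell=cell, space_group=sg, atoms=atoms, meta=dict(meta or {}))


def _format_atom_line(a: Atom, serial: int) -> str:
    record = "ATOM  " if a.is_amino_acid else "HETATM"
    name = a.name
    # PDB alignment: 1-char elements start in column 14 unless 4 chars long
    if len(name) < 4 and len(a.element) == 1:
        name = " " + name
    return (
        f"{record}{serial:5d} {name:<4s}{a.altloc or ' ':1s}{a.res_name:<3s} "
        f"{a.chain:1s}{a.res_seq:4d}    "
        f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
        f"{a.occupancy:6.2f}{a.b_factor:6.2f}          {a.element:>2s}"
    )


def write_structure(structure: Structure, path) -> None:
    """Write a Structure as a minimal, deterministic PDB file."""
    c = structure.cell
    lines = [
        f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
        f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} "
        f"{structure.space_group.hermann_mauguin_name:<11s}{1:4d}"
    ]
    for i, atom in enumerate(structure.atoms, start=1):
        lines.append(_format_atom_line(atom, i))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def transform_atoms(atoms: Iterable[Atom], cell: UnitCell, op: SymOp, shift) -> list:
    """Apply a symmetry op plus integer lattice shift to atoms (orth frame kept)."""
    shift = np.asarray(shift, dtype=float)
    out = []
    for a in atoms:
        frac = orth_to_frac(cell, a.pos)
        new = frac_to_orth(cell, op.apply(frac) + shift)
        out.append(replace(a, xyz=tuple(new)))
    return out
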