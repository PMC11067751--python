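"""Ground-truth fixture generator for the whole analysis pipeline.

Builds toy tetragonal lysozyme-like crystal structures carrying
fac-[Re(CO)3(Imi)(H2O)(X)] or fac-[Re(CO)3(Imi)2(X)] complexes planted on
minimal His/Asp/Asn side-chain stubs at configurable metal-donor
distances, an optional four-imidazole ring cage spanning a genuine
symmetry contact, per-week occupancy schedules, anomalous peak lists whose
heights scale with occupancy and f'', and a series manifest whose
refinement statistics reproduce a requested DPI. Every planted quantity is
recorded in a ground-truth object so parameter recovery can be checked
end to end.

The default series emulates the study conditions of the motivating
experiment: a P43212 cell of a = b = 81.1, c = 37.2 Angstrom, seven time
points at weeks 1-38 alternating between laboratory Cu K-alpha and
synchrotron wavelengths, three covalent sites (His15, Asp101, Asp119)
plus a weakly interacting Asn46 site, and occupancy schedules that tend
upward with time. The peak-height model (base x occupancy x f'' ratio +
noise) is a synthetic stand-in used to exercise the plumbing; real
anomalous peak heights are noisier than refined occupancies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .metal_coordination import f_double_prime
from .covalency import classify_interaction, donor_context_for
from .structure_io import (
    Atom,
    SpaceGroup,
    Structure,
    UnitCell,
    frac_to_orth,
    orth_to_frac,
    space_group_from_name,
    write_structure,
)

__all__ = [
    "SiteSpec",
    "CageSpec",
    "FixtureConfig",
    "GroundTruth",
    "build_complex",
    "generate_series",
]

RE_C_DISTANCE = 1.92  # Re-C(carbonyl), Angstrom
C_O_DISTANCE = 1.15  # carbonyl triple bond
RE_IMI_DISTANCE = 2.185  # Re-N(imidazole)
RE_WATER_DISTANCE = 2.19
RING_RADIUS = 1.166  # regular pentagon with 1.37 Angstrom edges

# default study wavelengths: laboratory Cu K-alpha and the Re L1-edge setting
LAB_WL = 1.5418
DLS_WL = 0.976


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _rotation_to(z_target) -> np.ndarray:
    """Proper rotation taking the +z axis onto ``z_target`` (Rodrigues)."""
    z = np.array([0.0, 0.0, 1.0])
    t = _unit(z_target)
    c = float(np.dot(z, t))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = _unit(np.cross(z, t))
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(math.acos(c)) * k + (1 - c) * (k @ k)


def _pentagon(centroid, normal, toward, names, elements, start_angle=0.0):
    """Five ring atoms on a circle of RING_RADIUS around ``centroid``.

    ``toward`` fixes the in-plane direction of the first atom.
    """
    n = _unit(normal)
    u = np.asarray(toward, dtype=float) - np.dot(toward, n) * n
    u = _unit(u)
    v = np.cross(n, u)
    pts = []
    for i in range(5):
        ang = math.radians(start_angle + 72.0 * i)
        pts.append(centroid + RING_RADIUS * (math.cos(ang) * u + math.sin(ang) * v))
    return list(zip(names, elements, pts))


def build_complex(kind: str, re_donor_distance: float, orientation=None) -> list:
    """Ideal fac-[Re(CO)3...] complex in a local frame, Re at the origin.

    Returns (name, element, xyz) triples. The three carbonyls are mutually
    cis along +x/+y/+z; the protein donor slot points along -z at the
    requested distance (the donor atom itself is not part of the complex);
    an imidazole N sits along -x and either a water O (``ImiAqua``) or a
    second imidazole (``ImiImi``) along -y. ``orientation`` is an optional
    3x3 rotation applied to every atom.
    """
    if kind not in ("ImiAqua", "ImiImi"):
        raise ValueError(f"unknown complex kind {kind!r}")
    if not 1.8 < re_donor_distance < 3.2:
        raise ValueError(f"Re-donor distance {re_donor_distance} outside (1.8, 3.2)")
    atoms: list = [("RE", "Re", np.zeros(3))]
    for i, axis in enumerate(np.eye(3)):
        atoms.append((f"C{i+1}", "C", RE_C_DISTANCE * axis))
        atoms.append((f"O{i+1}", "O", (RE_C_DISTANCE + C_O_DISTANCE) * axis))

    def imidazole(direction, normal, prefix):
        n_pos = RE_IMI_DISTANCE * direction
        centroid = n_pos + RING_RADIUS * direction
        # coordinating N points back toward the metal
        ring = _pentagon(
            centroid,
            normal,
            -direction,
            [f"N{prefix}1", f"C{prefix}2", f"N{prefix}3", f"C{prefix}4", f"C{prefix}5"],
            ["N", "C", "N", "C", "C"],
        )
        return ring

    atoms.extend(imidazole(np.array([-1.0, 0, 0]), np.array([0, 1.0, 0]), "1"))
    if kind == "ImiImi":
        atoms.extend(imidazole(np.array([0, -1.0, 0]), np.array([1.0, 0, 0]), "2"))
    else:
        atoms.append(("OW", "O", RE_WATER_DISTANCE * np.array([0, -1.0, 0])))
    if orientation is not None:
        r = np.asarray(orientation, dtype=float)
        atoms = [(n, e, r @ p) for n, e, p in atoms]
    return atoms


_STUB_BUILDERS = {}


def _stub(res_name):
    def wrap(fn):
        _STUB_BUILDERS[res_name] = fn
        return fn

    return wrap


@_stub("HIS")
def _his_stub(donor_pos, u):
    """Minimal His side chain; NE2 (the donor) at ``donor_pos``, ring away from Re."""
    centroid = donor_pos - RING_RADIUS * u
    names = ["NE2", "CD2", "CG", "ND1", "CE1"]
    elements = ["N", "C", "C", "N", "C"]
    w = _unit(np.cross(u, [0.31, 0.95, 0.07]))
    ring = _pentagon(centroid, w, u, names, elements)
    cg_pos = dict((n, p) for n, _, p in ring)["CG"]
    cb = cg_pos + 1.52 * _unit(cg_pos - centroid)
    return ring + [("CB", "C", cb)], "NE2"


@_stub("ASP")
def _asp_stub(donor_pos, u):
    cg = donor_pos - 1.25 * u
    w = _unit(np.cross(u, [0.23, 0.86, 0.45]))
    od1 = cg + 1.25 * _unit(-0.5 * u + 0.866 * w)
    cb = cg + 1.52 * _unit(-0.5 * u - 0.866 * w)
    return [("OD2", "O", donor_pos), ("CG", "C", cg), ("OD1", "O", od1), ("CB", "C", cb)], "OD2"


@_stub("ASN")
def _asn_stub(donor_pos, u):
    cg = donor_pos - 1.33 * u
    w = _unit(np.cross(u, [0.61, 0.32, 0.72]))
    od1 = cg + 1.23 * _unit(-0.5 * u + 0.866 * w)
    cb = cg + 1.52 * _unit(-0.5 * u - 0.866 * w)
    return [("ND2", "N", donor_pos), ("CG", "C", cg), ("OD1", "O", od1), ("CB", "C", cb)], "ND2"


@dataclass
class SiteSpec:
    """One planted metal site."""

    res_name: str  # HIS / ASP / ASN
    res_seq: int
    kind: str  # ImiAqua / ImiImi
    re_donor_distance: float
    occupancies: tuple  # one per week; None = site absent that week
    anchor: tuple  # donor-atom position, orthogonal Angstrom
    direction: tuple = (0.0, 0.0, 1.0)  # donor -> metal direction
    b_factor: float = 20.0

    def __post_init__(self):
        if self.res_name not in _STUB_BUILDERS:
            raise ValueError(f"unsupported residue {self.res_name!r}")
        if not 1.5 < self.re_donor_distance < 3.5:
            raise ValueError(
                f"re_donor_distance must lie in (1.5, 3.5), got {self.re_donor_distance}"
            )
        for occ in self.occupancies:
            if occ is not None and not 0 <= occ <= 1:
                raise ValueError(f"occupancy {occ} outside [0,1]")


@dataclass
class CageSpec:
    """Four imidazole rings spanning a symmetry contact.

    ``distances`` are the four cycle edges (ring1-ring2, ring2-ring3,
    ring3-ring4, ring4-ring1); rings 1 and 2 are planted in the reference
    asymmetric unit, rings 3 and 4 as preimages under ``op_index`` so the
    cage genuinely crosses a crystal contact. ``normal_tilts`` (degrees,
    about the cage-plane x axis) set the ring orientations.
    """

    distances: tuple = (4.16, 4.20, 4.83, 5.04)
    normal_tilts: tuple = (0.0, 65.0, 115.0, 50.0)
    diagonal: float = 6.5
    anchor: tuple = (20.0, 20.0, 10.0)
    op_index: int = 1

    def centroids(self) -> np.ndarray:
        d12, d23, d34, d41 = self.distances
        L = self.diagonal
        for a, b in ((d12, d23), (d41, d34)):
            if not abs(a - b) < L < a + b:
                raise ValueError(
                    f"cage geometry unsatisfiable: sides {a}, {b} with diagonal {L} "
                    "violate the triangle inequality"
                )
        x2 = (d12**2 - d23**2 + L**2) / (2 * L)
        y2 = math.sqrt(d12**2 - x2**2)
        x4 = (d41**2 - d34**2 + L**2) / (2 * L)
        y4 = -math.sqrt(d41**2 - x4**2)
        pts = np.array(
            [[0.0, 0.0, 0.0], [x2, y2, 0.0], [L, 0.0, 0.0], [x4, y4, 0.0]]
        )
        return pts + np.asarray(self.anchor, dtype=float)

    def normals(self) -> np.ndarray:
        return np.array(
            [
                [0.0, math.sin(math.radians(t)), math.cos(math.radians(t))]
                for t in self.normal_tilts
            ]
        )

    def pair_geometry(self) -> list:
        """Planted (distance, folded interplanar angle) for the 4 cycle edges."""
        cents = self.centroids()
        norms = self.normals()
        out = []
        for i, j in ((0, 1), (1, 2), (2, 3), (3, 0)):
            d = float(np.linalg.norm(cents[i] - cents[j]))
            cos = abs(float(np.dot(norms[i], norms[j])))
            out.append((d, math.degrees(math.acos(min(cos, 1.0)))))
        return out


def _default_sites() -> list:
    occ = {
        # Table-2-like upward occupancy schedules over the seven weeks
        "HIS15": (0.56, 0.75, 0.68, 0.75, 0.65, 0.84, 0.84),
        "ASP101": (0.54, 0.68, 0.44, 0.55, 0.56, 0.58, 0.43),
        "ASP119": (0.44, 0.64, 0.48, 0.60, 0.65, 0.58, 0.53),
        "ASN46": (None, 0.21, 0.08, None, None, 0.20, None),
    }
    return [
        SiteSpec("HIS", 15, "ImiAqua", 2.22, occ["HIS15"], (12.0, 12.0, 10.0), (0.2, 0.3, 0.93)),
        SiteSpec("ASP", 101, "ImiImi", 2.14, occ["ASP101"], (45.0, 14.0, 14.0), (0.8, 0.4, 0.45)),
        SiteSpec("ASP", 119, "ImiImi", 2.14, occ["ASP119"], (14.0, 48.0, 20.0), (0.5, 0.7, 0.5)),
        SiteSpec("ASN", 46, "ImiAqua", 2.43, occ["ASN46"], (50.0, 52.0, 8.0), (0.3, 0.8, 0.53)),
    ]


@dataclass
class FixtureConfig:
    cell: UnitCell = field(default_factory=lambda: UnitCell(81.1, 81.1, 37.2))
    space_group: str = "P 43 21 2"
    weeks: tuple = (1, 3, 9, 11, 14, 18, 38)
    wavelengths: tuple = (LAB_WL, DLS_WL, DLS_WL, LAB_WL, LAB_WL, DLS_WL, DLS_WL)
    sites: list = field(default_factory=_default_sites)
    cage: Optional[CageSpec] = None
    jitter_sigma: float = 0.0
    peak_base: float = 30.0  # sigma units at full occupancy and Cu K-alpha f''
    peak_noise_sd: float = 0.0
    target_dpi: tuple = (0.084, 0.072, 0.026, 0.042, 0.040, 0.023, 0.022)
    d_min: tuple = (1.75, 1.68, 1.23, 1.23, 1.41, 1.21, 1.15)
    n_reflections: int = 3000
    completeness: float = 0.98
    seed: int = 0

    def __post_init__(self):
        n = len(self.weeks)
        for name in ("wavelengths", "target_dpi", "d_min"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per week")
        for site in self.sites:
            if len(site.occupancies) != n:
                raise ValueError(
                    f"site {site.res_name}{site.res_seq}: occupancy schedule length "
                    f"{len(site.occupancies)} != {n} weeks"
                )


@dataclass
class GroundTruth:
    """Everything that was planted, self-consistent with the emitted files."""

    weeks: list = field(default_factory=list)  # one dict per week

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({"weeks": self.weeks}, indent=2, sort_keys=True))


def _plant_site(site: SiteSpec, occupancy: float, serial_start: int) -> tuple:
    """Residue stub + complex atoms for one site; returns (atoms, re_pos)."""
    u = _unit(site.direction)
    donor_pos = np.asarray(site.anchor, dtype=float)
    re_pos = donor_pos + site.re_donor_distance * u
    stub_atoms, donor_name = _STUB_BUILDERS[site.res_name](donor_pos, u)
    atoms = []
    serial = serial_start
    for name, element, pos in stub_atoms:
        atoms.append(
            Atom(serial, name, element, "", site.res_name, "A", site.res_seq,
                 tuple(pos), 1.0, site.b_factor)
        )
        serial += 1
    res_name = "REI" if site.kind == "ImiAqua" else "VHL"
    # complex -z axis (donor slot) must point from Re back to the donor
    rot = _rotation_to(u)
    for name, element, pos in build_complex(site.kind, site.re_donor_distance, orientation=rot):
        atoms.append(
            Atom(serial, name, element, "", res_name, "A", 200 + site.res_seq,
                 tuple(re_pos + pos), occupancy, site.b_factor)
        )
        serial += 1
    return atoms, re_pos


def _plant_cage(cage: CageSpec, sg: SpaceGroup, cell: UnitCell, serial_start: int) -> list:
    """Four free imidazole rings; rings 3 and 4 are preimages under the op."""
    cents = cage.centroids()
    norms = cage.normals()
    op = sg.ops[cage.op_index]
    if op.is_identity():
        raise ValueError("cage op_index must select a non-identity operator")
    rot_inv = np.linalg.inv(op.rot)
    atoms = []
    serial = serial_start
    for i in range(4):
        ring = _pentagon(
            cents[i], norms[i], [1.0, 0.2, 0.1],
            ["N1", "C2", "N3", "C4", "C5"], ["N", "C", "N", "C", "C"],
            start_angle=10.0 * i,
        )
        if i >= 2:  # plant the preimage so the op restores the target geometry
            moved = []
            for name, element, pos in ring:
                frac = orth_to_frac(cell, pos)
                pre = rot_inv @ (frac - op.trans)
                moved.append((name, element, frac_to_orth(cell, pre)))
            ring = moved
        for name, element, pos in ring:
            atoms.append(
                Atom(serial, name, element, "", "IMD", "B", 900 + i, tuple(pos), 1.0, 15.0)
            )
            serial += 1
    return atoms


def _solve_r_free(dpi: float, n_atoms: int, n_reflections: int, completeness: float,
                  d_min: float) -> float:
    r_free = dpi / (math.sqrt(n_atoms / n_reflections) * completeness ** (-1 / 3) * d_min)
    if not 0 < r_free < 1:
        raise ValueError(
            f"target DPI {dpi} not reachable with n_reflections={n_reflections}: "
            f"implied R_free {r_free:.3f}"
        )
    return r_free


def generate_series(config: FixtureConfig, out_dir) -> Tuple[Path, GroundTruth]:
    """Write one PDB + peak CSV per week plus a manifest and ground truth.

    Returns the manifest path and the :class:`GroundTruth`. With the same
    seed the emitted files are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sg = space_group_from_name(config.space_group)
    if config.cage is not None:
        config.cage.centroids()  # validate geometry before writing anything
    truth = GroundTruth()
    manifest_entries = []
    for wi, week in enumerate(config.weeks):
        wavelength = config.wavelengths[wi]
        atoms = []
        week_truth = {"week": week, "wavelength": wavelength, "sites": [], "cage": None}
        peak_rows = []
        f2 = f_double_prime("Re", wavelength)
        f2_ratio = f2 / f_double_prime("Re", LAB_WL)
        dpi = config.target_dpi[wi]
        for site in config.sites:
            occupancy = site.occupancies[wi]
            if occupancy is None:
                continue
            site_atoms, re_pos = _plant_site(site, occupancy, len(atoms) + 1)
            atoms.extend(site_atoms)
            donor_name = {"HIS": "NE2", "ASP": "OD2", "ASN": "ND2"}[site.res_name]
            ctx = donor_context_for(site.res_name, donor_name, donor_name[0])
            expected = classify_interaction(
                site.re_donor_distance, math.sqrt(2) * dpi, "Re",
                donor_context=ctx, donor_element=donor_name[0],
            )
            peak_height = config.peak_base * occupancy * f2_ratio
            week_truth["sites"].append(
                {
                    "residue": f"{site.res_name}{site.res_seq}",
                    "chain": "A",
                    "res_seq": site.res_seq,
                    "donor_atom": donor_name,
                    "distance": site.re_donor_distance,
                    "occupancy": occupancy,
                    "peak_height": peak_height,
                    "expected_label": expected.label,
                }
            )
            peak_rows.append((re_pos, peak_height))
        if config.cage is not None:
            atoms.extend(_plant_cage(config.cage, sg, config.cell, len(atoms) + 1))
            week_truth["cage"] = {
                "distances": [d for d, _ in config.cage.pair_geometry()],
                "angles": [a for _, a in config.cage.pair_geometry()],
            }
        if config.jitter_sigma > 0:
            atoms = [
                Atom(
                    a.serial, a.name, a.element, a.altloc, a.res_name, a.chain, a.res_seq,
                    tuple(a.pos + rng.normal(0.0, config.jitter_sigma, 3)),
                    a.occupancy, a.b_factor,
                )
                for a in atoms
            ]
        # peaks sit on the (possibly jittered) metal positions
        re_positions = [a.pos for a in atoms if a.element == "Re"]
        peaks_out = []
        for (planted_pos, height), pos in zip(peak_rows, re_positions):
            noisy = height + (rng.normal(0.0, config.peak_noise_sd) if config.peak_noise_sd else 0)
            peaks_out.append((pos, max(noisy, 0.1)))

        structure = Structure(
            cell=config.cell, space_group=sg, atoms=atoms,
            meta={"week_label": week, "wavelength": wavelength},
        )
        pdb_path = out_dir / f"week_{week:02d}_{wavelength:.3f}.pdb"
        write_structure(structure, pdb_path)
        peaks_path = out_dir / f"week_{week:02d}_{wavelength:.3f}_peaks.csv"
        with open(peaks_path, "w") as fh:
            fh.write("x,y,z,height\n")
            for pos, height in peaks_out:
                fh.write(f"{pos[0]:.3f},{pos[1]:.3f},{pos[2]:.3f},{height:.3f}\n")
        n_atoms = len(atoms)
        manifest_entries.append(
            {
                "path": pdb_path.name,
                "peaks": peaks_path.name,
                "week": week,
                "wavelength": wavelength,
                "label": f"week {week} ({wavelength} A)",
                "stats": {
                    "n_atoms": n_atoms,
                    "n_reflections": config.n_reflections,
                    "completeness": config.completeness,
                    "r_factor": round(
                        0.9 * _solve_r_free(dpi, n_atoms, config.n_reflections,
                                            config.completeness, config.d_min[wi]), 6),
                    "r_free": round(
                        _solve_r_free(dpi, n_atoms, config.n_reflections,
                                      config.completeness, config.d_min[wi]), 6),
                    "d_min": config.d_min[wi],
                    "avg_b": 20.0,
                },
            }
        )
        truth.weeks.append(week_truth)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps({"series": manifest_entries}, indent=2, sort_keys=True))
    truth.to_json(out_dir / "ground_truth.json")
    return manifest_path, truth
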