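"""Metal-site detection, coordination spheres and anomalous-signal scaling.

A metal site is a metal atom (rhenium by default) together with every
candidate donor atom (N, O, S) within a coordination cutoff (3.0 Angstrom
by default), searched over the reference molecule and its symmetry mates.
Each donor distance carries a standard uncertainty once a precision model
is attached. Sites also carry the refined occupancy and, when an anomalous
peak list is supplied, the height of the matching anomalous difference
map peak.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .precision import PrecisionModel, atom_su, distance_su
from .structure_io import Atom, Structure, frac_to_orth, orth_to_frac
from .symmetry_contacts import symmetry_mates

__all__ = [
    "MetalSite",
    "Ligand",
    "PeakListEntry",
    "find_metal_sites",
    "expected_peak_ratio",
    "format_ratio",
    "f_double_prime",
    "associate_peaks",
    "read_peak_list",
    "attach_precision",
]

DONOR_ELEMENTS = frozenset({"N", "O", "S"})
MIN_SANE_DISTANCE = 0.8  # Angstrom; anything shorter is a modelling artefact


@dataclass
class Ligand:
    atom: Atom
    distance: float
    su: Optional[float] = None
    is_symmetry_mate: bool = False


@dataclass
class MetalSite:
    metal: Atom
    ligands: List[Ligand] = field(default_factory=list)
    peak_height: Optional[float] = None
    residual_density: Optional[float] = None

    @property
    def occupancy(self) -> float:
        return self.metal.occupancy

    @property
    def binding_residues(self) -> list:
        """Amino-acid residues contributing donor atoms, ordered by distance."""
        seen = []
        for lig in sorted(self.ligands, key=lambda l: l.distance):
            key = lig.atom.residue_key
            if lig.atom.is_amino_acid and key not in seen:
                seen.append(key)
        return seen

    @property
    def primary_residue(self) -> Optional[tuple]:
        res = self.binding_residues
        return res[0] if res else None

    def protein_ligands(self) -> List[Ligand]:
        return [l for l in self.ligands if l.atom.is_amino_acid]


def find_metal_sites(
    structure: Structure,
    metal_elements: Set[str] = frozenset({"Re"}),
    cutoff: float = 3.0,
    donor_elements: Set[str] = DONOR_ELEMENTS,
    include_symmetry: bool = True,
) -> List[MetalSite]:
    """One :class:`MetalSite` per metal atom, with its donor sphere.

    Donors are non-metal N/O/S atoms within ``cutoff`` of the metal, taken
    from the reference molecule and (by default) symmetry mates. Among
    altlocs of one donor atom only the highest-occupancy copy is kept.
    Metal detection is by element, never by residue name.
    """
    if not 1.0 < cutoff < 5.0:
        warnings.warn(f"coordination cutoff {cutoff} outside the customary (1, 5) range")
    metals = [a for a in structure.atoms if a.element in metal_elements]
    if not metals:
        return []

    candidates = [
        (a, False)
        for a in structure.atoms
        if a.element in donor_elements and a.element not in metal_elements
    ]
    if include_symmetry:
        for mate in symmetry_mates(structure, cutoff + 0.5):
            candidates.extend(
                (a, True)
                for a in mate.atoms
                if a.element in donor_elements and a.element not in metal_elements
            )

    sites = []
    for metal in metals:
        best = {}  # (residue key, atom name, is_sym) -> Ligand, best altloc wins
        for atom, is_sym in candidates:
            d = float(np.linalg.norm(metal.pos - atom.pos))
            if not MIN_SANE_DISTANCE <= d <= cutoff:
                continue
            key = (atom.residue_key, atom.name, is_sym, round(d, 1) if is_sym else 0)
            cur = best.get(key)
            if cur is None or atom.occupancy > cur.atom.occupancy:
                best[key] = Ligand(atom=atom, distance=d, is_symmetry_mate=is_sym)
        ligands = sorted(best.values(), key=lambda l: l.distance)
        sites.append(MetalSite(metal=metal, ligands=ligands))
    return sites


def attach_precision(
    sites: Iterable[MetalSite], model: PrecisionModel, avg_b: Optional[float] = None
) -> None:
    """Fill each ligand's distance su from the precision model (in place)."""
    for site in sites:
        su_metal = atom_su(model, site.metal, avg_b)
        for lig in site.ligands:
            lig.su = distance_su(su_metal, atom_su(model, lig.atom, avg_b))


def expected_peak_ratio(f2_a: float, f2_b: float) -> float:
    """Expected anomalous-peak height ratio between two f'' values.

    Anomalous difference map peak heights scale linearly with f'', so the
    expected ratio is simply f''_a / f''_b.
    """
    if f2_a <= 0 or f2_b <= 0:
        raise ValueError(f"f'' values must be positive, got {f2_a}, {f2_b}")
    return f2_a / f2_b


def format_ratio(ratio: float, sig: int = 2) -> str:
    """Format a ratio to ``sig`` significant figures for reporting."""
    if ratio == 0:
        return "0"
    decimals = sig - 1 - math.floor(math.log10(abs(ratio)))
    return f"{round(ratio, decimals):.{max(decimals, 0)}f}"


def _load_f2_table() -> dict:
    table = {}
    with resources.files("metalloscan.data").joinpath("f_double_prime.csv").open() as fh:
        for row in csv.DictReader(filter(lambda l: not l.startswith("#"), fh)):
            table[(row["element"], float(row["wavelength"]))] = float(row["f_double_prime"])
    return table


_F2_TABLE = None


def f_double_prime(element: str, wavelength: float, tol: float = 0.02) -> float:
    """Bundled f'' (electrons) for an element at a wavelength (Angstrom)."""
    global _F2_TABLE
    if _F2_TABLE is None:
        _F2_TABLE = _load_f2_table()
    matches = [
        v for (el, wl), v in _F2_TABLE.items() if el == element and abs(wl - wavelength) <= tol
    ]
    if not matches:
        known = sorted(wl for el, wl in _F2_TABLE if el == element)
        raise KeyError(
            f"no bundled f'' for {element} at {wavelength} Angstrom (known: {known}); "
            "supply a value explicitly"
        )
    return matches[0]


@dataclass(frozen=True)
class PeakListEntry:
    xyz: tuple  # orthogonal Angstrom frame
    height: float  # sigma units

    def __post_init__(self):
        if self.height <= 0:
            raise ValueError(f"peak height must be positive, got {self.height}")

    @property
    def pos(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)


def read_peak_list(path, structure: Optional[Structure] = None, frame: str = "orthogonal"):
    """Read an anomalous peak list CSV with header ``x,y,z,height``.

    ``frame="fractional"`` converts coordinates through the structure's cell.
    """
    df = pd.read_csv(path, comment="#")
    expected = {"x", "y", "z", "height"}
    if not expected <= set(df.columns):
        raise ValueError(f"{path}: peak list must have columns {sorted(expected)}")
    peaks = []
    for _, row in df.iterrows():
        xyz = np.array([row["x"], row["y"], row["z"]], dtype=float)
        if frame == "fractional":
            if structure is None:
                raise ValueError("fractional peak lists need the structure for the cell")
            xyz = frac_to_orth(structure.cell, xyz)
        peaks.append(PeakListEntry(tuple(xyz), float(row["height"])))
    return peaks


def _symmetry_min_distance(structure: Structure, a: np.ndarray, b: np.ndarray) -> float:
    """Minimum distance between point a and any symmetry image of point b."""
    cell = structure.cell
    fa = orth_to_frac(cell, a)
    fb = orth_to_frac(cell, b)
    best = math.inf
    for op in structure.space_group.ops:
        img = op.apply(fb)
        diff = fa - img
        diff -= np.round(diff)  # nearest lattice image
        d = float(np.linalg.norm(frac_to_orth(cell, diff)))
        best = min(best, d)
    return best


def associate_peaks(
    sites: Sequence[MetalSite],
    peaks: Sequence[PeakListEntry],
    structure: Structure,
    match_radius: float = 1.0,
) -> List[MetalSite]:
    """Assign anomalous peak heights to metal sites (greedy by distance).

    Symmetry images of each peak are considered; each peak goes to at most
    one site and each site takes the nearest unassigned peak within
    ``match_radius``. Unmatched sites keep ``peak_height=None``.
    """
    pairs = []
    for si, site in enumerate(sites):
        for pi, peak in enumerate(peaks):
            d = _symmetry_min_distance(structure, site.metal.pos, peak.pos)
            if d <= match_radius:
                pairs.append((d, si, pi))
    pairs.sort()
    used_sites, used_peaks = set(), set()
    for d, si, pi in pairs:
        if si in used_sites or pi in used_peaks:
            continue
        sites[si].peak_height = peaks[pi].height
        used_sites.add(si)
        used_peaks.add(pi)
    return list(sites)


def sites_to_table(sites: Sequence[MetalSite]) -> pd.DataFrame:
    """Site-level summary table (occupancy, peak height, residual density)."""
    rows = []
    for site in sites:
        res = site.primary_residue
        rows.append(
            {
                "site": f"{res[2]}{res[1]}" if res else f"{site.metal.name}@{site.metal.serial}",
                "chain": res[0] if res else site.metal.chain,
                "occupancy": site.occupancy,
                "peak_height": site.peak_height,
                "residual_density": site.residual_density,
                "n_ligands": len(site.ligands),
            }
        )
    return pd.DataFrame(rows)


def distances_to_table(sites: Sequence[MetalSite], protein_only: bool = True) -> pd.DataFrame:
    """Distance table mirroring a bond-distance report (residue, atoms, d, su)."""
    rows = []
    for site in sites:
        ligs = site.protein_ligands() if protein_only else site.ligands
        for lig in ligs:
            rows.append(
                {
                    "residue": f"{lig.atom.res_name}{lig.atom.res_seq}",
                    "metal_atom": site.metal.name,
                    "donor_atom": lig.atom.name,
                    "distance": round(lig.distance, 3),
                    "su": round(lig.su, 4) if lig.su is not None else None,
                    "symmetry_mate": lig.is_symmetry_mate,
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["residue", "donor_atom"]).reset_index(drop=True)
    return df
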