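"""Aromatic-ring geometry and pi-pi stacking classification.

Rings are fitted with a least-squares plane (smallest principal axis of
the centred coordinates). Pairs of rings — including pairs that span a
crystal contact to a symmetry mate — are characterised by their
centroid-to-centroid distance and the dihedral angle between the ring
planes, folded into [0, 90] degrees, and classified as face-to-face,
edge-to-face or intermediate under either small-molecule or macromolecular
criteria. Connected components of the interaction graph are reported as
"cages" (the four-imidazole cage bridging two metal complexes across a
crystal contact is the motivating case).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .precision import PrecisionModel
from .structure_io import Atom, Structure
from .symmetry_contacts import SymMate, symmetry_mates

__all__ = [
    "AromaticRing",
    "RingInteraction",
    "fit_ring",
    "interplanar_angle",
    "classify_stacking",
    "find_ring_network",
    "RingNetwork",
]

# His side-chain imidazole by atom-name convention
_HIS_RING_ATOMS = ("CG", "ND1", "CD2", "CE1", "NE2")
_BOND_CUTOFF = 1.8  # Angstrom, covalent-bond perception for ligand rings


@dataclass
class AromaticRing:
    ring_id: tuple  # (chain, res_seq, res_name, copy descriptor)
    member_atoms: list
    centroid: np.ndarray
    normal: np.ndarray
    planarity_rmsd: float

    @property
    def base_id(self) -> tuple:
        """Ring identity ignoring which symmetry copy it belongs to."""
        chain, res_seq, res_name, _copy, *rest = self.ring_id + ("",)
        return (chain, res_seq, res_name) + tuple(sorted(a.name for a in self.member_atoms))


def fit_ring(atoms: Sequence[Atom], ring_id: tuple = ("", 0, "", "ref")) -> AromaticRing:
    """Least-squares plane fit of >= 3 ring atoms.

    The normal is the singular vector of the centred coordinates with the
    smallest singular value; the planarity rmsd is the rms perpendicular
    deviation from the fitted plane.
    """
    coords = np.array([a.xyz for a in atoms], dtype=float)
    if len(coords) < 3:
        raise ValueError(f"ring needs >= 3 atoms, got {len(coords)}")
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-9:  # only one non-trivial direction: collinear points
        raise ValueError("ring atoms are collinear; no plane is defined")
    normal = vt[-1]
    normal = normal / np.linalg.norm(normal)
    rmsd = float(np.sqrt(np.mean((centred @ normal) ** 2)))
    return AromaticRing(
        ring_id=ring_id,
        member_atoms=list(atoms),
        centroid=centroid,
        normal=normal,
        planarity_rmsd=rmsd,
    )


def interplanar_angle(normal_a, normal_b) -> float:
    """Angle between two ring planes in degrees, folded into [0, 90]."""
    a = np.asarray(normal_a, dtype=float)
    b = np.asarray(normal_b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("zero-length normal vector")
    cos = abs(float(np.dot(a, b)) / (na * nb))
    return math.degrees(math.acos(min(cos, 1.0)))


def classify_stacking(distance: float, angle: float, criteria: str = "small_molecule") -> str:
    """Classify a ring pair from centroid distance (Angstrom) and folded angle.

    small_molecule: face-to-face at d < 4.0 and angle < 30; edge-to-face at
    d < 5.5 and angle >= 60 (the 60-120 degree band folds to >= 60);
    intermediate at d < 5.5 with angle in [30, 60); none otherwise.

    macromolecular: face-to-face requires d in [3.3, 3.8]; edge-to-face at
    d <= 5.5 and angle >= 60; intermediate as above.
    """
    if distance <= 0:
        raise ValueError(f"distance must be positive, got {distance}")
    if not 0 <= angle <= 90:
        raise ValueError(f"angle must be folded into [0, 90], got {angle}")
    if criteria == "small_molecule":
        if distance < 4.0 and angle < 30:
            return "face_to_face"
        if distance < 5.5 and angle >= 60:
            return "edge_to_face"
        if distance < 5.5 and 30 <= angle < 60:
            return "intermediate"
        return "none"
    if criteria == "macromolecular":
        if 3.3 <= distance <= 3.8 and angle < 30:
            return "face_to_face"
        if distance <= 5.5 and angle >= 60:
            return "edge_to_face"
        if distance <= 5.5 and 30 <= angle < 60:
            return "intermediate"
        return "none"
    raise ValueError(f"unknown criteria set {criteria!r}")


@dataclass
class RingInteraction:
    ring_a: tuple
    ring_b: tuple
    centroid_distance: float
    interplanar_angle: float
    label: str
    criteria: str
    distance_su: Optional[float] = None

    def __post_init__(self):
        if not 0 <= self.interplanar_angle <= 90:
            raise ValueError("interplanar angle must be in [0, 90]")


@dataclass
class RingNetwork:
    interactions: List[RingInteraction]
    cages: List[list] = field(default_factory=list)  # lists of ring_ids

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "ring_a": "/".join(map(str, i.ring_a)),
                "ring_b": "/".join(map(str, i.ring_b)),
                "distance": round(i.centroid_distance, 3),
                "su": round(i.distance_su, 4) if i.distance_su is not None else None,
                "angle": round(i.interplanar_angle, 1),
                "label": i.label,
            }
            for i in self.interactions
        ]
        return pd.DataFrame(rows)


def _ligand_rings(atoms: Sequence[Atom]) -> list:
    """Five-membered N-containing rings in a non-amino-acid residue.

    Bond perception by distance (< 1.8 Angstrom between non-hydrogen C/N
    atoms), cycles from the bond graph; works for any ligand naming dialect.
    """
    ring_atoms = [a for a in atoms if a.element in ("C", "N")]
    if len(ring_atoms) < 5:
        return []
    g = nx.Graph()
    g.add_nodes_from(range(len(ring_atoms)))
    for i, j in itertools.combinations(range(len(ring_atoms)), 2):
        if np.linalg.norm(ring_atoms[i].pos - ring_atoms[j].pos) < _BOND_CUTOFF:
            g.add_edge(i, j)
    rings = []
    for cycle in nx.cycle_basis(g):
        if len(cycle) == 5:
            members = [ring_atoms[i] for i in cycle]
            if any(a.element == "N" for a in members):
                rings.append(members)
    return rings


def default_ring_selector(structure_atoms: Sequence[Atom]) -> list:
    """Default selector: His side-chain rings plus ligand imidazole rings.

    Returns (residue_key, [atoms]) groups. Detection of ligand rings is
    name-agnostic (connectivity based).
    """
    by_res = {}
    for a in structure_atoms:
        by_res.setdefault(a.residue_key, []).append(a)
    groups = []
    for key, atoms in by_res.items():
        chain, res_seq, res_name = key
        if res_name == "HIS":
            named = {a.name: a for a in atoms if not a.altloc or a.altloc == "A"}
            if all(n in named for n in _HIS_RING_ATOMS):
                groups.append((key, [named[n] for n in _HIS_RING_ATOMS]))
        elif res_name not in ("HOH", "WAT") and not atoms[0].is_amino_acid:
            for ring in _ligand_rings(atoms):
                groups.append((key, ring))
    return groups


def find_ring_network(
    structure: Structure,
    ring_selector: Optional[Callable] = None,
    max_distance: float = 5.5,
    precision_model: Optional[PrecisionModel] = None,
    criteria: str = "small_molecule",
    include_symmetry: bool = True,
    centroid_su_reduced: bool = False,
) -> RingNetwork:
    """All ring-pair interactions with centroid distance <= ``max_distance``.

    Rings of symmetry mates are included, and the cluster is closed under
    the distance cutoff so pairs between two mate rings that bridge the
    reference are kept. Interactions are deduplicated by symmetry: a cage
    component whose underlying rings are a subset of a larger component's
    (same rings, different symmetry copy) is suppressed.

    The centroid distance su is sqrt(2) times the per-centroid su, which by
    default equals the atom-level su; ``centroid_su_reduced`` divides it by
    sqrt(n_atoms) instead (the statistically optimistic option).
    """
    selector = ring_selector or default_ring_selector
    ref_groups = selector(structure.atoms)
    rings = []
    for idx, (key, atoms) in enumerate(ref_groups):
        rings.append(fit_ring(atoms, ring_id=(key[0], key[1], key[2], f"ref{idx}")))
    mate_rings = []
    if include_symmetry and rings:
        # buffer: a ring can reach past its centroid by roughly its radius
        for mate in symmetry_mates(structure, max_distance + 3.0):
            for idx, (key, atoms) in enumerate(selector(mate.atoms)):
                mate_rings.append(
                    fit_ring(atoms, ring_id=(key[0], key[1], key[2], mate.descriptor + f"_{idx}"))
                )

    # grow the local cluster: start from reference rings, absorb mate rings
    # within the cutoff of anything already in the cluster
    cluster = list(rings)
    remaining = list(mate_rings)
    changed = True
    while changed:
        changed = False
        still = []
        for mr in remaining:
            if any(np.linalg.norm(mr.centroid - r.centroid) <= max_distance for r in cluster):
                cluster.append(mr)
                changed = True
            else:
                still.append(mr)
        remaining = still

    su = None
    if precision_model is not None:
        per_centroid = precision_model.dpi
        if centroid_su_reduced:
            per_centroid = per_centroid / math.sqrt(5)
        su = math.sqrt(2) * per_centroid

    interactions = []
    g = nx.Graph()
    for r in cluster:
        g.add_node(r.ring_id, ring=r)
    for ra, rb in itertools.combinations(cluster, 2):
        d = float(np.linalg.norm(ra.centroid - rb.centroid))
        if d < 1e-6 or d > max_distance:
            continue
        ang = interplanar_angle(ra.normal, rb.normal)
        interactions.append(
            RingInteraction(
                ring_a=ra.ring_id,
                ring_b=rb.ring_id,
                centroid_distance=d,
                interplanar_angle=ang,
                label=classify_stacking(d, ang, criteria),
                criteria=criteria,
                distance_su=su,
            )
        )
        g.add_edge(ra.ring_id, rb.ring_id)

    # connected components as cages; drop symmetry-duplicate components
    # (their base-ring set is a subset of a larger component's)
    comps = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        if len(members) < 2:
            continue
        base = frozenset(g.nodes[m]["ring"].base_id for m in members)
        n_ref = sum(1 for m in members if str(m[3]).startswith("ref"))
        comps.append((members, base, n_ref))
    # biggest distinct cages first; among symmetry-equivalent copies prefer
    # the one anchored on the most reference rings
    comps.sort(key=lambda c: (-len(c[1]), -c[2], c[0]))
    kept = []
    for members, base, _ in comps:
        if any(base <= other_base for _, other_base in kept):
            continue
        kept.append((members, base))
    kept_ids = set()
    for members, _ in kept:
        kept_ids.update(members)
    interactions = [
        i for i in interactions if i.ring_a in kept_ids and i.ring_b in kept_ids
    ]
    interactions.sort(key=lambda i: (i.ring_a, i.ring_b))
    return RingNetwork(interactions=interactions, cages=[m for m, _ in kept])
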