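"""Covalent vs. weak-interaction classification of metal-donor distances.

Two reference families are bundled:

* sums of single-bond covalent radii (Cordero et al. 2008), with the
  per-element spreads combined in quadrature;
* small-molecule survey averages for fac-[Re(CO)3]+ complexes binding
  imidazole N, carboxylate O and amide N donors.

A distance is called *covalent* when it is equal within k combined
standard uncertainties to at least one applicable reference, *weak* when
it is not but still lies under a hard cap (3.0 Angstrom by default), and
*none* beyond the cap. All z-scores are recorded so borderline calls
remain auditable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence
import warnings

import pandas as pd

from .metal_coordination import MetalSite
from .precision import within_error

__all__ = [
    "ReferenceDistance",
    "InteractionCall",
    "covalent_radius_sum",
    "classify_interaction",
    "classify_structure",
    "donor_context_for",
    "load_covalent_radii",
    "load_survey_references",
]

# residue name -> donor atom names -> chemical context of the donor
_CONTEXT_MAP = {
    ("HIS", "ND1"): "imidazole_N",
    ("HIS", "NE2"): "imidazole_N",
    ("ASP", "OD1"): "carboxylate_O",
    ("ASP", "OD2"): "carboxylate_O",
    ("GLU", "OE1"): "carboxylate_O",
    ("GLU", "OE2"): "carboxylate_O",
    ("ASN", "ND2"): "amide_N",
    ("GLN", "NE2"): "amide_N",
}


@dataclass(frozen=True)
class ReferenceDistance:
    metal: str
    donor_context: str
    mean: float
    su: float
    source: str  # "covalent_radii_sum" or "csd_survey"
    n_hits: Optional[int] = None

    def __post_init__(self):
        if self.mean <= 0 or self.su < 0:
            raise ValueError(f"invalid reference distance {self}")


def _read_csv(name: str) -> list:
    with resources.files("metalloscan.data").joinpath(name).open() as fh:
        return list(csv.DictReader(filter(lambda l: not l.startswith("#"), fh)))


_RADII: Optional[dict] = None
_SURVEY: Optional[list] = None


def load_covalent_radii(override: Optional[dict] = None) -> dict:
    """Bundled covalent radii table: element -> (radius, spread) in Angstrom."""
    global _RADII
    if _RADII is None:
        _RADII = {
            row["element"]: (float(row["radius"]), float(row["su"]))
            for row in _read_csv("covalent_radii.csv")
        }
    table = dict(_RADII)
    if override:
        table.update(override)
    return table


def load_survey_references(override: Optional[Sequence[ReferenceDistance]] = None) -> list:
    """Bundled small-molecule survey references, plus any user-supplied ones."""
    global _SURVEY
    if _SURVEY is None:
        _SURVEY = [
            ReferenceDistance(
                metal=row["metal"],
                donor_context=row["donor_context"],
                mean=float(row["mean"]),
                su=float(row["su"]),
                source="csd_survey",
            )
            for row in _read_csv("reference_distances.csv")
        ]
    refs = list(_SURVEY)
    if override:
        refs.extend(override)
    return refs


def covalent_radius_sum(elem_a: str, elem_b: str, radii: Optional[dict] = None) -> tuple:
    """Sum of covalent radii of two elements with quadrature-combined spread."""
    table = radii or load_covalent_radii()
    for el in (elem_a, elem_b):
        if el not in table:
            raise KeyError(f"element {el!r} not in the covalent radii table")
    (ra, sa), (rb, sb) = table[elem_a], table[elem_b]
    return ra + rb, (sa**2 + sb**2) ** 0.5


def donor_context_for(res_name: str, atom_name: str, element: str) -> str:
    """Infer the donor chemical context from residue and atom names."""
    ctx = _CONTEXT_MAP.get((res_name, atom_name))
    if ctx:
        return ctx
    return f"generic_{element}" if element in ("N", "O") else "generic_other"


@dataclass
class InteractionCall:
    metal: str
    donor_res: str
    donor_atom: str
    donor_element: str
    donor_context: str
    distance: float
    su: float
    label: str  # "covalent" | "weak" | "none"
    z_scores: Dict[str, float] = field(default_factory=dict)
    best_reference: Optional[ReferenceDistance] = None
    is_symmetry_mate: bool = False
    site_ref: Optional[tuple] = None


def _references_for(metal: str, donor_context: str, donor_element: str,
                    radii: Optional[dict], survey: Optional[Sequence[ReferenceDistance]]):
    refs = []
    if donor_element in (radii or load_covalent_radii()):
        mean, su = covalent_radius_sum(metal, donor_element, radii)
        refs.append(
            ReferenceDistance(metal, f"generic_{donor_element}", mean, su, "covalent_radii_sum")
        )
    for ref in load_survey_references(survey):
        if ref.metal == metal and ref.donor_context == donor_context:
            refs.append(ref)
    return refs


def classify_interaction(
    distance: float,
    su: float,
    metal: str = "Re",
    donor_context: str = "generic_N",
    donor_element: Optional[str] = None,
    k: float = 2.0,
    cap: float = 3.0,
    radii: Optional[dict] = None,
    survey: Optional[Sequence[ReferenceDistance]] = None,
) -> InteractionCall:
    """Classify one metal-donor distance as covalent, weak or none.

    Covalent when consistent (within k combined su) with the radius-sum
    reference *or* the matching survey reference; weak otherwise up to the
    hard cap; none beyond it.
    """
    if distance <= 0:
        raise ValueError(f"distance must be positive, got {distance}")
    if donor_element is None:
        donor_element = donor_context[-1] if donor_context[-1] in ("N", "O", "S") else "N"
    known_contexts = {"imidazole_N", "carboxylate_O", "amide_N", "generic_N", "generic_O"}
    if donor_context not in known_contexts:
        warnings.warn(f"unknown donor context {donor_context!r}; using generic reference")
        donor_context = f"generic_{donor_element}"
    refs = _references_for(metal, donor_context, donor_element, radii, survey)
    z_scores = {}
    best = None
    covalent = False
    for ref in refs:
        verdict = within_error(distance, su, ref.mean, ref.su, k=k)
        z_scores[ref.source] = verdict.z
        if best is None or verdict.z < z_scores.get(best.source, float("inf")):
            best = ref
        if verdict.consistent:
            covalent = True
    if distance > cap:
        label = "none"
    elif covalent:
        label = "covalent"
    else:
        label = "weak"
    return InteractionCall(
        metal=metal,
        donor_res="",
        donor_atom="",
        donor_element=donor_element,
        donor_context=donor_context,
        distance=distance,
        su=su,
        label=label,
        z_scores=z_scores,
        best_reference=best,
    )


def classify_structure(
    sites: Sequence[MetalSite],
    k: float = 2.0,
    cap: float = 3.0,
    protein_only: bool = True,
    radii: Optional[dict] = None,
    survey: Optional[Sequence[ReferenceDistance]] = None,
) -> List[InteractionCall]:
    """One interaction call per (site, donor) pair, ordered by residue number.

    Sites must carry distance standard uncertainties (attach a precision
    model first); missing sus are treated as zero.
    """
    calls = []
    for site in sites:
        ligands = site.protein_ligands() if protein_only else site.ligands
        for lig in ligands:
            ctx = donor_context_for(lig.atom.res_name, lig.atom.name, lig.atom.element)
            call = classify_interaction(
                distance=lig.distance,
                su=lig.su or 0.0,
                metal=site.metal.element,
                donor_context=ctx,
                donor_element=lig.atom.element,
                k=k,
                cap=cap,
                radii=radii,
                survey=survey,
            )
            call.donor_res = f"{lig.atom.res_name}{lig.atom.res_seq}"
            call.donor_atom = lig.atom.name
            call.is_symmetry_mate = lig.is_symmetry_mate
            call.site_ref = site.metal.residue_key
            calls.append(call)
    calls.sort(key=lambda c: (int("".join(ch for ch in c.donor_res if ch.isdigit()) or 0),
                              c.donor_atom))
    return calls


def calls_to_table(calls: Sequence[InteractionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "residue": c.donor_res,
            "donor_atom": c.donor_atom,
            "distance": round(c.distance, 3),
            "su": round(c.su, 4),
            "label": c.label,
            "reference": c.best_reference.source if c.best_reference else None,
            "reference_mean": c.best_reference.mean if c.best_reference else None,
        }
        for src, z in c.z_scores.items():
            row[f"z_{src}"] = round(z, 2)
        rows.append(row)
    return pd.DataFrame(rows)
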