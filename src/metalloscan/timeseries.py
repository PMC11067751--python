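"""Tracking of metal-site attributes across an isomorphous structure series.

Sites sharing a binding-residue key are merged into one trajectory over
the week labels; trends are summarised with the Kendall rank correlation
(tie-corrected tau-b), computed strictly within one wavelength group since
anomalous peak heights are not comparable across wavelengths. No
structural superposition is performed anywhere: the comparisons assume
isomorphous cells, guarded by a cell-deviation warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .covalency import InteractionCall, calls_to_table
from .metal_coordination import MetalSite
from .ring_stacking import RingNetwork
from .structure_io import Structure

__all__ = [
    "SitePoint",
    "SiteTrajectory",
    "TrendSummary",
    "match_sites",
    "trend",
    "residue_shift",
    "build_report",
    "check_isomorphous",
]

ISOMORPHISM_TOLERANCE = 0.02  # max relative cell deviation before warning
POSITION_MATCH_RADIUS = 1.5  # Angstrom, fallback matching for residue-free metals


@dataclass
class SitePoint:
    week: float
    wavelength: float
    occupancy: float
    peak_height: Optional[float] = None
    residual_density: Optional[float] = None
    distance: Optional[float] = None
    distance_su: Optional[float] = None
    label: Optional[str] = None


@dataclass
class SiteTrajectory:
    site_key: tuple  # (chain, res_seq, res_name) of the binding residue
    points: List[SitePoint] = field(default_factory=list)

    def sorted_points(self) -> List[SitePoint]:
        return sorted(self.points, key=lambda p: (p.week, p.wavelength))

    def wavelength_groups(self) -> Dict[float, List[SitePoint]]:
        groups: Dict[float, List[SitePoint]] = {}
        for p in self.sorted_points():
            groups.setdefault(p.wavelength, []).append(p)
        return groups


@dataclass(frozen=True)
class TrendSummary:
    attribute: str
    kendall_tau: float
    n: int
    direction: str  # increasing | decreasing | flat

    def __post_init__(self):
        if not (np.isnan(self.kendall_tau) or abs(self.kendall_tau) <= 1):
            raise ValueError(f"|tau| must be <= 1, got {self.kendall_tau}")


def check_isomorphous(structures: Sequence[Structure]) -> float:
    """Warn when cells deviate by more than the isomorphism tolerance."""
    cells = np.array(
        [[s.cell.a, s.cell.b, s.cell.c, s.cell.alpha, s.cell.beta, s.cell.gamma]
         for s in structures]
    )
    ref = cells[0]
    dev = float(np.max(np.abs(cells - ref) / ref))
    if dev > ISOMORPHISM_TOLERANCE:
        warnings.warn(
            f"cells deviate by up to {dev:.1%}; structures may not be isomorphous "
            "and direct coordinate comparison is unsafe"
        )
    return dev


def _site_key(site: MetalSite) -> Optional[tuple]:
    return site.primary_residue


def match_sites(
    analyses: Sequence[dict],
) -> List[SiteTrajectory]:
    """Merge per-structure site lists into trajectories.

    ``analyses`` is a list of dicts with keys ``structure``, ``sites``,
    ``week``, ``wavelength``, and optionally ``calls`` (interaction calls).
    Sites sharing a binding-residue key merge; metals with no protein donor
    are matched by position within 1.5 Angstrom (isomorphous assumption).
    """
    if len(analyses) < 2:
        raise ValueError("need at least two analysed structures to build trajectories")
    check_isomorphous([a["structure"] for a in analyses])

    trajectories: Dict[tuple, SiteTrajectory] = {}
    positional: List[tuple] = []  # (position, key) for residue-free sites

    for entry in analyses:
        week = entry["week"]
        wavelength = entry["wavelength"]
        calls_by_site = {}
        for call in entry.get("calls", []):
            calls_by_site.setdefault(call.site_ref, []).append(call)
        for site in entry["sites"]:
            key = _site_key(site)
            if key is None:
                pos = site.metal.pos
                key = next(
                    (k for p, k in positional if np.linalg.norm(p - pos) <= POSITION_MATCH_RADIUS),
                    None,
                )
                if key is None:
                    key = ("", 0, f"XYZ_{pos[0]:.1f}_{pos[1]:.1f}_{pos[2]:.1f}")
                    positional.append((pos, key))
            traj = trajectories.setdefault(key, SiteTrajectory(site_key=key))
            if any(p.week == week and p.wavelength == wavelength for p in traj.points):
                raise ValueError(
                    f"duplicate point (week={week}, wavelength={wavelength}) for site {key}"
                )
            prot = sorted(site.protein_ligands(), key=lambda l: l.distance)
            primary = prot[0] if prot else None
            site_calls = calls_by_site.get(site.metal.residue_key, [])
            label = None
            if site_calls and primary is not None:
                for c in site_calls:
                    if c.donor_atom == primary.atom.name:
                        label = c.label
                        break
            traj.points.append(
                SitePoint(
                    week=week,
                    wavelength=wavelength,
                    occupancy=site.occupancy,
                    peak_height=site.peak_height,
                    residual_density=site.residual_density,
                    distance=primary.distance if primary else None,
                    distance_su=primary.su if primary else None,
                    label=label,
                )
            )
    return sorted(trajectories.values(), key=lambda t: (t.site_key[1], t.site_key))


def trend(values: Sequence[float], weeks: Sequence[float], attribute: str = "value") -> TrendSummary:
    """Kendall rank correlation of an attribute against time.

    Fewer than three points gives a no-trend summary (tau = nan, flat).
    """
    pairs = [(w, v) for w, v in zip(weeks, values) if v is not None and not np.isnan(v)]
    if len(pairs) < 3:
        return TrendSummary(attribute=attribute, kendall_tau=float("nan"), n=len(pairs),
                            direction="flat")
    w, v = zip(*pairs)
    if len(set(v)) == 1:
        tau = 0.0
    else:
        tau = float(sps.kendalltau(w, v).statistic)
    if np.isnan(tau):
        tau = 0.0
    direction = "flat" if tau == 0 else ("increasing" if tau > 0 else "decreasing")
    return TrendSummary(attribute=attribute, kendall_tau=tau, n=len(pairs), direction=direction)


def trajectory_trends(trajectories: Sequence[SiteTrajectory]) -> List[dict]:
    """Per-site, per-wavelength trends of occupancy and peak height."""
    out = []
    for traj in trajectories:
        for wl, points in traj.wavelength_groups().items():
            weeks = [p.week for p in points]
            for attr in ("occupancy", "peak_height"):
                vals = [getattr(p, attr) for p in points]
                summary = trend(
                    [v if v is not None else np.nan for v in vals], weeks, attribute=attr
                )
                out.append(
                    {
                        "site": f"{traj.site_key[2]}{traj.site_key[1]}",
                        "wavelength": wl,
                        "attribute": attr,
                        "kendall_tau": summary.kendall_tau,
                        "n": summary.n,
                        "direction": summary.direction,
                    }
                )
    return out


def residue_shift(struct_a: Structure, struct_b: Structure, residue_key: tuple) -> dict:
    """Atom displacements of one residue between two isomorphous structures.

    Computed on shared atom names in the common crystal frame (no
    superposition). Returns max/mean displacement and a per-atom table.
    """
    check_isomorphous([struct_a, struct_b])
    atoms_a = {a.name: a for a in struct_a.atoms_of_residue(residue_key) if not a.altloc or a.altloc == "A"}
    atoms_b = {a.name: a for a in struct_b.atoms_of_residue(residue_key) if not a.altloc or a.altloc == "A"}
    if not atoms_a or not atoms_b:
        raise ValueError(f"residue {residue_key} absent from one of the structures")
    shared = sorted(set(atoms_a) & set(atoms_b))
    if not shared:
        raise ValueError(f"residue {residue_key} has no shared atom names")
    rows = []
    for name in shared:
        d = float(np.linalg.norm(atoms_a[name].pos - atoms_b[name].pos))
        rows.append({"atom": name, "displacement": d})
    table = pd.DataFrame(rows)
    return {
        "max_displacement": float(table["displacement"].max()),
        "mean_displacement": float(table["displacement"].mean()),
        "per_atom": table,
        "missing_in_a": sorted(set(atoms_b) - set(atoms_a)),
        "missing_in_b": sorted(set(atoms_a) - set(atoms_b)),
    }


def build_report(
    trajectories: Sequence[SiteTrajectory],
    trends: Sequence[dict],
    out_dir,
    cages: Optional[RingNetwork] = None,
    calls: Optional[Sequence[InteractionCall]] = None,
    config: Optional[dict] = None,
) -> dict:
    """Write the report bundle (deterministic file names and ordering).

    Emits occupancy/peak tables per site x time point, a distance table,
    the ring-cage table and a JSON summary with trends.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    occ_rows = []
    dist_rows = []
    for traj in trajectories:
        site = f"{traj.site_key[2]}{traj.site_key[1]}"
        for p in traj.sorted_points():
            occ_rows.append(
                {
                    "site": site,
                    "week": p.week,
                    "wavelength": p.wavelength,
                    "occupancy": p.occupancy,
                    "peak_height": p.peak_height,
                    "residual_density": p.residual_density,
                }
            )
            if p.distance is not None:
                dist_rows.append(
                    {
                        "site": site,
                        "week": p.week,
                        "wavelength": p.wavelength,
                        "distance": round(p.distance, 3),
                        "su": round(p.distance_su, 4) if p.distance_su is not None else None,
                        "label": p.label,
                    }
                )
    occ_df = pd.DataFrame(occ_rows)
    dist_df = pd.DataFrame(dist_rows)
    occ_df.to_csv(out_dir / "site_occupancies.csv", index=False)
    dist_df.to_csv(out_dir / "site_distances.csv", index=False)
    if cages is not None:
        cages.to_table().to_csv(out_dir / "ring_cages.csv", index=False)
    if calls is not None:
        calls_to_table(list(calls)).to_csv(out_dir / "interaction_calls.csv", index=False)

    summary = {
        "n_trajectories": len(trajectories),
        "sites": [f"{t.site_key[2]}{t.site_key[1]}" for t in trajectories],
        "trends": sorted(
            ({k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in t.items()}
             for t in trends),
            key=lambda t: (t["site"], t["wavelength"] or 0, t["attribute"]),
        ),
        "config": config or {},
    }
    with open(out_dir / "series_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
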