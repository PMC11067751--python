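"""High-level orchestration: single-structure and series analyses.

These functions chain the stages — parse, metal-site detection, precision
attachment, covalency classification, ring network — and are what both the
command-line interface and the example scripts call.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

from . import covalency, metal_coordination as mc, ring_stacking, timeseries
from .precision import DpiVariant, RefinementStats, precision_model_from_stats
from .structure_io import Structure, parse_structure

__all__ = ["RunConfig", "load_manifest", "analyze_structure", "analyze_series", "StructureAnalysis"]


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, echoed into every report."""

    coordination_cutoff: float = 3.0  # Angstrom, metal-donor sphere
    contact_cutoff: float = 4.0  # Angstrom, crystal contacts
    ring_network_cutoff: float = 5.5  # Angstrom, centroid-centroid
    peak_match_radius: float = 1.0  # Angstrom, peak-to-site assignment
    k: float = 2.0  # within-error multiplier
    dpi_variant: str = DpiVariant.cruickshank_rfree.value
    criteria: str = "small_molecule"  # stacking criteria set
    metal_elements: tuple = ("Re",)
    seed: int = 0

    def __post_init__(self):
        for name in ("coordination_cutoff", "contact_cutoff", "ring_network_cutoff",
                     "peak_match_radius", "k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config value {name} must be positive")

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}


@dataclass
class StructureAnalysis:
    structure: Structure
    sites: list
    calls: list
    ring_network: ring_stacking.RingNetwork
    week: Optional[float] = None
    wavelength: Optional[float] = None


def _stats_from_dict(d: dict) -> RefinementStats:
    return RefinementStats(
        n_atoms=int(d["n_atoms"]),
        n_reflections=int(d["n_reflections"]),
        completeness=float(d["completeness"]),
        r_factor=float(d["r_factor"]),
        r_free=float(d["r_free"]),
        d_min=float(d["d_min"]),
        n_params=d.get("n_params"),
        avg_b=d.get("avg_b"),
    )


def load_manifest(path) -> list:
    """Read a series manifest (JSON or TOML) into entry dicts.

    Each entry: path, week, wavelength, optional label / peaks /
    stats{n_atoms, n_reflections, completeness, r_factor, r_free, d_min}.
    Relative paths are resolved against the manifest location.
    """
    path = Path(path)
    if path.suffix.lower() == ".toml":
        data = tomllib.loads(path.read_text())
    else:
        data = json.loads(path.read_text())
    entries = data["series"] if isinstance(data, dict) else data
    out = []
    for e in entries:
        entry = dict(e)
        entry["path"] = (path.parent / e["path"]).resolve()
        if e.get("peaks"):
            entry["peaks"] = (path.parent / e["peaks"]).resolve()
        out.append(entry)
    return out


def analyze_structure(
    structure_or_path,
    stats: Optional[RefinementStats] = None,
    peaks_path=None,
    config: Optional[RunConfig] = None,
    meta: Optional[dict] = None,
) -> StructureAnalysis:
    """Run the per-structure pipeline: sites, precision, covalency, rings."""
    config = config or RunConfig()
    if isinstance(structure_or_path, Structure):
        structure = structure_or_path
    else:
        structure = parse_structure(structure_or_path, meta=meta)
    if isinstance(stats, dict):
        stats = _stats_from_dict(stats)
    sites = mc.find_metal_sites(
        structure,
        metal_elements=set(config.metal_elements),
        cutoff=config.coordination_cutoff,
    )
    model = None
    if stats is not None:
        structure.stats = stats
        model = precision_model_from_stats(stats, DpiVariant(config.dpi_variant))
        mc.attach_precision(sites, model)
    if peaks_path is not None:
        peaks = mc.read_peak_list(peaks_path, structure)
        mc.associate_peaks(sites, peaks, structure, match_radius=config.peak_match_radius)
    calls = covalency.classify_structure(sites, k=config.k)
    network = ring_stacking.find_ring_network(
        structure,
        max_distance=config.ring_network_cutoff,
        precision_model=model,
        criteria=config.criteria,
    )
    return StructureAnalysis(
        structure=structure,
        sites=sites,
        calls=calls,
        ring_network=network,
        week=structure.meta.get("week_label"),
        wavelength=structure.meta.get("wavelength"),
    )


def analyze_series(
    manifest_path,
    config: Optional[RunConfig] = None,
    out_dir=None,
) -> dict:
    """Analyse every structure in a manifest and build the series report."""
    config = config or RunConfig()
    entries = load_manifest(manifest_path)
    if len(entries) < 2:
        raise ValueError("a series needs at least two manifest entries")
    analyses: List[dict] = []
    per_structure: List[StructureAnalysis] = []
    for entry in entries:
        res = analyze_structure(
            entry["path"],
            stats=entry.get("stats"),
            peaks_path=entry.get("peaks"),
            config=config,
            meta={"week_label": entry["week"], "wavelength": entry["wavelength"],
                  "source_label": entry.get("label", "")},
        )
        per_structure.append(res)
        analyses.append(
            {
                "structure": res.structure,
                "sites": res.sites,
                "calls": res.calls,
                "week": entry["week"],
                "wavelength": entry["wavelength"],
            }
        )
    trajectories = timeseries.match_sites(analyses)
    trends = timeseries.trajectory_trends(trajectories)
    summary = None
    if out_dir is not None:
        # the ring network of the last (most evolved) structure is reported
        summary = timeseries.build_report(
            trajectories,
            trends,
            out_dir,
            cages=per_structure[-1].ring_network,
            calls=[c for a in analyses for c in a["calls"]],
            config=config.to_dict(),
        )
    return {
        "analyses": per_structure,
        "trajectories": trajectories,
        "trends": trends,
        "summary": summary,
    }
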