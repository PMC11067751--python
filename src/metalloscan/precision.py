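"""Coordinate-precision estimates and error propagation.

The Cruickshank diffraction precision index (DPI) turns global refinement
statistics into an average positional standard uncertainty:

    DPI(R_free) = sqrt(N_atoms / N_refl) * C^(-1/3) * R_free * d_min
    DPI(R)      = sqrt(N_atoms / (N_refl - N_params)) * C^(-1/3) * R * d_min

with completeness C as a fraction and d_min the resolution limit in
Angstrom. Bond-distance uncertainties combine two positional uncertainties
in quadrature, and two distances are "equal within error" when they differ
by less than k combined standard uncertainties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

__all__ = [
    "RefinementStats",
    "PrecisionModel",
    "DpiVariant",
    "cruickshank_dpi",
    "atom_su",
    "distance_su",
    "within_error",
    "WithinErrorVerdict",
    "su_bracket",
    "format_distance_with_su",
]


class DpiVariant(str, Enum):
    cruickshank_r = "cruickshank_r"
    cruickshank_rfree = "cruickshank_rfree"


@dataclass(frozen=True)
class RefinementStats:
    """Global refinement statistics, as printed in a data-collection table."""

    n_atoms: int
    n_reflections: int
    completeness: float  # fraction in (0, 1]
    r_factor: float
    r_free: float
    d_min: float  # Angstrom
    n_params: Optional[int] = None
    avg_b: Optional[float] = None

    def __post_init__(self):
        if not 0 < self.completeness <= 1:
            raise ValueError(f"completeness must be in (0,1], got {self.completeness}")
        if not 0 < self.r_free < 1:
            raise ValueError(f"r_free must be in (0,1), got {self.r_free}")
        if self.d_min <= 0:
            raise ValueError(f"d_min must be positive, got {self.d_min}")
        if self.n_reflections <= self.n_atoms:
            raise ValueError(
                f"n_reflections ({self.n_reflections}) must exceed n_atoms ({self.n_atoms})"
            )


@dataclass(frozen=True)
class PrecisionModel:
    dpi: float  # Angstrom
    variant: DpiVariant = DpiVariant.cruickshank_rfree
    per_atom_scaling: bool = False
    avg_b: Optional[float] = None

    def __post_init__(self):
        if self.dpi <= 0:
            raise ValueError(f"dpi must be positive, got {self.dpi}")


def cruickshank_dpi(
    stats: RefinementStats, variant: DpiVariant = DpiVariant.cruickshank_rfree
) -> float:
    """Cruickshank DPI in Angstrom for the given variant."""
    variant = DpiVariant(variant)
    comp = stats.completeness ** (-1.0 / 3.0)
    if variant is DpiVariant.cruickshank_rfree:
        return math.sqrt(stats.n_atoms / stats.n_reflections) * comp * stats.r_free * stats.d_min
    if stats.n_params is None:
        raise ValueError("the R-factor DPI variant requires n_params")
    dof = stats.n_reflections - stats.n_params
    if dof <= 0:
        raise ValueError(
            f"n_reflections ({stats.n_reflections}) must exceed n_params ({stats.n_params})"
        )
    return math.sqrt(stats.n_atoms / dof) * comp * stats.r_factor * stats.d_min


def precision_model_from_stats(
    stats: RefinementStats,
    variant: DpiVariant = DpiVariant.cruickshank_rfree,
    per_atom_scaling: bool = False,
) -> PrecisionModel:
    return PrecisionModel(
        dpi=cruickshank_dpi(stats, variant),
        variant=DpiVariant(variant),
        per_atom_scaling=per_atom_scaling,
        avg_b=stats.avg_b,
    )


def atom_su(model: PrecisionModel, atom=None, avg_b: Optional[float] = None) -> float:
    """Positional standard uncertainty of one atom under the model.

    With ``per_atom_scaling`` off every atom gets the DPI; with it on the
    DPI is scaled by sqrt(B / <B>).
    """
    if not model.per_atom_scaling or atom is None:
        return model.dpi
    avg = avg_b if avg_b is not None else model.avg_b
    if avg is None or avg <= 0:
        raise ValueError("per-atom scaling requires a positive average B factor")
    return model.dpi * math.sqrt(atom.b_factor / avg)


def distance_su(su_a: float, su_b: float) -> float:
    """Combine two positional uncertainties in quadrature."""
    if su_a < 0 or su_b < 0:
        raise ValueError("standard uncertainties must be non-negative")
    return math.hypot(su_a, su_b)


@dataclass(frozen=True)
class WithinErrorVerdict:
    consistent: bool
    z: float
    delta: float
    combined_su: float

    @property
    def label(self) -> str:
        return "consistent" if self.consistent else "inconsistent"


def within_error(
    d_obs: float, su_obs: float, d_ref: float, su_ref: float, k: float = 2.0
) -> WithinErrorVerdict:
    """Are two distances equal within k combined standard uncertainties?

    Symmetric in (obs, ref). With both uncertainties zero the verdict is
    exact equality (infinite z on any difference).
    """
    if su_obs < 0 or su_ref < 0:
        raise ValueError("standard uncertainties must be non-negative")
    delta = abs(d_obs - d_ref)
    combined = distance_su(su_obs, su_ref)
    if combined == 0:
        z = 0.0 if delta == 0 else math.inf
    else:
        z = delta / combined
    return WithinErrorVerdict(consistent=z <= k, z=z, delta=delta, combined_su=combined)


def su_bracket(su: float) -> tuple:
    """Round an su to one significant digit.

    Returns ``(digit, decimals)`` for the crystallographic bracket
    convention, e.g. 0.0368 -> (4, 2), printed as "(4)" on a value quoted
    to 2 decimals.
    """
    if su <= 0:
        raise ValueError(f"su must be positive, got {su}")
    decimals = -math.floor(math.log10(su))
    digit = round(su * 10**decimals)
    if digit == 10:  # rounding rolled over to the next decade
        digit = 1
        decimals -= 1
    return digit, decimals


def format_distance_with_su(value: float, su: float) -> str:
    """Crystallographic bracket notation, e.g. (2.28, 0.0368) -> "2.28 (4)"."""
    digit, decimals = su_bracket(su)
    return f"{value:.{max(decimals, 0)}f} ({digit})"
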