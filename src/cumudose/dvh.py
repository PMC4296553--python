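"""Cumulative dose-volume histograms and D90 / D2cc parameter extraction.

Two ways of combining treatment components are supported:

* *accumulated*: DVH parameters read off the voxel-wise cumulative EQD2
  grid produced by registration-based dose accumulation;
* *simple addition*: per-component D90 / D2cc values summed directly, the
  GEC-ESTRO convention that implicitly assumes hot (and cold) spots occupy
  the same anatomy in every component.

When components are not perfectly co-located, simple addition tends to
overestimate the near-maximum OAR parameter D2cc and underestimate the
near-minimum target parameter D90 relative to true voxel-wise accumulation;
`compare_methods` exposes the signed differences used to test that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, EmptyStructureError, FrameError, UnitError
from .grids import GY_EQD2, DoseGrid, StructureMask, volume_cc

__all__ = [
    "DVHCurve",
    "DVHParameters",
    "compute_dvh",
    "dose_at_volume",
    "dvh_parameters",
    "simple_parameter_addition",
    "compare_methods",
]


@dataclass
class DVHCurve:
    """Cumulative DVH for one structure.

    ``volume_at_or_above[i]`` is the absolute volume (cm³) receiving at
    least ``dose_edges[i]`` Gy.  ``dose_edges`` starts at 0, where the curve
    equals the total structure volume, and is non-increasing thereafter.
    The exact sorted per-voxel doses and the voxel volume are retained so
    dose-at-volume queries are computed from the voxel samples themselves
    rather than from the (possibly binned) display curve.
    """

    dose_edges: np.ndarray
    volume_at_or_above: np.ndarray
    structure: str
    total_volume_cc: float
    voxel_doses_sorted: np.ndarray = field(repr=False, default=None)
    voxel_volume_cc: float = 0.0

    def __post_init__(self) -> None:
        self.dose_edges = np.asarray(self.dose_edges, dtype=float)
        self.volume_at_or_above = np.asarray(self.volume_at_or_above, dtype=float)
        if np.any(np.diff(self.dose_edges) < 0):
            raise DomainError("dose_edges must be non-decreasing")
        if np.any(np.diff(self.volume_at_or_above) > 1e-12):
            raise DomainError("volume_at_or_above must be non-increasing")


@dataclass(frozen=True)
class DVHParameters:
    """The dose-volume parameters reported per structure and method."""

    d90: float
    d2cc: float
    dmean: float
    dmax: float
    structure: str = ""
    method: str = "DIR_accumulated"  # or "simple_addition"

    def __post_init__(self) -> None:
        if min(self.d90, self.d2cc, self.dmean, self.dmax) < 0:
            raise DomainError("DVH parameters must be non-negative")
        if self.d90 > self.dmax + 1e-9 or self.d2cc > self.dmax + 1e-9:
            raise DomainError("D90/D2cc cannot exceed Dmax")


def compute_dvh(
    dose: DoseGrid, mask: StructureMask, bin_width: float = 0.1
) -> DVHCurve:
    """Cumulative DVH of ``dose`` over ``mask`` (shared geometry required).

    Every occupied voxel contributes its full voxel volume (no fractional
    boundary supersampling).  ``bin_width`` (Gy) controls only the exported
    curve resolution; parameter queries use the exact voxel doses.
    """
    if not dose.geometry.same_lattice(mask.geometry):
        raise FrameError("dose and mask must share one lattice")
    if bin_width <= 0:
        raise DomainError("bin_width must be positive")
    doses = dose.values[mask.occupancy]
    if doses.size == 0:
        raise EmptyStructureError(f"structure {mask.label!r} has no voxels")
    v_mm3 = mask.geometry.voxel_volume_mm3
    v_vox = v_mm3 / 1000.0
    # same operation order as volume_cc so the dose-0 volume matches exactly
    total = doses.size * v_mm3 / 1000.0
    dmax = float(doses.max())
    edges = np.arange(0.0, dmax + 2 * bin_width, bin_width)
    # volume receiving >= edge
    counts = np.searchsorted(np.sort(doses), edges, side="left")
    vol = (doses.size - counts) * v_mm3 / 1000.0
    vol[0] = total  # dose 0 edge: every voxel receives >= 0
    return DVHCurve(
        dose_edges=edges,
        volume_at_or_above=vol,
        structure=mask.label,
        total_volume_cc=total,
        voxel_doses_sorted=np.sort(doses)[::-1],  # descending
        voxel_volume_cc=v_vox,
    )


def dose_at_volume(
    curve: DVHCurve,
    percent: float | None = None,
    cc: float | None = None,
) -> float:
    """D_x: minimum dose received by the hottest x volume of the structure.

    Exactly one of ``percent`` (D90 → ``percent=90``) or ``cc``
    (D2cc → ``cc=2``) must be given.  Defined as the largest dose d with
    volume(≥ d) ≥ x, evaluated on the sorted voxel doses with linear
    interpolation between adjacent cumulative-volume samples; ties resolve
    toward the higher dose.  Requested volumes above the structure volume
    are a domain error.
    """
    if (percent is None) == (cc is None):
        raise DomainError("specify exactly one of percent= or cc=")
    target = curve.total_volume_cc * percent / 100.0 if percent is not None else cc
    if target < 0 or target > curve.total_volume_cc + 1e-12:
        raise DomainError(
            f"requested volume {target:.3f} cm3 exceeds structure volume "
            f"{curve.total_volume_cc:.3f} cm3"
        )
    d = curve.voxel_doses_sorted
    if d is None:
        raise DomainError("curve lacks voxel samples for exact queries")
    v = curve.voxel_volume_cc
    # cumulative volume after k voxels is k*v; invert with linear interpolation
    k = target / v
    if k <= 1.0:
        return float(d[0])
    k_lo = int(np.floor(k))
    if k_lo >= d.size:
        return float(d[-1])
    frac = k - k_lo
    return float(d[k_lo - 1] + frac * (d[k_lo] - d[k_lo - 1]))


def dvh_parameters(
    dose: DoseGrid,
    mask: StructureMask,
    method: str = "DIR_accumulated",
    d2cc_cc: float = 2.0,
) -> DVHParameters:
    """D90, D2cc, Dmean and Dmax for one structure on one (EQD2) dose grid.

    Structures smaller than the D2cc query volume raise rather than guess.
    """
    if dose.unit != GY_EQD2:
        raise UnitError("DVH parameters are reported in Gy_EQD2")
    curve = compute_dvh(dose, mask)
    if curve.total_volume_cc < d2cc_cc:
        raise DomainError(
            f"structure {mask.label!r} ({curve.total_volume_cc:.2f} cm3) is "
            f"smaller than the {d2cc_cc} cm3 query volume"
        )
    doses = dose.values[mask.occupancy]
    return DVHParameters(
        d90=dose_at_volume(curve, percent=90.0),
        d2cc=dose_at_volume(curve, cc=d2cc_cc),
        dmean=float(doses.mean()),
        dmax=float(doses.max()),
        structure=mask.label,
        method=method,
    )


def simple_parameter_addition(components: list[DVHParameters]) -> DVHParameters:
    """Sum per-component DVH parameters (the simple-addition convention).

    All components must describe the same structure on the EQD2 scale; the
    result is tagged ``simple_addition``.  Dmean/Dmax sum likewise (their
    sums are upper bounds of the accumulated values).
    """
    if not components:
        raise DomainError("need at least one component")
    structures = {c.structure for c in components}
    if len(structures) > 1:
        raise UnitError(f"components describe different structures: {structures}")
    return DVHParameters(
        d90=sum(c.d90 for c in components),
        d2cc=sum(c.d2cc for c in components),
        dmean=sum(c.dmean for c in components),
        dmax=sum(c.dmax for c in components),
        structure=components[0].structure,
        method="simple_addition",
    )


def compare_methods(
    accumulated: DVHParameters, added: DVHParameters
) -> dict[str, float]:
    """Signed differences (simple addition − accumulation) per parameter."""
    if accumulated.method == added.method:
        raise DomainError("compare_methods expects one result per method")
    return {
        "d90": added.d90 - accumulated.d90,
        "d2cc": added.d2cc - accumulated.d2cc,
        "dmean": added.dmean - accumulated.dmean,
        "dmax": added.dmax - accumulated.dmax,
    }
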