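"""Regular 3-D lattices with world geometry: dose grids and structure masks.

Conventions used throughout the package:

* Arrays are indexed ``values[ix, iy, iz]`` with shape ``(nx, ny, nz)``.
* World coordinates are in millimetres.  The world position of voxel
  ``(i, j, k)`` is ``origin + (i, j, k) * spacing`` — i.e. ``origin`` is the
  *center* of voxel ``(0, 0, 0)`` and indices are 0-based.
* Grids are axis-aligned; oblique lattices are out of scope.
* Volumes are reported in cm³ with 1 cm³ = 1000 mm³.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

from .errors import DomainError, FrameError, GeometryError

__all__ = [
    "GridGeometry",
    "DoseGrid",
    "StructureMask",
    "resample",
    "volume_cc",
    "GY_PHYSICAL",
    "GY_EQD2",
]

GY_PHYSICAL = "Gy_physical"
GY_EQD2 = "Gy_EQD2"

StructureLabel = Literal["HR-CTV", "rectum", "bladder", "bone", "other"]


@dataclass(frozen=True)
class GridGeometry:
    """Axis-aligned regular lattice embedded in a named world frame.

    Parameters
    ----------
    origin:
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    spacing:
        Per-axis voxel edge length in mm; strictly positive.
    shape:
        Voxel counts per axis, each ≥ 1.
    frame_id:
        Opaque label naming the coordinate frame (e.g. ``"ICBT1"``).
        Cross-frame operations outside the registration stage refuse to mix
        frames.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]
    frame_id: str = "unknown"

    def __post_init__(self) -> None:
        origin = tuple(float(v) for v in self.origin)
        spacing = tuple(float(v) for v in self.spacing)
        shape = tuple(int(v) for v in self.shape)
        if len(origin) != 3 or len(spacing) != 3 or len(shape) != 3:
            raise GeometryError("origin, spacing and shape must be 3-vectors")
        if any(s <= 0 for s in spacing):
            raise GeometryError(f"spacing must be strictly positive, got {spacing}")
        if any(n < 1 for n in shape):
            raise GeometryError(f"shape must be >= 1 per axis, got {shape}")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "shape", shape)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape ``(nx, ny, nz, 3)``."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        grid = np.meshgrid(*axes, indexing="ij")
        return np.stack(grid, axis=-1)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (…, 3) to continuous voxel indices (…, 3)."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def same_lattice(self, other: "GridGeometry") -> bool:
        """True when origin, spacing and shape agree (frame label ignored)."""
        return (
            np.allclose(self.origin, other.origin)
            and np.allclose(self.spacing, other.spacing)
            and self.shape == other.shape
        )

    def with_frame(self, frame_id: str) -> "GridGeometry":
        return replace(self, frame_id=frame_id)


def _check_values(geometry: GridGeometry, values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values)
    if arr.shape != geometry.shape:
        raise GeometryError(
            f"values shape {arr.shape} does not match geometry shape {geometry.shape}"
        )
    return arr


@dataclass
class DoseGrid:
    """Scalar dose on a lattice, tagged as physical Gy or Gy_EQD2.

    ``n_fractions`` is the number of equal fractions over which ``values``
    was delivered; it drives the per-voxel fraction dose d(v) = D(v)/n in
    the linear-quadratic conversion.
    """

    geometry: GridGeometry
    values: np.ndarray
    unit: str = GY_PHYSICAL
    n_fractions: int = 1
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = _check_values(self.geometry, self.values).astype(float, copy=False)
        if self.unit not in (GY_PHYSICAL, GY_EQD2):
            raise DomainError(f"unknown dose unit {self.unit!r}")
        if self.n_fractions < 1:
            raise DomainError("n_fractions must be >= 1")
        if np.any(self.values < 0):
            raise DomainError("dose values must be non-negative")


@dataclass
class StructureMask:
    """Binary occupancy on a lattice for one anatomical structure."""

    geometry: GridGeometry
    occupancy: np.ndarray
    label: str = "other"

    def __post_init__(self) -> None:
        self.occupancy = _check_values(self.geometry, self.occupancy).astype(bool)

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.occupancy))


def volume_cc(mask: StructureMask) -> float:
    """Structure volume in cm³: occupied-voxel count × voxel volume / 1000."""
    return mask.voxel_count * mask.geometry.voxel_volume_mm3 / 1000.0


def sample_at_points(
    values: np.ndarray,
    geometry: GridGeometry,
    points: np.ndarray,
    order: int = 1,
) -> np.ndarray:
    """Interpolate ``values`` at world-mm ``points`` (…, 3).

    Trilinear for ``order=1``, nearest-neighbor for ``order=0``.  Points
    outside the grid extent return 0 (background / unknown dose).
    """
    idx = geometry.world_to_index(points)
    # snap coordinates within 1e-6 voxel of the lattice boundary onto it:
    # map_coordinates treats even infinitesimally outside points as
    # background, which would corrupt identity-like transforms
    upper = np.asarray(geometry.shape, dtype=float) - 1.0
    clipped = np.clip(idx, 0.0, upper)
    idx = np.where(np.abs(idx - clipped) <= 1e-6, clipped, idx)
    coords = np.moveaxis(idx, -1, 0)
    return ndimage.map_coordinates(
        np.asarray(values, dtype=float), coords, order=order, mode="constant", cval=0.0
    )


def resample(
    grid: "DoseGrid | StructureMask",
    target: GridGeometry,
    interpolation: str = "trilinear",
):
    """Resample a dose grid or mask onto ``target`` geometry (same frame).

    Dose grids use trilinear interpolation of values at the target voxel
    centers.  Masks use nearest-neighbor by default, or trilinear followed
    by a 0.5 threshold when ``interpolation="trilinear"`` is requested.
    Moving data *between* frames is the registration module's job; the
    source and target frame ids must agree here.
    """
    if interpolation not in ("trilinear", "nearest"):
        raise DomainError(f"unknown interpolation {interpolation!r}")
    if grid.geometry.frame_id != target.frame_id:
        raise FrameError(
            f"cannot resample across frames "
            f"({grid.geometry.frame_id!r} -> {target.frame_id!r}); register instead"
        )
    if grid.geometry.same_lattice(target):
        # Identity case: bitwise-equal copy on the target geometry object.
        if isinstance(grid, DoseGrid):
            return DoseGrid(target, grid.values.copy(), grid.unit, grid.n_fractions,
                            list(grid.provenance))
        return StructureMask(target, grid.occupancy.copy(), grid.label)

    points = target.voxel_centers()
    if isinstance(grid, DoseGrid):
        vals = sample_at_points(grid.values, grid.geometry, points, order=1)
        return DoseGrid(target, vals, grid.unit, grid.n_fractions, list(grid.provenance))

    if interpolation == "nearest":
        occ = sample_at_points(grid.occupancy, grid.geometry, points, order=0) > 0.5
    else:
        occ = sample_at_points(grid.occupancy, grid.geometry, points, order=1) >= 0.5
    return StructureMask(target, occ, grid.label)
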