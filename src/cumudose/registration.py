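"""Rigid landmark fusion, demons-style deformable registration, and warping.

The spatial model is a backward (pull-back) one: a ``DeformationField`` on
the fixed frame stores, per fixed-frame voxel center x, a displacement
u(x) in mm such that the corresponding moving-frame point is x + u(x).
Warping then *samples* the moving volume at x + u(x), which is the natural
direction for dose accumulation (every reference voxel receives exactly one
interpolated value; no forward-splatting holes).

The deformable algorithm is a classical multi-resolution demons scheme:
iterative intensity matching under sum-of-squared-differences with Gaussian
regularization of both the update (fluid-like) and the accumulated field
(diffusion-like).  It is fully deterministic — no stochastic optimization.
The pipeline equally accepts externally supplied fields, which is how
known ground-truth deformations are injected in phantom experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateLandmarksError,
    FrameError,
    GeometryError,
    UnitError,
)
from .grids import (
    GY_EQD2,
    DoseGrid,
    GridGeometry,
    StructureMask,
    sample_at_points,
)

__all__ = [
    "RigidTransform",
    "DeformationField",
    "DIRSettings",
    "fit_rigid_landmarks",
    "register_demons",
    "compose",
    "warp_dose",
    "warp_mask",
    "warp_scalar",
]


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation mapping fixed-frame points to moving-frame points.

    ``apply(x) = R @ x + t``.  Used as a pull-back map: to bring a moving
    volume onto the fixed frame, sample it at ``apply(x)`` for each fixed
    voxel center x.
    """

    rotation: np.ndarray
    translation: np.ndarray
    fixed_frame: str = "fixed"
    moving_frame: str = "moving"
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise GeometryError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise GeometryError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise GeometryError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls, fixed_frame: str = "fixed", moving_frame: str = "moving"):
        return cls(np.eye(3), np.zeros(3), fixed_frame, moving_frame)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(
            Rinv, -Rinv @ self.translation, self.moving_frame, self.fixed_frame,
            self.residual_rms,
        )

    def is_identity(self, atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=atol)
            and np.allclose(self.translation, 0.0, atol=atol)
        )

    def as_field(self, geometry: GridGeometry) -> "DeformationField":
        """Sample the rigid map as a displacement field on ``geometry``."""
        x = geometry.voxel_centers()
        disp = self.apply(x.reshape(-1, 3)).reshape(x.shape) - x
        return DeformationField(geometry, disp)


@dataclass
class DeformationField:
    """Per-voxel mm displacement on the fixed frame (pull-back convention)."""

    geometry: GridGeometry
    displacement: np.ndarray

    def __post_init__(self) -> None:
        disp = np.asarray(self.displacement, dtype=float)
        if disp.shape != self.geometry.shape + (3,):
            raise GeometryError(
                f"displacement shape {disp.shape} must be geometry shape + (3,)"
            )
        if not np.all(np.isfinite(disp)):
            raise GeometryError("displacement must be finite")
        self.displacement = disp

    @classmethod
    def identity(cls, geometry: GridGeometry) -> "DeformationField":
        return cls(geometry, np.zeros(geometry.shape + (3,)))

    @property
    def max_displacement_mm(self) -> float:
        """Largest displacement magnitude, reported for QC."""
        return float(np.sqrt((self.displacement ** 2).sum(axis=-1)).max())

    def mapped_points(self) -> np.ndarray:
        """x + u(x) for every fixed voxel center, shape (nx, ny, nz, 3)."""
        return self.geometry.voxel_centers() + self.displacement


@dataclass(frozen=True)
class DIRSettings:
    """Demons optimization settings.

    pyramid_levels / iterations:
        Coarse-to-fine downsampling factors are 2**(level) with
        ``iterations[i]`` demons sweeps at each level (len == pyramid_levels).
    update_sigma_mm / field_sigma_mm:
        Gaussian widths (mm) smoothing the per-iteration update (fluid
        regularization) and the accumulated field (diffusion regularization).
    step_cap_mm:
        Maximum displacement added per iteration; keeping it at or below the
        voxel spacing is the invertibility heuristic.
    tolerance_mm:
        Convergence threshold on the mean update magnitude.
    """

    pyramid_levels: int = 3
    iterations: tuple[int, ...] = (50, 30, 10)
    update_sigma_mm: float = 3.0
    field_sigma_mm: float = 2.0
    step_cap_mm: float = 2.0
    tolerance_mm: float = 1e-3

    def __post_init__(self) -> None:
        if self.pyramid_levels < 1 or len(self.iterations) != self.pyramid_levels:
            raise GeometryError("iterations must list one count per pyramid level")
        if min(self.iterations) < 1:
            raise GeometryError("iteration counts must be positive")
        if min(self.update_sigma_mm, self.field_sigma_mm, self.step_cap_mm,
               self.tolerance_mm) <= 0:
            raise GeometryError("DIR settings must be strictly positive")


def fit_rigid_landmarks(
    fixed_points: np.ndarray,
    moving_points: np.ndarray,
    fixed_frame: str = "fixed",
    moving_frame: str = "moving",
) -> RigidTransform:
    """Least-squares rigid fit of paired landmarks (Kabsch / Procrustes).

    Returns the rotation R and translation t minimizing
    Σᵢ ‖R fᵢ + t − mᵢ‖², i.e. the pull-back map carrying fixed-frame
    landmark positions onto their moving-frame mates.  Requires at least
    three non-collinear pairs; ``residual_rms`` (mm) is stored on the result.
    """
    f = np.asarray(fixed_points, dtype=float)
    m = np.asarray(moving_points, dtype=float)
    if f.shape != m.shape or f.ndim != 2 or f.shape[1] != 3:
        raise DegenerateLandmarksError("need equally many paired 3-D landmarks")
    n = f.shape[0]
    if n < 3:
        raise DegenerateLandmarksError(f"need >= 3 landmark pairs, got {n}")
    fc = f - f.mean(axis=0)
    mc = m - m.mean(axis=0)
    # Collinear points leave a rotation axis unconstrained.
    if np.linalg.matrix_rank(fc, tol=1e-9 * max(1.0, np.abs(fc).max())) < 2:
        raise DegenerateLandmarksError("landmarks are collinear")
    H = fc.T @ mc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = m.mean(axis=0) - R @ f.mean(axis=0)
    residuals = f @ R.T + t - m
    rms = float(np.sqrt((residuals ** 2).sum(axis=1).mean()))
    return RigidTransform(R, t, fixed_frame, moving_frame, residual_rms=rms)


def warp_scalar(
    values: np.ndarray,
    source_geometry: GridGeometry,
    fld: DeformationField,
    order: int = 1,
) -> np.ndarray:
    """Sample ``values`` (on source geometry) at the field's mapped points."""
    return sample_at_points(values, source_geometry, fld.mapped_points(), order=order)


def warp_dose(dose: DoseGrid, fld: DeformationField) -> DoseGrid:
    """Pull a moving-frame EQD2 dose back onto the field's fixed geometry.

    Only EQD2 grids may be warped — conversion precedes spatial transport in
    the accumulation workflow, so physical-dose inputs are rejected.
    Out-of-extent samples are zero.
    """
    if dose.unit != GY_EQD2:
        raise UnitError("warp_dose requires Gy_EQD2 input (convert before warping)")
    vals = warp_scalar(dose.values, dose.geometry, fld, order=1)
    geom = fld.geometry
    return DoseGrid(geom, vals, GY_EQD2, dose.n_fractions,
                    list(dose.provenance) + ["warped"])


def warp_mask(
    mask: StructureMask, fld: DeformationField, interpolation: str = "nearest"
) -> StructureMask:
    """Propagate a contour mask onto the field's fixed geometry.

    Nearest-neighbor by default; ``interpolation="trilinear"`` samples the
    binary occupancy linearly and thresholds at 0.5.
    """
    if interpolation == "nearest":
        occ = warp_scalar(mask.occupancy, mask.geometry, fld, order=0) > 0.5
    elif interpolation == "trilinear":
        occ = warp_scalar(mask.occupancy, mask.geometry, fld, order=1) >= 0.5
    else:
        raise FrameError(f"unknown interpolation {interpolation!r}")
    return StructureMask(fld.geometry, occ, mask.label)


def compose(outer: DeformationField, inner: DeformationField) -> DeformationField:
    """Chain two pull-back fields: (outer ∘ inner)(x) = T_inner(x + u_outer(x)).

    The composed map sends a fixed point x first through the outer field and
    then through the inner one, with the inner displacement interpolated
    trilinearly at the intermediate points.  Composing with an identity
    field on either side returns the other field unchanged (up to
    interpolation at the sampled lattice, exact for identity).
    """
    mid = outer.mapped_points()
    u_inner = np.stack(
        [
            sample_at_points(inner.displacement[..., c], inner.geometry, mid, order=1)
            for c in range(3)
        ],
        axis=-1,
    )
    total = mid + u_inner - outer.geometry.voxel_centers()
    return DeformationField(outer.geometry, total)


def _downsample_geometry(geom: GridGeometry, factor: int) -> GridGeometry:
    shape = tuple(max(1, int(np.ceil(n / factor))) for n in geom.shape)
    spacing = tuple(s * factor for s in geom.spacing)
    return GridGeometry(geom.origin, spacing, shape, geom.frame_id)


def _resample_volume(values: np.ndarray, src: GridGeometry, dst: GridGeometry):
    return sample_at_points(values, src, dst.voxel_centers(), order=1)


def register_demons(
    fixed_image: np.ndarray,
    moving_image: np.ndarray,
    geometry: GridGeometry,
    settings: DIRSettings = DIRSettings(),
) -> DeformationField:
    """Demons deformable registration of two co-resampled scalar volumes.

    Both volumes must already live on ``geometry`` (rigidly pre-aligned and
    resampled).  Returns the pull-back displacement field that, applied to
    the moving image, approximates the fixed image.  The update rule is the
    classical demons force

        v = (M(x+u) − F(x)) ∇F / (‖∇F‖² + (M(x+u) − F(x))²/κ²)

    with κ the mean voxel spacing, Gaussian smoothing of v (fluid) and of u
    (diffusion), and a per-iteration step cap.  Identical inputs yield the
    exact zero field; a constant-intensity fixed image has no gradient to
    follow, so the identity field is returned with a warning.
    """
    F_full = np.asarray(fixed_image, dtype=float)
    M_full = np.asarray(moving_image, dtype=float)
    if F_full.shape != geometry.shape or M_full.shape != geometry.shape:
        raise GeometryError("fixed/moving shapes must match the geometry")

    if np.ptp(F_full) == 0:
        warnings.warn("constant-intensity fixed image: no gradient, identity field")
        return DeformationField.identity(geometry)
    if np.array_equal(F_full, M_full):
        return DeformationField.identity(geometry)

    # Intensity scale normalization keeps the force balance resolution-free.
    scale = np.ptp(F_full)
    F_full = F_full / scale
    M_full = M_full / scale

    field_mm = None  # displacement on the current level geometry
    levels = [2 ** (settings.pyramid_levels - 1 - i) for i in range(settings.pyramid_levels)]
    for level, n_iter in zip(levels, settings.iterations):
        geom_l = _downsample_geometry(geometry, level) if level > 1 else geometry
        if level > 1:
            sigma_vox = 0.5 * level  # anti-alias before decimation
            F = _resample_volume(ndimage.gaussian_filter(F_full, sigma_vox), geometry, geom_l)
            M = _resample_volume(ndimage.gaussian_filter(M_full, sigma_vox), geometry, geom_l)
        else:
            F, M = F_full, M_full

        if field_mm is None:
            u = np.zeros(geom_l.shape + (3,))
        else:
            centers = geom_l.voxel_centers()
            u = np.stack(
                [sample_at_points(field_mm[..., c], prev_geom, centers, order=1)
                 for c in range(3)], axis=-1)

        spacing = np.asarray(geom_l.spacing)
        kappa2 = float(np.mean(spacing)) ** 2
        grad_F = np.stack(np.gradient(F, *spacing), axis=-1)
        grad_norm2 = (grad_F ** 2).sum(axis=-1)
        sig_u_vox = settings.update_sigma_mm / spacing
        sig_f_vox = settings.field_sigma_mm / spacing

        for _ in range(n_iter):
            warped = sample_at_points(
                M, geom_l, geom_l.voxel_centers() + u, order=1)
            diff = warped - F
            denom = grad_norm2 + diff ** 2 / kappa2
            with np.errstate(invalid="ignore", divide="ignore"):
                v = -(diff / np.where(denom > 0, denom, np.inf))[..., None] * grad_F
            # fluid regularization + step cap
            for c in range(3):
                v[..., c] = ndimage.gaussian_filter(v[..., c], sig_u_vox)
            mag = np.sqrt((v ** 2).sum(axis=-1))
            cap = settings.step_cap_mm
            over = mag > cap
            if np.any(over):
                v[over] *= (cap / mag[over])[..., None]
            u = u + v
            # diffusion regularization
            for c in range(3):
                u[..., c] = ndimage.gaussian_filter(u[..., c], sig_f_vox)
            if float(mag.mean()) < settings.tolerance_mm:
                break

        field_mm = u
        prev_geom = geom_l

    return DeformationField(geometry, field_mm)
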