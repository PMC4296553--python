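"""Synthetic multi-session pelvic phantom with known ground-truth deformations.

The generator emulates a combined-radiotherapy course for cervical cancer:
one external-beam (EBRT) planning frame plus four weekly intracavitary
brachytherapy (ICBT) frames, the first ICBT frame serving as the reference.
Each frame carries a CT-like intensity volume, binary organ masks (HR-CTV,
rectum, bladder), landmark sets (bony points for EBRT, applicator points
for ICBT), and a physical dose grid — a four-field-box 45 Gy / 25-fraction
plateau for EBRT and a capped inverse-square multi-dwell source model for
each single-fraction ICBT session, calibrated so the session HR-CTV D90 is
6 Gy physical.

Anatomy in the non-reference frames is produced by pushing the reference
organs through smooth, analytically evaluable displacement maps (Gaussian
bumps + per-organ scalings for bladder/rectum filling jitter and tumor
shrinkage).  Because both the maps and the organs are closed-form, every
frame's masks and doses are exact, the true reference→frame deformation
fields are recoverable to machine-level accuracy by fixed-point inversion,
and an *analytic* cumulative EQD2 grid — closed-form dose evaluated at the
exactly mapped points, no grid interpolation — is available as an oracle
for the accumulation pipeline.

Deliberate anatomical simplifications: displacements vanish near the
applicator (its position fixes the intra-ICBT rigid alignment and anchors
the adjacent tissue) and near the scan boundary (so mapped points stay
inside the scanned extent); bony anatomy moves only with the EBRT rigid
offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import DomainError, PhantomSpecError
from .grids import GY_PHYSICAL, DoseGrid, GridGeometry, StructureMask
from .radiobiology import LQ_NORMAL, LQ_TUMOR, LQParameters, eqd2_scalar
from .registration import DeformationField, RigidTransform

__all__ = [
    "OrganSpec",
    "PhantomSpec",
    "PhantomFrame",
    "PhantomCourse",
    "generate_course",
    "brachy_dose",
    "ebrt_dose",
    "random_smooth_field",
    "calibrate_brachy_strength",
    "jacobian_determinant",
    "to_treatment_course",
    "aligned_course_spec",
]

FRAME_IDS = ("EBRT", "ICBT1", "ICBT2", "ICBT3", "ICBT4")


# --------------------------------------------------------------------------
# specification


@dataclass(frozen=True)
class OrganSpec:
    """Superellipsoid organ: Σ |(p−c)/a|^e ≤ 1."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    exponents: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def inside(self, points: np.ndarray) -> np.ndarray:
        return self.implicit(points) <= 1.0

    def implicit(self, points: np.ndarray) -> np.ndarray:
        p = (np.asarray(points, dtype=float) - self.center) / self.semi_axes
        e = np.asarray(self.exponents)
        return (np.abs(p) ** e).sum(axis=-1)


def _default_organs() -> dict[str, OrganSpec]:
    return {
        "HR-CTV": OrganSpec((0.0, 0.0, 12.0), (19.0, 17.0, 24.0)),
        "rectum": OrganSpec((0.0, 38.0, 0.0), (13.0, 13.0, 45.0), (2, 2, 4)),
        "bladder": OrganSpec((0.0, -46.0, 12.0), (40.0, 27.0, 38.0)),
    }


def _default_bone_landmarks() -> np.ndarray:
    return np.array(
        [
            [62.0, 15.0, -40.0],
            [-62.0, 15.0, -40.0],
            [62.0, 15.0, 25.0],
            [-62.0, 15.0, 25.0],
            [0.0, 58.0, -45.0],
        ]
    )


def _default_dwells() -> np.ndarray:
    # tandem along z through the cervix + two ovoid positions
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [0.0, 0.0, 10.0],
            [0.0, 0.0, 20.0],
            [0.0, 0.0, 30.0],
            [11.0, 0.0, -6.0],
            [-11.0, 0.0, -6.0],
        ]
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Conditions of the emulated treatment course.

    Defaults reproduce the study conditions: 45 Gy / 25 fx whole-pelvis
    EBRT, four weekly single-fraction ICBT sessions prescribed to
    HR-CTV D90 = 6 Gy physical each, transverse tumor diameter 52 mm at
    EBRT planning shrinking to 38 mm at the first ICBT and mildly further
    over the remaining sessions, organ volumes inside the clinically
    observed ranges (HR-CTV ≈ 13–49, rectum ≈ 27–95, bladder ≈ 138–540 cm³),
    and small residual bladder/rectum volume jitter, emulating careful
    pre-imaging preparations (fixed bladder filling, rectal gas drainage,
    constant tandem angle).
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    organs: dict = field(default_factory=_default_organs)
    bone_landmarks: np.ndarray = field(default_factory=_default_bone_landmarks)
    dwell_positions: np.ndarray = field(default_factory=_default_dwells)
    dwell_weights: tuple = (1.0, 1.0, 1.0, 1.0, 0.7, 0.7)
    # per-frame transverse tumor diameter, mm: (EBRT, ICBT1..4)
    tumor_diameter_mm: tuple = (52.0, 38.0, 36.0, 34.0, 32.0)
    deformation_magnitude_mm: float = 8.0
    field_smoothing_mm: float = 25.0
    n_bumps: int = 6
    volume_jitter: float = 0.04
    dwell_jitter_mm: float = 1.0
    noise_sigma: float = 4.0
    ebrt_dose_gy: float = 45.0
    ebrt_n_fractions: int = 25
    icbt_d90_gy: float = 6.0
    ebrt_translation_mm: tuple = (2.0, -2.0, 2.0)
    ebrt_rotation_deg: float = 1.5
    brachy_r_min_mm: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.deformation_magnitude_mm < 0 or self.field_smoothing_mm <= 0:
            raise PhantomSpecError("deformation/smoothing must be non-negative")
        if self.deformation_magnitude_mm >= self.field_smoothing_mm:
            raise PhantomSpecError(
                "invertibility guard: deformation magnitude must stay below "
                "the field smoothing width"
            )
        if len(self.tumor_diameter_mm) != 5:
            raise PhantomSpecError("tumor_diameter_mm needs one entry per frame")

    def geometry(self, frame_id: str) -> GridGeometry:
        origin = tuple(
            -(n - 1) / 2.0 * s for n, s in zip(self.shape, self.spacing)
        )
        return GridGeometry(origin, self.spacing, self.shape, frame_id)


@dataclass
class PhantomFrame:
    frame_id: str
    modality: str  # "EBRT" | "ICBT"
    session_index: int | None
    geometry: GridGeometry
    ct: np.ndarray
    organs: dict  # label -> StructureMask
    dose: DoseGrid
    landmarks: dict  # "bone" / "applicator" -> (N, 3) mm


@dataclass
class PhantomCourse:
    """Generated frames plus every piece of ground truth."""

    spec: PhantomSpec
    frames: list  # ordered EBRT, ICBT1..4
    reference_frame: str
    truth_fields: dict  # frame_id -> DeformationField (reference -> frame)
    ebrt_rigid: RigidTransform  # true reference -> EBRT rigid map
    analytic_cumulative_tumor: DoseGrid
    analytic_cumulative_normal: DoseGrid

    @property
    def reference(self) -> PhantomFrame:
        return next(f for f in self.frames if f.frame_id == self.reference_frame)


# --------------------------------------------------------------------------
# analytic dose models


def _smoothstep01(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


class _EbrtField:
    """Closed-form box dose: plateau × per-face cubic falloff × (1 + η).

    The falloff along each axis is a compactly supported sigmoid-like cubic:
    exactly 0 beyond 3σ outside a face, exactly the plateau beyond 3σ
    inside, and half the plateau on the face itself.  The inhomogeneity η
    is a smooth triple-cosine modulation with seeded wavelengths and
    phases, strictly bounded inside ±`inhomogeneity`.
    """

    def __init__(self, box_lo, box_hi, penumbra_sigma, inhomogeneity,
                 plateau_gy=45.0, seed=0):
        self.lo = np.asarray(box_lo, dtype=float)
        self.hi = np.asarray(box_hi, dtype=float)
        if np.any(self.hi <= self.lo):
            raise DomainError("box_hi must exceed box_lo")
        self.sigma = float(penumbra_sigma)
        self.eps = float(inhomogeneity)
        self.plateau = float(plateau_gy)
        rng = np.random.default_rng(seed)
        self.wavelengths = rng.uniform(80.0, 140.0, size=3)
        self.phases = rng.uniform(0.0, 2 * np.pi, size=3)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        width = 6.0 * self.sigma
        prof = np.ones(p.shape[:-1])
        for a in range(3):
            prof = prof * _smoothstep01((p[..., a] - self.lo[a]) / width + 0.5)
            prof = prof * _smoothstep01((self.hi[a] - p[..., a]) / width + 0.5)
        if self.eps > 0:
            eta = np.ones(p.shape[:-1])
            for a in range(3):
                eta = eta * np.cos(
                    2 * np.pi * p[..., a] / self.wavelengths[a] + self.phases[a]
                )
            prof = prof * (1.0 + 0.9 * self.eps * eta)
        return self.plateau * prof


class _BrachyField:
    """Capped inverse-square multi-source dose: D(x) = Σ sᵢ / max(rᵢ, r_min)²."""

    def __init__(self, dwell_points, strengths, r_min_mm=8.0):
        self.dwells = np.atleast_2d(np.asarray(dwell_points, dtype=float))
        if self.dwells.shape[0] < 1:
            raise DomainError("need at least one dwell point")
        self.strengths = np.broadcast_to(
            np.asarray(strengths, dtype=float), (self.dwells.shape[0],)
        )
        self.r_min = float(r_min_mm)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        out = np.zeros(p.shape[:-1])
        for dwell, s in zip(self.dwells, self.strengths):
            r2 = ((p - dwell) ** 2).sum(axis=-1)
            r2 = np.maximum(r2, self.r_min ** 2)
            out += s / r2
        return out


def ebrt_dose(
    box_lo,
    box_hi,
    geometry: GridGeometry,
    penumbra_sigma: float = 2.5,
    inhomogeneity: float = 0.02,
    plateau_gy: float = 45.0,
    n_fractions: int = 25,
    seed: int = 0,
) -> DoseGrid:
    """Four-field-box-like EBRT dose on ``geometry`` (physical Gy)."""
    fieldfn = _EbrtField(box_lo, box_hi, penumbra_sigma, inhomogeneity,
                         plateau_gy, seed)
    values = fieldfn(geometry.voxel_centers())
    return DoseGrid(geometry, values, GY_PHYSICAL, n_fractions,
                    provenance=["ebrt_box"])


def brachy_dose(
    dwell_points,
    strengths,
    geometry: GridGeometry,
    r_min_mm: float = 8.0,
) -> DoseGrid:
    """Point-source inverse-square brachytherapy dose (physical Gy).

    ``strengths`` are per-dwell constants in Gy·mm²; the dose is capped at
    each source by clamping the distance at ``r_min_mm``, which keeps the
    characteristic steep gradient while bounding the maximum.
    """
    fieldfn = _BrachyField(dwell_points, strengths, r_min_mm)
    values = fieldfn(geometry.voxel_centers())
    return DoseGrid(geometry, values, GY_PHYSICAL, 1, provenance=["brachy"])


def calibrate_brachy_strength(
    dwell_points,
    dwell_weights,
    hrctv: StructureMask,
    target_d90_gy: float = 6.0,
    r_min_mm: float = 8.0,
    tol_gy: float = 1e-3,
    max_iter: int = 60,
) -> float:
    """Bisection on an overall strength multiplier so HR-CTV D90 hits target.

    Returns the multiplier m such that D90 of ``m × weights`` inverse-square
    dose over ``hrctv`` equals ``target_d90_gy`` within ``tol_gy``.
    """
    from .dvh import compute_dvh, dose_at_volume  # local import, no cycle

    # dose is linear in the multiplier, so compute the unit-strength grid
    # once and bisect on the cached D90 query
    unit = brachy_dose(dwell_points, np.asarray(dwell_weights, dtype=float),
                       hrctv.geometry, r_min_mm)
    unit_curve = compute_dvh(unit, hrctv)
    unit_d90 = dose_at_volume(unit_curve, percent=90.0)

    def d90(multiplier: float) -> float:
        return multiplier * unit_d90

    lo, hi = 1e-2, 1.0
    while d90(hi) < target_d90_gy:
        hi *= 4.0
        if hi > 1e9:
            raise DomainError("calibration bracket failed")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        val = d90(mid)
        if abs(val - target_d90_gy) < tol_gy:
            return mid
        if val < target_d90_gy:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# smooth displacement machinery


class _BumpSum:
    """Sum of Gaussian displacement bumps, evaluable at arbitrary points."""

    def __init__(self, centers, vectors, sigma_mm):
        self.centers = np.atleast_2d(centers)
        self.vectors = np.atleast_2d(vectors)
        self.sigma = float(sigma_mm)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        out = np.zeros(p.shape)
        for c, v in zip(self.centers, self.vectors):
            w = np.exp(-((p - c) ** 2).sum(axis=-1) / (2 * self.sigma ** 2))
            out += w[..., None] * v
        return out


class _OrganScaling:
    """Local radial scaling about an organ center.

    Displacement (frame → reference space) carrying a point of the
    λ-scaled organ back onto the unscaled one: d(x) = w(x)·(x − c)(1/λ − 1),
    with w ≡ 1 throughout the scaled organ (the scaling is exact there, so
    the frame organ is exactly the λ-scaled reference organ wherever no
    other window interferes) and a smooth compact falloff outside.
    """

    def __init__(self, organ: OrganSpec, scale: float,
                 falloff_start=1.05, falloff_end=1.9):
        self.center = np.asarray(organ.center)
        self.axes = np.asarray(organ.semi_axes) * float(scale)
        self.scale = float(scale)
        self.t0, self.t1 = float(falloff_start), float(falloff_end)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        rel = p - self.center
        # elliptic radius in units of the scaled organ (1 at its surface)
        m = np.sqrt(((rel / self.axes) ** 2).sum(axis=-1))
        w = 1.0 - _smoothstep01((m - self.t0) / (self.t1 - self.t0))
        return (1.0 / self.scale - 1.0) * w[..., None] * rel


class _WindowedSum:
    """Composite displacement: Σ components, multiplied by scalar windows."""

    def __init__(self, components, windows):
        self.components = list(components)
        self.windows = list(windows)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        out = np.zeros(p.shape)
        for comp in self.components:
            out += comp(p)
        for win in self.windows:
            out *= win(p)[..., None]
        return out


def _applicator_window(applicator_points, r_inner=12.0, r_outer=40.0):
    """0 within ``r_inner`` mm of the applicator, ramping to 1 at ``r_outer``."""
    pts = np.atleast_2d(applicator_points)

    def window(p):
        p = np.asarray(p, dtype=float)
        # distance to the applicator point set (dwells + tip sample the axis)
        d2 = np.full(p.shape[:-1], np.inf)
        for a in pts:
            d2 = np.minimum(d2, ((p - a) ** 2).sum(axis=-1))
        return _smoothstep01((np.sqrt(d2) - r_inner) / (r_outer - r_inner))

    return window


def _boundary_window(geometry: GridGeometry, margin_mm=16.0):
    """0 at the scan boundary, 1 at ``margin_mm`` inside it."""
    lo = np.asarray(geometry.origin)
    hi = lo + (np.asarray(geometry.shape) - 1) * np.asarray(geometry.spacing)

    def window(p):
        p = np.asarray(p, dtype=float)
        d = np.minimum(p - lo, hi - p).min(axis=-1)
        return _smoothstep01(d / margin_mm)

    return window


def jacobian_determinant(fld: DeformationField) -> np.ndarray:
    """Finite-difference Jacobian determinant of x ↦ x + u(x), per voxel."""
    u = fld.displacement
    sp = fld.geometry.spacing
    J = np.empty(u.shape[:-1] + (3, 3))
    for c in range(3):
        grads = np.gradient(u[..., c], *sp)
        for a in range(3):
            J[..., c, a] = grads[a] + (1.0 if a == c else 0.0)
    return np.linalg.det(J)


def random_smooth_field(
    magnitude_mm: float,
    n_bumps: int,
    smoothing_mm: float,
    geometry: GridGeometry,
    seed: int = 0,
) -> DeformationField:
    """Random sum-of-Gaussian-bumps displacement field, max |u| ≤ magnitude.

    Displacements are normalized so the largest voxel displacement equals
    ``magnitude_mm`` and checked to be invertibility-safe (positive
    finite-difference Jacobian determinant everywhere); the guard
    ``magnitude < smoothing`` rejects fields that could fold.
    """
    if magnitude_mm < 0 or smoothing_mm <= 0:
        raise PhantomSpecError("magnitude must be >= 0, smoothing > 0")
    if magnitude_mm >= smoothing_mm:
        raise PhantomSpecError("invertibility guard: magnitude must be < smoothing")
    if magnitude_mm == 0:
        return DeformationField.identity(geometry)
    callable_fn = _random_bump_callable(
        magnitude_mm, n_bumps, smoothing_mm, geometry, np.random.default_rng(seed)
    )
    fld = DeformationField(geometry, callable_fn(geometry.voxel_centers()))
    if jacobian_determinant(fld).min() <= 0:
        raise PhantomSpecError("generated field folds (Jacobian <= 0)")
    return fld


def _random_bump_callable(magnitude_mm, n_bumps, smoothing_mm, geometry, rng):
    lo = np.asarray(geometry.origin)
    extent = (np.asarray(geometry.shape) - 1) * np.asarray(geometry.spacing)
    # bump centers in the central portion of the volume
    centers = lo + extent * rng.uniform(0.2, 0.8, size=(n_bumps, 3))
    vectors = rng.normal(size=(n_bumps, 3))
    bumps = _BumpSum(centers, vectors, smoothing_mm)
    sample = bumps(geometry.voxel_centers())
    peak = np.sqrt((sample ** 2).sum(axis=-1)).max()
    if peak == 0:
        return _BumpSum(centers, np.zeros_like(vectors), smoothing_mm)
    return _BumpSum(centers, vectors * (magnitude_mm / peak), smoothing_mm)


def _invert_displacement(v_callable, geometry: GridGeometry,
                         coarse_factor=2, coarse_iters=12, fine_iters=3):
    """Fixed-point inverse: find u with u(x) = −v(x + u(x)).

    Converges when the forward map x ↦ x + v(x) is a contraction
    perturbation (‖∇v‖ < 1), which the generator guards enforce.  Most
    iterations run on a coarsened lattice (the fields are far smoother than
    the voxel scale); the upsampled estimate is then polished at full
    resolution.
    """
    from .grids import sample_at_points

    coarse = GridGeometry(
        geometry.origin,
        tuple(s * coarse_factor for s in geometry.spacing),
        tuple(max(1, int(np.ceil(n / coarse_factor))) for n in geometry.shape),
        geometry.frame_id,
    )
    xc = coarse.voxel_centers()
    u = np.zeros_like(xc)
    for _ in range(coarse_iters):
        u = -v_callable(xc + u)
    x = geometry.voxel_centers()
    u = np.stack(
        [sample_at_points(u[..., c], coarse, x, order=1) for c in range(3)],
        axis=-1,
    )
    for _ in range(fine_iters):
        u = -v_callable(x + u)
    return DeformationField(geometry, u)


# --------------------------------------------------------------------------
# course generation


def _intensity_model(spec: PhantomSpec):
    """CT-like analytic intensity in reference space (approx. HU)."""
    body = OrganSpec((0.0, 0.0, 0.0), (90.0, 88.0, 118.0))
    organs = spec.organs

    def intensity(points):
        p = np.asarray(points, dtype=float)
        out = np.full(p.shape[:-1], -1000.0)
        inside_body = body.inside(p)
        out[inside_body] = 35.0
        # bone: two iliac rods, rigid in reality but drawn in frame space
        for sx in (62.0, -62.0):
            rod = ((p[..., 0] - sx) ** 2 + (p[..., 1] - 15.0) ** 2) <= 11.0 ** 2
            out[rod & inside_body] = 400.0
        levels = {"bladder": 0.0, "rectum": -80.0, "HR-CTV": 90.0}
        for label, value in levels.items():
            out[organs[label].inside(p)] = value
        return out

    return intensity


def _frame_displacement(spec: PhantomSpec, frame_index: int, rng):
    """Analytic displacement (frame space → reference space) for one frame."""
    components, windows = [], []
    geometry = spec.geometry("ref")
    if spec.deformation_magnitude_mm > 0:
        components.append(
            _random_bump_callable(
                spec.deformation_magnitude_mm, spec.n_bumps,
                spec.field_smoothing_mm, geometry, rng,
            )
        )
    # bladder / rectum filling jitter
    for label in ("bladder", "rectum"):
        lam = 1.0 + spec.volume_jitter * rng.uniform(-1.0, 1.0)
        if spec.volume_jitter > 0:
            components.append(_OrganScaling(spec.organs[label], lam))
    # tumor shrinkage relative to the reference (first-ICBT) diameter
    d_ref = spec.tumor_diameter_mm[1]
    lam_t = spec.tumor_diameter_mm[frame_index] / d_ref
    if abs(lam_t - 1.0) > 1e-12:
        components.append(_OrganScaling(spec.organs["HR-CTV"], lam_t))
    if not components:
        return None
    windows.append(_boundary_window(geometry))
    if FRAME_IDS[frame_index] != "EBRT":
        applicator = np.vstack([spec.dwell_positions, [[0.0, 0.0, 38.0]]])
        windows.append(_applicator_window(applicator))
    return _WindowedSum(components, windows)


def generate_course(spec: PhantomSpec) -> PhantomCourse:
    """Deterministically generate the five-frame phantom course.

    All randomness flows from ``spec.seed`` through independent per-frame
    substreams; two calls with the same spec are bit-identical.
    """
    root = np.random.SeedSequence(spec.seed)
    frame_seeds = root.spawn(len(FRAME_IDS))
    intensity = _intensity_model(spec)
    applicator_landmarks = np.vstack([spec.dwell_positions, [[0.0, 0.0, 38.0]]])

    # true reference -> EBRT rigid map
    ang = math.radians(spec.ebrt_rotation_deg)
    R = np.array(
        [[math.cos(ang), -math.sin(ang), 0.0],
         [math.sin(ang), math.cos(ang), 0.0],
         [0.0, 0.0, 1.0]]
    )
    ebrt_rigid = RigidTransform(R, np.asarray(spec.ebrt_translation_mm),
                                "ICBT1", "EBRT")
    ebrt_rigid_inv = ebrt_rigid.inverse()

    frames: list[PhantomFrame] = []
    truth_fields: dict[str, DeformationField] = {}
    dose_fns: dict[str, object] = {}

    for idx, frame_id in enumerate(FRAME_IDS):
        rng = np.random.default_rng(frame_seeds[idx])
        geometry = spec.geometry(frame_id)
        centers = geometry.voxel_centers()
        is_ebrt = frame_id == "EBRT"
        is_reference = frame_id == "ICBT1"

        warp = None if is_reference else _frame_displacement(spec, idx, rng)

        def to_reference(points, warp=warp, is_ebrt=is_ebrt):
            p = np.asarray(points, dtype=float)
            if is_ebrt:
                p = ebrt_rigid_inv.apply(p)
            if warp is not None:
                p = p + warp(p)
            return p

        ref_points = to_reference(centers)
        organs = {
            label: StructureMask(geometry, org.inside(ref_points), label)
            for label, org in spec.organs.items()
        }
        ct = intensity(ref_points)
        ct = ct + rng.normal(0.0, spec.noise_sigma, size=ct.shape)
        ct = ndimage.gaussian_filter(ct, 0.8)

        if is_ebrt:
            # lateral (x) and longitudinal (z) penumbrae fall inside the
            # scan; the anterior-posterior faces sit further out so the
            # bladder keeps a full-plateau margin of >= 3 sigma
            half = np.asarray([82.0, 90.0, 77.0])
            center_off = np.asarray([0.0, 0.0, 5.0])
            dose_fn = _EbrtField(
                center_off - half, center_off + half,
                penumbra_sigma=4.0, inhomogeneity=0.02,
                plateau_gy=spec.ebrt_dose_gy,
                seed=int(rng.integers(2 ** 31)),
            )
            dose = DoseGrid(geometry, dose_fn(centers), GY_PHYSICAL,
                            spec.ebrt_n_fractions, provenance=["ebrt_box"])
            landmarks = {"bone": ebrt_rigid.apply(spec.bone_landmarks)}
            session = None
        else:
            dwells = spec.dwell_positions + rng.normal(
                0.0, spec.dwell_jitter_mm, size=spec.dwell_positions.shape
            )
            mult = calibrate_brachy_strength(
                dwells, spec.dwell_weights, organs["HR-CTV"],
                spec.icbt_d90_gy, spec.brachy_r_min_mm,
            )
            dose_fn = _BrachyField(
                dwells, mult * np.asarray(spec.dwell_weights),
                spec.brachy_r_min_mm,
            )
            dose = DoseGrid(geometry, dose_fn(centers), GY_PHYSICAL, 1,
                            provenance=["brachy"])
            landmarks = {
                "applicator": applicator_landmarks.copy(),
                "bone": spec.bone_landmarks.copy(),
            }
            session = idx  # ICBT1..4 -> 1..4

        frames.append(
            PhantomFrame(frame_id, "EBRT" if is_ebrt else "ICBT", session,
                         geometry, ct, organs, dose, landmarks)
        )
        dose_fns[frame_id] = dose_fn

        if not is_ebrt and not is_reference:
            if warp is None:
                truth_fields[frame_id] = DeformationField.identity(
                    spec.geometry("ICBT1")
                )
            else:
                truth_fields[frame_id] = _invert_displacement(
                    warp, spec.geometry("ICBT1")
                )

    # analytic cumulative EQD2 on the reference frame: closed-form dose
    # evaluated at the exactly mapped points (no grid interpolation)
    ref_geom = spec.geometry("ICBT1")
    ref_centers = ref_geom.voxel_centers()
    mapped_dose = {"EBRT": dose_fns["EBRT"](ebrt_rigid.apply(ref_centers))}
    for frame_id in FRAME_IDS[1:]:
        pts = ref_centers if frame_id == "ICBT1" else (
            ref_centers + truth_fields[frame_id].displacement
        )
        mapped_dose[frame_id] = dose_fns[frame_id](pts)
    cumulative = {}
    for name, lq in (("tumor", LQ_TUMOR), ("normal", LQ_NORMAL)):
        total = eqd2_scalar(mapped_dose["EBRT"], spec.ebrt_n_fractions, lq)
        for frame_id in FRAME_IDS[1:]:
            total = total + eqd2_scalar(mapped_dose[frame_id], 1, lq)
        cumulative[name] = DoseGrid(ref_geom, total, "Gy_EQD2",
                                    provenance=[f"analytic_cumulative_{name}"])

    return PhantomCourse(
        spec=spec,
        frames=frames,
        reference_frame="ICBT1",
        truth_fields=truth_fields,
        ebrt_rigid=ebrt_rigid,
        analytic_cumulative_tumor=cumulative["tumor"],
        analytic_cumulative_normal=cumulative["normal"],
    )


def to_treatment_course(course: PhantomCourse):
    """Package a phantom course as accumulation-pipeline input."""
    from .accumulation import FractionRecord, TreatmentCourse

    records = [
        FractionRecord(
            dose=frame.dose,
            modality=frame.modality,
            frame_id=frame.frame_id,
            landmarks=frame.landmarks,
            session_index=frame.session_index,
            image=frame.ct,
            structures=frame.organs,
        )
        for frame in course.frames
    ]
    return TreatmentCourse(
        records=records,
        reference_frame=course.reference_frame,
        structures=course.reference.organs,
    )


def aligned_course_spec(seed: int, shape=(48, 48, 48), spacing=(3.0, 3.0, 3.0)):
    """Spec for an aligned-anatomy course: identical frames, jittered dwells.

    With deformation, volume jitter and shrinkage off, every frame shares
    the reference anatomy and all transforms are the identity, while the
    per-session dwell jitter still moves the brachytherapy hot spots — the
    configuration under which simple DVH-parameter addition brackets the
    voxel-wise accumulated parameters.
    """
    return PhantomSpec(
        shape=shape,
        spacing=spacing,
        deformation_magnitude_mm=0.0,
        volume_jitter=0.0,
        tumor_diameter_mm=(38.0,) * 5,
        dwell_jitter_mm=2.0,
        ebrt_translation_mm=(0.0, 0.0, 0.0),
        ebrt_rotation_deg=0.0,
        seed=seed,
    )
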