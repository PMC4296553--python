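# Methods

This note documents the models, conventions and numerical choices behind
`cumudose`, and what the synthetic phantom does and does not demonstrate.

## Geometry and dose model

All volumes live on axis-aligned regular lattices. Arrays are indexed
`(ix, iy, iz)`; the world position (mm) of voxel `(i, j, k)` is
`origin + (i, j, k) · spacing`, with `origin` the *center* of voxel
`(0, 0, 0)`. Volumes are full-voxel counts (`count × voxel volume`,
1 cm³ = 1000 mm³); no fractional boundary supersampling is attempted, which
keeps structure volumes, DVH denominators and Dice denominators mutually
exact. Samples outside a grid's extent read as 0 (dose outside the scanned
volume is unknown; zero is the conservative choice). Coordinates within
10⁻⁶ voxel of the lattice boundary are snapped onto it before interpolation
so that identity-like transforms are exact despite floating-point rounding.

## Linear-quadratic conversion

Physical dose D delivered in n equal fractions maps to
`EQD2 = D (d + α/β) / (2 + α/β)` with `d = D/n`, applied voxel-wise with the
per-voxel fraction dose `d(v) = D(v)/n`. Equal fractions are assumed: the
emulated schedules (45 Gy in 25 daily EBRT fractions; one HDR fraction per
brachytherapy session) deliver identical fractions, and the EBRT field is
homogeneous to ±2 % over the organs, so per-fraction variation is
negligible. Defaults are α/β = 10 Gy (tumor) and 3 Gy (normal tissue), the
values standard for this disease site; the reference fraction size is 2 Gy,
which is the exact fixed point of the conversion. Conversion happens
*before* any warping or summation; a `convert_before_warp=False` flag
exposes the warp-then-convert variant for sensitivity analysis only. Two
cumulative grids are kept (one per α/β) rather than a voxel-wise tissue
map: target parameters are read from the α/β = 10 grid and organ-at-risk
parameters from the α/β = 3 grid, matching how combined-modality results
are reported.

## Registration

*Rigid.* Paired landmarks are fused with the closed-form orthogonal
Procrustes/Kabsch solution (centroids + SVD, with the determinant
correction for proper rotations). At least three non-collinear pairs are
required; the RMS residual is recorded on the transform. Bony landmarks
align the EBRT frame; the applicator position aligns brachytherapy frames,
mirroring clinical practice.

*Deformable.* A deterministic multi-resolution demons scheme: the update
force is `−diff · ∇F / (‖∇F‖² + diff²/κ²)` with `diff = M(x+u) − F(x)` and
κ the mean voxel spacing; each update is Gaussian-smoothed (fluid
regularization, default 3 mm), capped at 2 mm per iteration, added to the
field, and the field is Gaussian-smoothed again (diffusion regularization,
default 2 mm). Three pyramid levels (×4, ×2, ×1 downsampling) run 50/30/10
iterations with early exit when the mean update falls below 10⁻³ mm.
Identical inputs return the exact zero field; a constant fixed image has no
gradient and returns identity with a warning. There is no stochastic
optimization anywhere, so results are bit-reproducible. The step cap at the
voxel scale is an invertibility heuristic, not a diffeomorphic guarantee.

*Warping.* All transport is backward/pull-back: output voxel x samples the
moving volume at x + u(x) (trilinear for dose, nearest-neighbor for masks
with a linear + 0.5-threshold alternative). Forward splatting was rejected
because it leaves holes and requires ad-hoc normalization. Dose warping
refuses physical-Gy input, enforcing the convert-then-warp order at the
type level. Rigid maps are folded into the demons field analytically
(`T_rigid(x + u_demons(x))`), so each dose grid is interpolated exactly
once. Externally supplied ("injected") fields bypass demons entirely; this
replaces interactive registration refinement and is how phantom ground
truth drives validation.

## DVH parameters

Cumulative DVH curves bin at 0.1 Gy by default for export, but D90/D2cc
queries are evaluated on the exact sorted voxel doses: D_x is the largest
dose d with volume(≥ d) ≥ x, linearly interpolated between adjacent
cumulative-volume samples, ties toward the higher dose (the minimum dose of
the hottest x volume). Structures smaller than the 2 cm³ query volume raise
an error rather than extrapolate. Simple parameter addition sums
per-component parameters and tags the result, so the two calculation
methods cannot be confused downstream.

## Statistics

Dice coefficients are reported at full precision internally and at 2
decimals in table reproductions. The degenerate both-empty case is defined
as DSC = 1 with a warning. DIR-vs-rigid comparisons use the classical
two-sided paired t-test (n − 1 degrees of freedom); zero-variance
differences raise instead of returning an undefined statistic. The bundled
reference table of published per-contour volumes and DSC values contains a
few internally inconsistent rows (the printed volumes do not reproduce the
printed DSC, and one intersection exceeds a component volume); these rows
are kept verbatim for the summary statistics but flagged NaN when DSC is
recomputed from volumes, and only self-consistent rows serve as worked
examples.

## Synthetic phantom

The generator emulates one treatment course: an EBRT planning frame and
four weekly ICBT frames on a 96³ lattice at 2 mm (≈ ±95 mm of pelvis), the
first ICBT frame being the reference. Organs are superellipsoids — HR-CTV
(38 mm transverse diameter at the first ICBT, ≈ 32 cm³), rectum (a
13 mm-radius tube, ≈ 37 cm³) and bladder (≈ 172 cm³) — inside the volume
ranges observed clinically for this treatment context (HR-CTV ≈ 13–49,
rectum ≈ 27–95, bladder ≈ 138–540 cm³).

*Inter-fraction variation.* Non-reference frames are produced by evaluating
the reference anatomy through smooth analytic displacement maps: a sum of
normalized Gaussian bumps (default max 8 mm, 25 mm width — the invertibility
guard requires magnitude < smoothing), per-organ radial scalings for
bladder/rectum filling jitter (±4 % linear, emulating the small residual
variation left after strict pre-imaging preparations: reproducible bladder
filling, rectal gas drainage, fixed tandem angle), and tumor shrinkage
(52 mm transverse diameter at EBRT planning shrinking to 38 mm at the first
ICBT and mildly further over the sessions, an affine contraction of the
HR-CTV region). Displacements vanish smoothly (i) within ~12 mm of the
applicator — its position defines the intra-ICBT rigid alignment and
anchors adjacent tissue — and (ii) within ~16 mm of the scan boundary, so
mapped points never leave the scanned extent. Because organs and maps are
closed-form, frame masks are exact (no resampling), and the true
reference→frame fields are obtained by fixed-point inversion of the
analytic maps (coarse-lattice iterations polished at full resolution;
residual far below voxel scale). The EBRT frame additionally carries a
known rigid offset (2 mm translations, 1.5° rotation) realized exactly in
its bone landmarks.

*Doses.* Brachytherapy uses a capped inverse-square multi-dwell model
(4 tandem + 2 ovoid dwells, distance clamped at 8 mm), calibrated per
session by bisection on a global strength multiplier so the session HR-CTV
D90 is 6 Gy physical — the prescription level of the emulated schedule.
This reproduces the characteristic steep gradients and the very high
central doses of intracavitary treatment without TG-43 machinery
(anisotropy and radial dose functions are deliberately omitted). EBRT is a
45 Gy box with compact-support cubic penumbra (σ = 4 mm; exactly the
plateau ≥ 3σ inside the faces, exactly half at a face) and a smooth
triple-cosine inhomogeneity strictly inside ±2 %; the anterior–posterior
faces sit outside the bladder's 3σ margin so all organ voxels receive
45 Gy ± 2 %. CT-like intensities assign distinct levels to soft tissue,
organs and bone plus Gaussian noise (σ = 4) and light smoothing — enough
contrast for intensity-based demons, with no claim of realistic CT texture.

*Ground-truth consistency.* The analytic cumulative EQD2 grids evaluate the
closed-form doses at the exactly mapped points (no grid interpolation) and
are the oracle for the pipeline. The pipeline with injected truth fields
agrees with this oracle to within 2 % of the local dose over the
dosimetrically relevant region — all organ voxels (measured ≤ 0.3 %) and
everywhere the cumulative dose exceeds 10 Gy_EQD2 (measured ≤ 0.9 %). The
relative bound cannot extend to penumbra/background tails, where the local
dose approaches zero while trilinear interpolation error of a ~45 Gy field
stays finite; that region carries no reported parameter. Warping a
session's organs through the truth field reproduces the reference contours
up to voxelization; for the thin-walled rectum at 2 mm voxels this caps the
round-trip Dice near 0.95 even though the field inversion itself is
machine-accurate.

*What passing phantom tests do not show.* The phantom has piecewise-
constant intensities, geometric organs, rigid bone drawn in frame space,
and deformations that are smooth, invertible and small near the applicator
by construction. Success here validates the pipeline's bookkeeping —
conversion order, transform composition, interpolation, parameter
extraction — not the clinical accuracy of demons registration on real CT,
where sliding interfaces, contrast changes and large bladder variation can
defeat intensity-based DIR. Rigid-baseline Dice on the default phantom
(≈ 0.94–0.96) is accordingly much higher than the published clinical
rigid-fusion values (≈ 0.46–0.69); only the *ordering* (DIR above rigid)
is expected to transfer. Dose is transported kinematically: no
energy/mass-conservation correction is applied when tissue compresses.

## Problem sizes and determinism

Default experiment sizes: 96³ phantom frames for end-to-end runs;
aligned-anatomy bound experiments use 48³ at 3 mm (their conclusions depend
only on dose ordering statistics, not resolution); the organ-volume sweep
runs at 64³ / 3 mm since volumes are set by the analytic geometry, not the
lattice. Every random quantity derives from a single integer seed through
independent per-frame substreams; no global random state is touched. Two
runs with the same spec are bit-identical, and the demons optimizer is
deterministic, so the full pipeline (simulate → accumulate → report) is
reproducible byte-for-byte.
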