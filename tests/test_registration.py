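import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cumudose import (
    DeformationField,
    DIRSettings,
    DoseGrid,
    GridGeometry,
    StructureMask,
    compose,
    fit_rigid_landmarks,
    register_demons,
    volume_cc,
    warp_dose,
    warp_mask,
)
from cumudose.errors import DegenerateLandmarksError, UnitError
from cumudose.grids import GY_EQD2


def _random_rigid(rng):
    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return R, t


class TestRigidFit:
    def test_identity_for_identical_points(self, rng):
        pts = rng.uniform(-50, 50, (6, 3))
        T = fit_rigid_landmarks(pts, pts)
        assert T.is_identity(atol=1e-9)
        assert T.residual_rms < 1e-9

    def test_recovers_known_rotation_translation(self, rng):
        pts = rng.uniform(-50, 50, (8, 3))
        ang = np.radians(10.0)
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        t = np.array([5.0, 0.0, 0.0])
        T = fit_rigid_landmarks(pts, pts @ R.T + t)
        np.testing.assert_allclose(T.rotation, R, atol=1e-6)
        np.testing.assert_allclose(T.translation, t, atol=1e-6)

    def test_exact_recovery_over_100_random_transforms(self, rng):
        pts = rng.uniform(-60, 60, (10, 3))
        for _ in range(100):
            R, t = _random_rigid(rng)
            T = fit_rigid_landmarks(pts, pts @ R.T + t)
            assert np.abs(T.rotation - R).max() < 1e-6
            assert np.abs(T.translation - t).max() < 1e-6

    def test_noisy_fit_within_tolerance(self, rng):
        """sigma = 0.5 mm landmark noise: residual <= 3 sigma, params tight."""
        pts = rng.uniform(-60, 60, (10, 3))
        R, t = _random_rigid(rng)
        noisy = pts @ R.T + t + rng.normal(0, 0.5, (10, 3))
        T = fit_rigid_landmarks(pts, noisy)
        assert T.residual_rms <= 3 * 0.5
        rot_err = Rotation.from_matrix(T.rotation @ R.T).magnitude()
        assert np.degrees(rot_err) < 1.0
        assert np.linalg.norm(T.translation - t) < 1.0

    def test_transform_round_trip(self, rng):
        pts = rng.uniform(-40, 40, (5, 3))
        R, t = _random_rigid(rng)
        T = fit_rigid_landmarks(pts, pts @ R.T + t)
        back = T.inverse().apply(T.apply(pts))
        np.testing.assert_allclose(back, pts, atol=1e-6)

    def test_agrees_with_scipy_alignment(self, rng):
        """Independent cross-check against scipy's Kabsch solver."""
        fixed = rng.uniform(-50, 50, (12, 3))
        R, t = _random_rigid(rng)
        moving = fixed @ R.T + t + rng.normal(0, 1.0, (12, 3))
        T = fit_rigid_landmarks(fixed, moving)
        rot_ref, _ = Rotation.align_vectors(
            moving - moving.mean(0), fixed - fixed.mean(0)
        )
        np.testing.assert_allclose(T.rotation, rot_ref.as_matrix(), atol=1e-8)

    def test_degenerate_landmarks_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateLandmarksError):
            fit_rigid_landmarks(line, line)
        with pytest.raises(DegenerateLandmarksError):
            fit_rigid_landmarks(line[:2], line[:2])


def _geometry(n=20, spacing=2.0, frame="ICBT1"):
    orig = -(n - 1) / 2 * spacing
    return GridGeometry((orig,) * 3, (spacing,) * 3, (n,) * 3, frame)


class TestWarping:
    def test_identity_field_preserves_dose(self, rng):
        g = _geometry()
        dose = DoseGrid(g, rng.random(g.shape), GY_EQD2)
        out = warp_dose(dose, DeformationField.identity(g))
        np.testing.assert_array_equal(out.values, dose.values)

    def test_physical_dose_refused(self, rng):
        g = _geometry()
        dose = DoseGrid(g, rng.random(g.shape))
        with pytest.raises(UnitError):
            warp_dose(dose, DeformationField.identity(g))

    def test_ramp_under_constant_translation(self):
        """A linear ramp shifted by t is exactly the translated ramp."""
        g = _geometry(24, 2.0)
        x = g.voxel_centers()[..., 0] + 30.0
        dose = DoseGrid(g, x, GY_EQD2)
        t = np.array([4.0, 0.0, 0.0])
        fld = DeformationField(g, np.broadcast_to(t, g.shape + (3,)).copy())
        out = warp_dose(dose, fld)
        interior = np.s_[2:-4, 2:-2, 2:-2]
        np.testing.assert_allclose(out.values[interior], (x + 4.0)[interior],
                                   atol=1e-9)

    def test_warp_bounded_by_input_range(self, rng):
        g = _geometry()
        dose = DoseGrid(g, rng.random(g.shape) * 10, GY_EQD2)
        fld = DeformationField(g, rng.normal(0, 3, g.shape + (3,)))
        out = warp_dose(dose, fld)
        assert out.values.min() >= 0.0
        assert out.values.max() <= dose.values.max() + 1e-12

    def test_sphere_mask_translation_preserves_volume(self):
        g = _geometry(40, 1.0)
        c = g.voxel_centers()
        sphere = ((c - np.array([0, 0, 0.0])) ** 2).sum(-1) <= 10.0 ** 2
        mask = StructureMask(g, sphere, "bladder")
        t = np.array([3.0, 2.0, 1.0])
        fld = DeformationField(g, np.broadcast_to(t, g.shape + (3,)).copy())
        out = warp_mask(mask, fld)
        assert volume_cc(out) == pytest.approx(volume_cc(mask), rel=0.02)


class TestCompose:
    def test_identity_neutral_element(self, rng):
        g = _geometry()
        u = rng.normal(0, 2, g.shape + (3,))
        f = DeformationField(g, u)
        ident = DeformationField.identity(g)
        np.testing.assert_allclose(compose(ident, f).displacement, u, atol=1e-12)
        np.testing.assert_allclose(compose(f, ident).displacement, u, atol=1e-12)

    def test_translations_add(self):
        g = _geometry()
        a = DeformationField(g, np.broadcast_to([1.0, 2, 3], g.shape + (3,)).copy())
        b = DeformationField(g, np.broadcast_to([-2.0, 1, 4], g.shape + (3,)).copy())
        out = compose(a, b)
        # interior only: intermediate points near the boundary leave the
        # extent of the inner field, where displacement reads as 0
        interior = np.s_[3:-3, 3:-3, 3:-3]
        np.testing.assert_allclose(
            out.displacement[interior],
            np.broadcast_to([-1.0, 3, 7], g.shape + (3,))[interior],
            atol=1e-9,
        )

    def test_matches_two_step_lookup_oracle(self, rng):
        """compose equals warping through both fields sequentially."""
        from cumudose.grids import sample_at_points

        g = _geometry(24, 2.0)

        def smooth(seed):
            r = np.random.default_rng(seed)
            u = r.normal(0, 1.5, g.shape + (3,))
            from scipy.ndimage import gaussian_filter
            for c in range(3):
                u[..., c] = gaussian_filter(u[..., c], 3)
            return DeformationField(g, u * 4)

        outer, inner = smooth(1), smooth(2)
        composed = compose(outer, inner)
        pts = g.voxel_centers() + outer.displacement
        expected = pts + np.stack(
            [sample_at_points(inner.displacement[..., c], g, pts) for c in range(3)],
            axis=-1,
        ) - g.voxel_centers()
        np.testing.assert_allclose(composed.displacement, expected, atol=1e-10)


class TestDemons:
    def test_identical_images_give_zero_field(self, rng):
        g = _geometry(24)
        img = rng.random(g.shape)
        fld = register_demons(img, img, g, DIRSettings(1, (5,)))
        assert fld.max_displacement_mm == 0.0

    def test_constant_fixed_image_warns_identity(self):
        g = _geometry(16)
        with pytest.warns(UserWarning, match="constant-intensity"):
            fld = register_demons(np.ones(g.shape), np.zeros(g.shape), g)
        assert fld.max_displacement_mm == 0.0

    def test_recovers_small_translation_of_blob(self):
        """A 2 mm shift of a smooth blob is recovered within half a voxel."""
        g = _geometry(32, 2.0)
        c = g.voxel_centers()
        def blob(center):
            return 100 * np.exp(-((c - center) ** 2).sum(-1) / (2 * 12.0 ** 2))
        fixed = blob(np.zeros(3))
        moving = blob(np.array([-2.0, 0.0, 0.0]))  # pull-back shift of +2 in x
        fld = register_demons(fixed, moving, g,
                              DIRSettings(2, (40, 20)))
        core = fixed > 30
        mean_u = fld.displacement[core].mean(axis=0)
        assert abs(mean_u[0] - (-2.0)) < 1.0  # within 0.5 * spacing
        assert np.abs(mean_u[1:]).max() < 0.5

    def test_deterministic(self, rng):
        g = _geometry(20)
        fixed = rng.random(g.shape)
        moving = rng.random(g.shape)
        s = DIRSettings(1, (5,))
        a = register_demons(fixed, moving, g, s)
        b = register_demons(fixed, moving, g, s)
        np.testing.assert_array_equal(a.displacement, b.displacement)
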