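"""Template matching, sub-pixel refinement and precision metrics."""

import numpy as np
import pytest

import ssrpsf as S


def brute_force_ncc(target: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Direct-sum Pearson correlation at every full-overlap displacement."""
    th, tw = template.shape
    H = target.shape[0] - th + 1
    W = target.shape[1] - tw + 1
    out = np.empty((H, W))
    tz = template - template.mean()
    tn = np.sqrt((tz * tz).sum())
    for j in range(H):
        for i in range(W):
            win = target[j : j + th, i : i + tw]
            wz = win - win.mean()
            out[j, i] = (wz * tz).sum() / (np.sqrt((wz * wz).sum()) * tn)
    return out


@pytest.fixture(scope="module")
def fake_stack(system):
    rng = np.random.default_rng(0)
    planes = rng.uniform(0.1, 1.0, size=(61, 101, 101))
    return S.ImageStack(planes, np.linspace(-3, 3, 61), system.camera_pixel, system.sample_pixel, "z")


class TestTemplateLibrary:
    def test_one_template_per_plane(self, fake_stack):
        lib = S.build_template_library(fake_stack, (50, 50), 51)
        assert len(lib) == 61
        assert lib.size == 51

    def test_even_size_rejected(self, fake_stack):
        with pytest.raises(ValueError):
            S.build_template_library(fake_stack, (50, 50), 50)

    def test_center_pixel_preserved(self, fake_stack):
        lib = S.build_template_library(fake_stack, (40, 60), 51)
        assert lib.templates[7, 25, 25] == fake_stack.planes[7, 40, 60]

    def test_out_of_bounds_crop_rejected(self, fake_stack):
        with pytest.raises(ValueError):
            S.build_template_library(fake_stack, (10, 50), 51)

    def test_nonuniform_labels_rejected(self):
        with pytest.raises(ValueError):
            S.TemplateLibrary(np.zeros((3, 5, 5)), [0.0, 0.1, 0.3], 0.108)


class TestNccMatch:
    def test_agrees_with_direct_sum_oracle(self):
        rng = np.random.default_rng(12)
        target = rng.normal(size=(24, 28))
        template = rng.normal(size=(9, 7))
        surf = S.ncc_match(target, template)
        assert np.allclose(surf.values, brute_force_ncc(target, template), atol=1e-10)

    def test_self_match_scores_one_at_center(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(size=(11, 11))
        surf = S.ncc_match(t, t)
        assert surf.peak_value == pytest.approx(1.0, abs=1e-12)
        assert surf.peak_displacement == (0, 0)

    def test_recovers_constructed_shift(self):
        rng = np.random.default_rng(5)
        template = rng.uniform(size=(15, 15))
        target = np.zeros((41, 41))
        # place template center at (+3, -2) relative to target center
        target[20 + 3 - 7 : 20 + 3 + 8, 20 - 2 - 7 : 20 - 2 + 8] = template
        surf = S.ncc_match(target, template)
        assert surf.peak_displacement == (3, -2)

    def test_affine_intensity_invariance(self):
        rng = np.random.default_rng(8)
        target = rng.uniform(size=(20, 20))
        template = rng.uniform(size=(7, 7))
        a = S.ncc_match(target, template).values
        b = S.ncc_match(3.5 * target + 11.0, template).values
        assert np.allclose(a, b, atol=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            S.ncc_match(np.ones((10, 10)), np.ones((5, 5)))  # zero variance
        with pytest.raises(ValueError):
            S.ncc_match(np.zeros((5, 5)), np.random.default_rng(0).uniform(size=(9, 9)))


class TestSubpixelXY:
    @staticmethod
    def surface_from_quadratic(vx, vy, d=-1.0, f=-1.3, e=0.2):
        yy, xx = np.mgrid[-3:4, -3:4].astype(float)
        vals = 1.0 + d * (xx - vx) ** 2 + e * (xx - vx) * (yy - vy) + f * (yy - vy) ** 2
        return S.CorrelationSurface(vals, (3, 3))

    def test_exact_vertex_recovery(self):
        surf = self.surface_from_quadratic(0.3, -0.2)
        dx, dy = S.subpixel_xy(surf)
        assert dx == pytest.approx(0.3, abs=1e-10)
        assert dy == pytest.approx(-0.2, abs=1e-10)

    def test_symmetric_surface_centers(self):
        surf = self.surface_from_quadratic(0.0, 0.0, e=0.0)
        dx, dy = S.subpixel_xy(surf)
        assert dx == pytest.approx(0.0, abs=1e-12)
        assert dy == pytest.approx(0.0, abs=1e-12)

    def test_saddle_clamps_to_zero(self):
        # an anti-diagonal ridge: the interior argmax survives, but the
        # least-squares quadratic is a hyperbolic paraboloid
        vals = np.array([
            [0.0, 0.5, 0.9],
            [0.5, 1.0, 0.5],
            [0.9, 0.5, 0.0],
        ])
        padded = np.full((5, 5), -1.0)
        padded[1:4, 1:4] = vals
        assert S.subpixel_xy(S.CorrelationSurface(padded, (2, 2))) == (0.0, 0.0)

    def test_border_maximum_warns_and_clamps(self):
        vals = np.zeros((5, 5))
        vals[0, 2] = 1.0
        with pytest.warns(UserWarning):
            assert S.subpixel_xy(S.CorrelationSurface(vals, (2, 2))) == (0.0, 0.0)


class TestSubpixelZ:
    def test_closed_form_vertex(self):
        assert S.subpixel_z([0.8, 1.0, 0.9]) == pytest.approx(
            (0.8 - 0.9) / (2 * (0.8 - 2.0 + 0.9)), abs=1e-12
        )

    def test_symmetric_scores_center(self):
        assert S.subpixel_z([0.9, 1.0, 0.9]) == 0.0

    def test_overshooting_vertex_clamps_to_zero(self):
        assert S.subpixel_z([0.8, 0.9, 0.9999]) == 0.0

    def test_convex_triplet_clamps_to_zero(self):
        assert S.subpixel_z([1.0, 0.5, 1.0]) == 0.0


class TestLocalize:
    def test_unmodified_template_plane_is_exact(self, small_library):
        with pytest.warns(UserWarning):  # 1x1 surface: no sub-pixel fit possible
            r = S.localize(small_library.templates[17], small_library)
        assert r.best_plane == 17
        assert (r.x_px, r.y_px) == (0.0, 0.0)
        # sub-plane refinement may add a (sub-nm) offset from the slightly
        # asymmetric neighbour scores
        assert r.z_um == pytest.approx(small_library.dz_labels[17], abs=1e-3)

    def test_off_grid_depth_interpolated(self, system, design, small_grid, small_library):
        target = S.image_of_point(S.EmitterPose(0, 0, 0.55), system, design, small_grid, 57)
        r = S.localize(target.values, small_library)
        assert r.z_um == pytest.approx(0.55, abs=0.05)

    def test_integer_shift_equivariance(self, small_library):
        canvas = np.zeros((71, 71))
        tpl = small_library.templates[10]
        canvas[35 - 25 : 35 + 26, 35 - 25 : 35 + 26] = tpl  # centred
        shifted = np.zeros((71, 71))
        shifted[35 + 4 - 25 : 35 + 4 + 26, 35 - 6 - 25 : 35 - 6 + 26] = tpl
        r0 = S.localize(canvas, small_library)
        r1 = S.localize(shifted, small_library)
        assert r1.y_px - r0.y_px == pytest.approx(4.0, abs=1e-9)
        assert r1.x_px - r0.x_px == pytest.approx(-6.0, abs=1e-9)

    def test_noisy_target_still_localizes(self, small_library, system, design, small_grid):
        clean = S.image_of_point(S.EmitterPose(0, 0, -0.4), system, design, small_grid, 57)
        noisy = S.add_noise(clean, S.NoiseModel(rng_seed=4))
        r = S.localize(noisy.values, small_library)
        assert r.peak_score < 1.0
        assert abs(r.z_um - (-0.4)) < 0.1


class TestEvaluatePrecision:
    @staticmethod
    def results_from(meas_um, px=0.108):
        return [
            S.LocalizationResult(
                x_px=x / px, y_px=y / px, x_um=x, y_um=y, z_um=z,
                best_plane=0, peak_score=1.0,
            )
            for x, y, z in meas_um
        ]

    def test_perfect_results_have_zero_spread(self):
        truth = np.column_stack([np.zeros(10), np.zeros(10), np.repeat([0.0, 0.1], 5)])
        rep = S.evaluate_precision(self.results_from(truth), truth, 0.108, 0.1)
        assert np.nanmax(rep.sigma_x_nm) == 0
        assert np.nanmax(rep.sigma_z_nm) == 0

    def test_z_stepping_gives_unit_plane_steps(self):
        truth = np.column_stack([np.zeros(10), np.zeros(10), 0.1 * np.arange(10)])
        rep = S.evaluate_precision(self.results_from(truth), truth, 0.108, 0.1)
        assert np.allclose(rep.dz_planes, 1.0)
        assert np.allclose(rep.dx_px, 0.0)
        edges, perc = rep.step_histogram("z")
        assert perc.sum() == pytest.approx(100.0)

    def test_injected_gaussian_error_is_recovered(self):
        rng = np.random.default_rng(21)
        sigma_nm = 20.0
        planes = np.repeat(np.arange(5) * 0.1, 60)
        truth = np.column_stack([np.zeros(300), np.zeros(300), planes])
        meas = truth + rng.normal(0, sigma_nm * 1e-3, truth.shape)
        rep = S.evaluate_precision(self.results_from(meas), truth, 0.108, 0.1)
        se = sigma_nm / np.sqrt(2 * 59)
        for sig in rep.mean_sigmas_nm():
            assert abs(sig - sigma_nm) < 3 * se

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            S.evaluate_precision(self.results_from(np.zeros((3, 3))), np.zeros((4, 3)), 0.108, 0.1)
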