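"""B-spline transformation, warping and adjoint-pair tests."""
import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from respfit.transform import (
    ControlPointGrid,
    cubic_bspline_basis,
    evaluate_displacement,
    image_gradient,
    n_control_points,
    project_gradient_to_cpg,
    warp_pull,
    warp_pull_with_gradient,
    warp_push,
)


class TestEvaluateDisplacement:
    def test_zero_coefficients_give_zero_field(self):
        cpg = ControlPointGrid.zeros((20, 30), 4.0)
        assert not evaluate_displacement(cpg).any()

    def test_partition_of_unity_constant_displacement(self):
        cpg = ControlPointGrid.zeros((33, 21), 5.0)
        cpg.coefficients[0] = 1.25
        cpg.coefficients[1] = -0.75
        field = evaluate_displacement(cpg)
        assert np.allclose(field[0], 1.25, atol=1e-12)
        assert np.allclose(field[1], -0.75, atol=1e-12)

    def test_matches_direct_tensor_sum(self, rng):
        """One probe pixel against the explicit 16-term tensor sum."""
        spacing = 6.0
        cpg = ControlPointGrid.zeros((12, 12), spacing)
        cpg.coefficients[:] = rng.standard_normal(cpg.coefficients.shape)
        y, x = 7, 5
        field = evaluate_displacement(cpg)[:, y, x]
        # direct evaluation: lattice j at position (j-1)*spacing
        expected = np.zeros(2)
        for c in range(2):
            ty, tx = y / spacing, x / spacing
            by, bx = int(np.floor(ty)), int(np.floor(tx))
            wy = cubic_bspline_basis(ty - by)
            wx = cubic_bspline_basis(tx - bx)
            for a in range(4):
                for b in range(4):
                    expected[c] += wy[a] * wx[b] * cpg.coefficients[c, by + a, bx + b]
        assert np.allclose(field, expected, atol=1e-12)

    def test_lattice_covers_image_or_raises(self):
        with pytest.raises(ValueError):
            ControlPointGrid(np.zeros((2, 3, 3)), 5.0, (40, 40))


class TestWarpPull:
    def test_zero_field_is_identity(self, rng):
        img = rng.standard_normal((15, 17))
        out = warp_pull(img, np.zeros((2, 15, 17)))
        np.testing.assert_array_equal(out, img)

    def test_integer_shift_of_ramp(self):
        img = np.tile(np.arange(20.0), (10, 1))
        field = np.zeros((2, 10, 20))
        field[1] = 1.0  # sample one pixel to the right
        out = warp_pull(img, field)
        assert np.allclose(out[:, :-1], img[:, 1:])

    def test_matches_bilinear_oracle_interior(self, rng):
        img = rng.standard_normal((25, 30))
        field = rng.standard_normal((2, 25, 30)) * 2.0
        py = np.arange(25)[:, None] + field[0]
        px = np.arange(30)[None, :] + field[1]
        oracle = map_coordinates(img, [py, px], order=1, mode="constant", cval=0.0)
        interior = (py >= 0) & (py <= 24) & (px >= 0) & (px <= 29)
        out = warp_pull(img, field)
        assert np.allclose(out[interior], oracle[interior], atol=1e-12)

    def test_non_finite_field_rejected(self):
        field = np.zeros((2, 4, 4))
        field[0, 1, 1] = np.nan
        with pytest.raises(ValueError):
            warp_pull(np.zeros((4, 4)), field)

    def test_gradient_is_exact_bilinear_derivative(self, rng):
        img = rng.standard_normal((20, 20))
        field = rng.uniform(-3, 3, (2, 20, 20)) + 0.3  # keep off cell corners
        _, grad = warp_pull_with_gradient(img, field)
        eps = 1e-6
        for comp in range(2):
            shifted = field.copy()
            shifted[comp] += eps
            up = warp_pull(img, shifted)
            shifted[comp] -= 2 * eps
            dn = warp_pull(img, shifted)
            fd = (up - dn) / (2 * eps)
            # away from cell boundaries the interpolant is linear in the offset
            close = np.isclose(fd, grad[comp], atol=1e-4)
            assert close.mean() > 0.97


class TestWarpPush:
    def test_zero_field_identity(self, rng):
        img = rng.standard_normal((9, 11))
        acc, w = warp_push(img, np.zeros((2, 9, 11)), (9, 11))
        np.testing.assert_allclose(acc, img)
        np.testing.assert_allclose(w, 1.0)

    def test_half_pixel_splat_splits_evenly(self):
        img = np.zeros((5, 5))
        img[2, 2] = 8.0
        field = np.zeros((2, 5, 5))
        field[1, 2, 2] = 0.5
        acc, _ = warp_push(img, field, (5, 5))
        assert acc[2, 2] == pytest.approx(4.0)
        assert acc[2, 3] == pytest.approx(4.0)

    def test_adjoint_of_pull(self, rng):
        img = rng.standard_normal((18, 22))
        v = rng.standard_normal((18, 22))
        field = rng.standard_normal((2, 18, 22)) * 4
        lhs = (warp_pull(img, field, pad=0.0) * v).sum()
        acc, _ = warp_push(v, field, (18, 22))
        rhs = (img * acc).sum()
        assert abs(lhs - rhs) <= 1e-10 * max(abs(lhs), 1.0)


class TestImageGradient:
    def test_constant_image(self):
        assert not image_gradient(np.full((6, 6), 3.0)).any()

    def test_linear_ramp(self):
        img = 2.5 * np.arange(10.0)[None, :] * np.ones((8, 1))
        g = image_gradient(img)
        assert np.allclose(g[1], 2.5)
        assert np.allclose(g[0], 0.0)

    def test_probe_matches_central_difference(self, rng):
        img = rng.standard_normal((12, 12))
        g = image_gradient(img)
        assert g[0, 5, 7] == pytest.approx((img[6, 7] - img[4, 7]) / 2)
        assert g[1, 5, 7] == pytest.approx((img[5, 8] - img[5, 6]) / 2)


class TestProjectGradient:
    def test_zero_gradient(self):
        cpg = ControlPointGrid.zeros((16, 16), 4.0)
        out = project_gradient_to_cpg(np.zeros((2, 16, 16)), cpg)
        assert not out.any()

    def test_adjoint_of_evaluate(self, rng):
        cpg = ControlPointGrid.zeros((24, 19), 5.0)
        cpg.coefficients[:] = rng.standard_normal(cpg.coefficients.shape)
        g = rng.standard_normal((2, 24, 19))
        lhs = (evaluate_displacement(cpg) * g).sum()
        rhs = (cpg.coefficients * project_gradient_to_cpg(g, cpg)).sum()
        assert abs(lhs - rhs) <= 1e-10 * abs(lhs)

    def test_delta_gradient_receives_tensor_kernel_weight(self):
        """A unit pixel gradient at a lattice-coincident pixel projects with
        weight B(0)^2 = (4/6)^2 onto the coincident control point."""
        spacing = 4.0
        cpg = ControlPointGrid.zeros((17, 17), spacing)
        g = np.zeros((2, 17, 17))
        g[0, 8, 8] = 1.0  # pixel 8 = lattice position (j-1)*4 with j=3
        out = project_gradient_to_cpg(g, cpg)
        assert out[0, 3, 3] == pytest.approx((4 / 6) ** 2)

    def test_grid_mismatch_raises(self):
        cpg = ControlPointGrid.zeros((16, 16), 4.0)
        with pytest.raises(ValueError):
            project_gradient_to_cpg(np.zeros((2, 10, 16)), cpg)
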