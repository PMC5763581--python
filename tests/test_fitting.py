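"""Unified-fit cost, gradient and recovery tests."""
import numpy as np
import pytest
from scipy import optimize

from respfit.acquisition import AcquisitionSpec
from respfit.correspondence import (
    CorrespondenceModel,
    SurrogateSeries,
    basis_matrix,
    normalize_surrogate,
    temporal_derivative,
)
from respfit.evaluation import dfe_stats
from respfit.fitting import (
    FitConfig,
    SurrogateMotionModel,
    fit_model,
    frame_cost_gradient,
    ssd_and_gradient,
)
from respfit.transform import ControlPointGrid, evaluate_displacement, n_control_points, warp_pull


def _toy_surrogate(values):
    s = SurrogateSeries(np.arange(len(values), dtype=float), np.asarray(values, dtype=float))
    return temporal_derivative(normalize_surrogate(s))


class TestSSD:
    def test_equal_inputs(self):
        c, g = ssd_and_gradient(np.ones((3, 3)), np.ones((3, 3)))
        assert c == 0.0 and not g.any()

    def test_closed_form(self):
        c, g = ssd_and_gradient(np.array([0.0]), np.array([3.0]))
        assert c == 9.0
        np.testing.assert_allclose(g, [6.0])

    def test_gradient_matches_finite_differences(self, rng):
        P = rng.standard_normal((4, 5))
        Q = rng.standard_normal((4, 5))
        _, g = ssd_and_gradient(P, Q)
        eps = 1e-6
        E = np.zeros_like(Q)
        E[2, 3] = eps
        fd = (ssd_and_gradient(P, Q + E)[0] - ssd_and_gradient(P, Q - E)[0]) / (2 * eps)
        assert fd == pytest.approx(g[2, 3], rel=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ssd_and_gradient(np.ones(3), np.ones(4))


class TestFrameCostGradient:
    def _setup(self, rng, small_phantom, spacing=8.0):
        surr = _toy_surrogate([0.1, 0.6, 0.9, 0.4])
        shape = small_phantom.shape
        nc = (n_control_points(shape[0], spacing), n_control_points(shape[1], spacing))
        R = 0.5 * rng.standard_normal((3, 2) + nc)
        model = CorrespondenceModel("linear_sdot", R, spacing, shape)
        return surr, model

    def test_consistent_frame_has_zero_cost(self, rng, small_phantom):
        """A noise-free frame generated from the current model is fitted
        perfectly: zero cost, zero gradient."""
        surr, model = self._setup(rng, small_phantom)
        spec = AcquisitionSpec("slab", row_start=16, n_rows=8)
        Phi = basis_matrix("linear_sdot", surr)
        band = spec.rows(64)
        cpg = ControlPointGrid(model.motion(Phi[2]), model.cpg_spacing, model.image_shape)
        field = evaluate_displacement(cpg, rows=band)
        P = warp_pull(small_phantom, field, rows=band)
        c, g = frame_cost_gradient(2, P, small_phantom, model, surr, spec)
        assert c == pytest.approx(0.0, abs=1e-16)
        assert np.abs(g).max() == pytest.approx(0.0, abs=1e-10)

    def test_static_data_with_zero_model(self, small_phantom):
        surr = _toy_surrogate([0.1, 0.6, 0.9, 0.4])
        spacing = 8.0
        nc = (n_control_points(64, spacing),) * 2
        model = CorrespondenceModel("linear_sdot", np.zeros((3, 2) + nc), spacing, (64, 64))
        spec = AcquisitionSpec("full")
        c, _ = frame_cost_gradient(0, small_phantom, small_phantom, model, surr, spec)
        assert c == 0.0

    def test_gradient_matches_finite_differences(self, rng, small_phantom):
        surr, model = self._setup(rng, small_phantom)
        spec = AcquisitionSpec("slab", row_start=24, n_rows=8)
        P = 100.0 * rng.standard_normal((8, 64))
        _, g = frame_cost_gradient(1, P, small_phantom, model, surr, spec)
        eps = 1e-5
        fd = np.zeros_like(g)
        R = model.coefficients
        probes = [tuple(rng.integers(s) for s in R.shape) for _ in range(12)]
        errs = []
        for idx in probes:
            for sign in (1, -1):
                Rp = R.copy()
                Rp[idx] += sign * eps
                mp = CorrespondenceModel("linear_sdot", Rp, model.cpg_spacing, model.image_shape)
                cval, _ = frame_cost_gradient(1, P, small_phantom, mp, surr, spec)
                fd[idx] += sign * cval
            fd[idx] /= 2 * eps
            if abs(fd[idx]) > 1e-3:
                errs.append(abs(fd[idx] - g[idx]) / abs(fd[idx]))
        assert np.median(errs) < 1e-5


class TestFitModel:
    def test_null_recovery(self, small_phantom, rng):
        """Zero-motion data: the fitted model reproduces ~zero motion."""
        surr = _toy_surrogate([0.2, 0.8, 0.5, 0.1, 0.9])
        frames = [small_phantom + rng.normal(0, 20, small_phantom.shape) for _ in range(5)]
        est = SurrogateMotionModel(kind="linear_sdot", cpg_spacing=8.0, levels=2, max_iter=40)
        est.fit(frames, surr, reference=small_phantom)
        fields = est.predict()
        mean_disp = np.mean([np.hypot(f[0], f[1]).mean() for f in fields])
        assert mean_disp < 0.1

    def test_representable_motion_recovery(self, small_phantom, rng):
        """Noise-free motion generated on the fit lattice is recovered to a
        small fraction of the no-motion error."""
        spacing = 8.0
        surr = _toy_surrogate(np.cos(np.pi * np.arange(6) / 6.0) ** 4)
        Phi = basis_matrix("linear_sdot", surr)
        nc = (n_control_points(64, spacing),) * 2
        R_true = np.zeros((3, 2) + nc)
        R_true[0] = 12.0 * np.stack([  # smooth value-channel maps, +-2 px
            np.outer(np.sin(np.linspace(0, np.pi, nc[0])), np.sin(np.linspace(0, np.pi, nc[1]))),
            np.outer(np.sin(np.linspace(0, np.pi, nc[0])), np.cos(np.linspace(0, np.pi, nc[1]))),
        ]) * 0.25
        truth = CorrespondenceModel("linear_sdot", R_true, spacing, (64, 64))
        frames = []
        for t in range(6):
            cpg = ControlPointGrid(truth.motion(Phi[t]), spacing, (64, 64))
            frames.append(warp_pull(small_phantom, evaluate_displacement(cpg)))
        est = SurrogateMotionModel(kind="linear_sdot", cpg_spacing=spacing, levels=2, max_iter=80)
        est.fit(frames, surr, reference=small_phantom)
        true_fields = [evaluate_displacement(ControlPointGrid(truth.motion(p), spacing, (64, 64)))
                       for p in Phi]
        est_fields = est.predict()
        mask = small_phantom > 100
        masks = [mask] * 6
        fit_mean, _, _ = dfe_stats(true_fields, est_fields, masks)
        nomo_mean, _, _ = dfe_stats(true_fields, [np.zeros_like(f) for f in est_fields], masks)
        assert fit_mean < 0.1 * nomo_mean

    def test_single_frame_equals_pairwise_registration(self, small_phantom, rng):
        """With one frame and a constant basis the unified fit reduces to an
        ordinary pairwise registration; an independently written direct
        optimization over the control points reaches the same optimum."""
        spacing = 16.0
        # a modest smooth deformation of the phantom as the target frame
        nc = (n_control_points(64, spacing),) * 2
        coeff = 1.5 * np.tanh(rng.standard_normal((2,) + nc))
        target = warp_pull(small_phantom,
                           evaluate_displacement(ControlPointGrid(coeff, spacing, (64, 64))))

        est = SurrogateMotionModel(kind="constant", cpg_spacing=spacing, levels=1,
                                   max_iter=150, normalize=False, tol=1e-6)
        est.fit([target], reference=small_phantom)

        def pairwise_cost(x):
            cpg = ControlPointGrid(x.reshape((2,) + nc), spacing, (64, 64))
            warped = warp_pull(small_phantom, evaluate_displacement(cpg))
            return ((warped - target) ** 2).sum()

        res = optimize.minimize(pairwise_cost, np.zeros(2 * nc[0] * nc[1]), method="CG",
                                options={"maxiter": 150})
        assert est.final_cost_ == pytest.approx(res.fun, rel=0.05, abs=1.0)

    def test_cost_trace_non_increasing(self, small_phantom, rng):
        surr = _toy_surrogate([0.2, 0.9, 0.4])
        frames = [small_phantom + rng.normal(0, 30, small_phantom.shape) for _ in range(3)]
        est = SurrogateMotionModel(kind="linear_sdot", cpg_spacing=8.0, levels=2, max_iter=30)
        est.fit(frames, surr, reference=small_phantom)
        for trace in est.cost_trace_:
            diffs = np.diff(trace)
            assert (diffs <= 1e-8 * abs(trace[0])).all()

    def test_requires_reference(self, small_phantom):
        est = SurrogateMotionModel()
        with pytest.raises(ValueError, match="reference"):
            est.fit([small_phantom], np.array([0.0, 1.0]))

    def test_sklearn_param_interface(self):
        est = SurrogateMotionModel(kind="poly2", cpg_spacing=7.0)
        params = est.get_params()
        assert params["kind"] == "poly2"
        est.set_params(cpg_spacing=9.0)
        assert est.cpg_spacing == 9.0

    def test_fit_config_validation(self):
        with pytest.raises(ValueError):
            FitConfig(cpg_spacing=0.5)
        with pytest.raises(ValueError):
            FitConfig(levels=0)


def test_lattice_transfer_preserves_induced_field(rng):
    """Least-squares transfer of coefficients between lattices of different
    spacing keeps the induced displacement field (finer lattices can
    represent everything the coarse one could)."""
    from respfit.fitting import _refine_cpg

    shape = (48, 48)
    coarse = ControlPointGrid.zeros(shape, 12.0)
    coarse.coefficients[:] = rng.standard_normal(coarse.coefficients.shape)
    fine_coef = _refine_cpg(coarse.coefficients[None], 12.0, 6.0, shape)[0]
    fine = ControlPointGrid(fine_coef, 6.0, shape)
    f_c = evaluate_displacement(coarse)
    f_f = evaluate_displacement(fine)
    assert np.abs(f_c - f_f).max() < 0.05 * np.abs(f_c).max()
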