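"""Motion-compensated reconstruction tests."""
import numpy as np
import pytest

from respfit.acquisition import AcquisitionSpec
from respfit.correspondence import CorrespondenceModel, SurrogateSeries, temporal_derivative
from respfit.mcir import MotionCompensatedReconstructor, fit_with_mcir, mcir_average, mcir_superres


def _surr(values):
    return temporal_derivative(
        SurrogateSeries(np.arange(len(values), dtype=float), np.asarray(values, dtype=float)))


class TestAveraging:
    def test_zero_motion_full_frames_reproduce_truth_exactly(self, rng):
        truth = rng.uniform(0, 100, (12, 10))
        frames = [truth.copy() for _ in range(4)]
        specs = [AcquisitionSpec("full", time=float(t)) for t in range(4)]
        recon, holes = mcir_average(frames, specs, out_shape=truth.shape)
        np.testing.assert_allclose(recon, truth, atol=1e-12)
        assert not holes.any()

    def test_two_half_coverage_frames_stitch(self, rng):
        truth = rng.uniform(0, 10, (8, 6))
        specs = [AcquisitionSpec("slab", 0, 4, time=0.0), AcquisitionSpec("slab", 4, 4, time=1.0)]
        frames = [truth[:4], truth[4:]]
        recon, holes = mcir_average(frames, specs, out_shape=truth.shape)
        np.testing.assert_allclose(recon, truth, atol=1e-12)
        assert not holes.any()

    def test_zero_motion_equals_weighted_mean_oracle(self, rng):
        """With no motion the reconstruction is the ordinary per-pixel
        weighted mean of the embedded frames."""
        truth_shape = (10, 7)
        specs = [AcquisitionSpec("slab", 0, 6, time=0.0), AcquisitionSpec("slab", 3, 6, time=1.0)]
        frames = [rng.uniform(0, 5, (6, 7)), rng.uniform(0, 5, (6, 7))]
        recon, _ = mcir_average(frames, specs, out_shape=truth_shape)
        num = np.zeros(truth_shape)
        den = np.zeros(truth_shape)
        for P, s in zip(frames, specs):
            num[s.row_start:s.row_start + 6] += P
            den[s.row_start:s.row_start + 6] += 1
        expected = np.where(den > 0, num / np.maximum(den, 1), 0.0)
        np.testing.assert_allclose(recon, expected, atol=1e-12)

    def test_linear_in_intensities_for_fixed_motion(self, rng):
        shape = (10, 8)
        surr = _surr([0.3, -0.3])
        nc = 2 + 0  # dense model
        R = np.zeros((2, 2) + shape)
        R[0, 0] = 0.4  # small row displacement proportional to s
        model = CorrespondenceModel("linear_sdot_no_offset", R, None, shape)
        specs = [AcquisitionSpec("full", time=0.0), AcquisitionSpec("full", time=1.0)]
        f1 = [rng.uniform(0, 5, shape) for _ in range(2)]
        f2 = [rng.uniform(0, 5, shape) for _ in range(2)]
        r1, _ = mcir_average(f1, specs, model, surr, shape)
        r2, _ = mcir_average(f2, specs, model, surr, shape)
        r12, _ = mcir_average([a + 2 * b for a, b in zip(f1, f2)], specs, model, surr, shape)
        np.testing.assert_allclose(r12, r1 + 2 * r2, atol=1e-9)

    def test_unobserved_rows_are_holes(self):
        specs = [AcquisitionSpec("slab", 0, 3, time=0.0)]
        frames = [np.ones((3, 5))]
        with pytest.warns(UserWarning, match="hole"):
            recon, holes = mcir_average(frames, specs, out_shape=(8, 5), pad=-1.0)
        assert holes[6:].all()
        assert (recon[6:] == -1.0).all()


class TestSuperres:
    def test_constant_image_is_fixed_point(self):
        """Static noise-free thick-slice data of a constant image: the
        residual is zero so no correction is applied."""
        truth = np.full((40, 6), 7.0)
        sigma = 5.0 / 2.355
        # keep every Gaussian support inside the image so the measured rows
        # are exactly the constant (no boundary clipping)
        specs = [AcquisitionSpec("thick_slice", r, 1, profile_sigma=sigma, time=float(r))
                 for r in range(12, 28)]
        from respfit.acquisition import acquire

        frames = [acquire(truth, s) for s in specs]
        recon, residuals = mcir_superres(frames, specs, out_shape=truth.shape, n_iter=3)
        assert np.allclose(recon[12:28], 7.0, atol=1e-8)
        assert residuals[-1] == pytest.approx(0.0, abs=1e-12)

    def test_residual_decreases_on_bar_pattern(self):
        """Static thick-slice data of a two-bar pattern: iterative
        back-projection strictly reduces the data residual at first."""
        truth = np.zeros((24, 8))
        truth[6:9] = 100.0
        truth[14:17] = 100.0
        sigma = 5.0 / 2.355
        specs = [AcquisitionSpec("thick_slice", r, 1, profile_sigma=sigma, time=float(r))
                 for r in range(2, 22)]
        from respfit.acquisition import acquire

        frames = [acquire(truth, s) for s in specs]
        _, residuals = mcir_superres(frames, specs, out_shape=truth.shape, n_iter=6)
        assert len(residuals) >= 3
        assert residuals[1] < residuals[0]
        assert residuals[2] < residuals[1]


class TestFitWithMcir:
    def test_zero_motion_converges_to_plain_average(self, small_phantom, rng):
        frames = [small_phantom + rng.normal(0, 10, small_phantom.shape) for _ in range(4)]
        specs = [AcquisitionSpec("full", time=float(t)) for t in range(4)]
        surr = _surr([0.4, -0.2, 0.3, -0.5])
        model, recon, costs = fit_with_mcir(frames, specs, surr, kind="linear_sdot",
                                            config=None, n_outer=2)
        plain = np.mean(frames, axis=0)
        # the reference stays (essentially) the plain average and the model
        # finds (essentially) no motion
        assert np.abs(recon - plain).mean() < 1.0
        fields = np.abs(model.coefficients).max()
        assert fields < 0.5

    def test_round_costs_decrease_on_slab_data(self, small_phantom, rng):
        """Scaled-down slab dataset: alternation cost trace decreases."""
        from respfit.fitting import FitConfig
        from respfit.transform import warp_pull

        surr = _surr(np.cos(np.pi * np.arange(8) / 4.0) ** 4)
        specs, frames = [], []
        field = np.zeros((2, 64, 64))
        yy = np.linspace(0, np.pi, 64)
        bump = 3.0 * np.outer(np.sin(yy), np.sin(np.linspace(0, np.pi, 64)))
        for t in range(8):
            s_val = surr.values[t, 0]
            field[0] = bump * s_val
            row = (t % 4) * 16
            spec = AcquisitionSpec("slab", row, 16, time=float(t))
            warped = warp_pull(small_phantom, field[:, row:row + 16, :],
                               rows=np.arange(row, row + 16))
            frames.append(warped + rng.normal(0, 20, warped.shape))
            specs.append(spec)
        cfg = FitConfig(cpg_spacing=8.0, max_iterations=30)
        model, recon, costs = fit_with_mcir(frames, specs, surr, kind="linear_sdot",
                                            config=cfg, n_outer=4)
        # the trace never rises by more than the alternation's 1% tolerance
        for a, b in zip(costs, costs[1:]):
            assert b <= 1.01 * a

    def test_estimator_interface(self, small_phantom, rng):
        frames = [small_phantom for _ in range(3)]
        rec = MotionCompensatedReconstructor(kind="linear_sdot", cpg_spacing=16.0,
                                             max_iter=10, n_outer=1)
        rec.fit(frames, np.array([0.1, 0.5, 0.9]))
        assert rec.image_.shape == small_phantom.shape
        assert hasattr(rec, "model_")


@pytest.mark.parametrize("regime", ["slab", "thick_slice"])
def test_no_holes_at_native_resolution(regime):
    """Push-interpolated reconstruction under the true model leaves no
    holes for the canonical regimes at native resolution."""
    from respfit.phantom import PhantomSpec, simulate_dataset

    ds = simulate_dataset(PhantomSpec(regime=regime, seed=0, dfe_target=3.0))
    R = np.stack([ds.r1, ds.r2])
    model = CorrespondenceModel("linear_sdot_no_offset", R, None, ds.shape)
    _, holes = mcir_average(ds.frames, ds.specs, model, ds.surrogate, ds.shape)
    assert not holes.any()
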