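import numpy as np
import pytest

from eerkit import (
    DetectorGeometry,
    ExposureWeightParams,
    RenderSpec,
    Trajectory,
    ValidationError,
    apply_trajectory,
    exposure_weighted_average,
    exposure_weights,
    fraction_centers,
    interpolate_trajectory,
    rasterize,
    residual_blur,
)
from eerkit.motion import critical_exposure
from eerkit.simulate import (
    DecayingDrift,
    ImageSpecimen,
    SimulationConfig,
    TableDrift,
    simulate_movie,
    trajectory_shifts,
)


def fraction_average_knots(true_shifts, fpf):
    """Emulate motion measured from fractions: the fraction-mean position."""
    n = true_shifts.shape[0] // fpf
    return true_shifts[:n * fpf].reshape(n, fpf, 2).mean(axis=1)


class TestInterpolation:
    def test_constant_knots_give_constant_shifts_both_modes(self):
        centers = fraction_centers(100, 10)
        knots = np.tile([2.0, -1.0], (10, 1))
        for mode in ("spline", "piecewise_constant"):
            out = interpolate_trajectory(Trajectory(centers, knots, mode),
                                         100, 10)
            assert np.allclose(out, [2.0, -1.0])

    def test_spline_passes_through_knots(self):
        t = np.array([0.0, 10.0, 25.0, 40.0, 60.0])
        knots = np.column_stack([np.sin(t / 10), np.cos(t / 15)])
        traj = Trajectory(t, knots, "spline")
        out = interpolate_trajectory(traj, 61)
        for i, ti in enumerate(t):
            assert np.allclose(out[int(ti)], knots[i], atol=1e-9)

    def test_cubic_spline_reproduces_linear_motion_exactly(self):
        t = np.arange(5.0, 100.0, 10.0)
        knots = np.column_stack([0.3 * t + 1, -0.1 * t])
        out = interpolate_trajectory(Trajectory(t, knots, "spline"), 120)
        tt = np.arange(120.0)
        expected = np.column_stack([0.3 * tt + 1, -0.1 * tt])
        # includes linear extrapolation beyond the terminal knots
        assert np.allclose(out, expected, atol=1e-8)

    def test_piecewise_constant_replicates_fraction_values(self):
        centers = fraction_centers(12, 4)
        knots = np.array([[1.0, 0], [2.0, 0], [3.0, 0]])
        out = interpolate_trajectory(
            Trajectory(centers, knots, "piecewise_constant"), 12, 4)
        assert np.array_equal(out[:, 0],
                              np.repeat([1.0, 2.0, 3.0], 4))

    def test_smoothing_spline_damps_noisy_knots(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 300.0, 10.0)
        clean = np.column_stack([0.01 * t, np.zeros_like(t)])
        noisy = clean + rng.normal(0, 0.5, clean.shape)
        rough = interpolate_trajectory(Trajectory(t, noisy, "spline"), 300)
        smooth = interpolate_trajectory(
            Trajectory(t, noisy, "spline", smoothing=100.0), 300)
        tt = np.arange(300.0)
        truth = np.column_stack([0.01 * tt, np.zeros_like(tt)])
        assert residual_blur(truth, smooth) < residual_blur(truth, rough)

    def test_single_knot_spline_rejected(self):
        with pytest.raises(ValidationError):
            Trajectory(np.array([0.0]), np.zeros((1, 2)), "spline")

    def test_bad_n_frames_rejected(self):
        traj = Trajectory(np.array([0.0, 1.0]), np.zeros((2, 2)))
        with pytest.raises(ValidationError):
            interpolate_trajectory(traj, 0)


class TestResidualBlur:
    def test_spline_beats_piecewise_on_curved_drift(self):
        n_frames, fpf = 300, 10
        centers = fraction_centers(n_frames, fpf)
        for drift in (DecayingDrift(0.05, -0.03, tau=60),
                      TableDrift(np.column_stack([
                          1e-4 * np.arange(300.0) ** 2,
                          np.zeros(300)]))):
            true = trajectory_shifts(drift, n_frames)
            knots = fraction_average_knots(true, fpf)
            sp = interpolate_trajectory(Trajectory(centers, knots, "spline"),
                                        n_frames)
            pc = interpolate_trajectory(
                Trajectory(centers, knots, "piecewise_constant"), n_frames, fpf)
            assert residual_blur(true, sp) < residual_blur(true, pc)

    def test_equal_on_constant_drift(self):
        n_frames, fpf = 120, 10
        centers = fraction_centers(n_frames, fpf)
        true = np.tile([1.5, -2.0], (n_frames, 1))
        knots = fraction_average_knots(true, fpf)
        sp = interpolate_trajectory(Trajectory(centers, knots, "spline"),
                                    n_frames)
        pc = interpolate_trajectory(
            Trajectory(centers, knots, "piecewise_constant"), n_frames, fpf)
        assert residual_blur(true, sp) == pytest.approx(
            residual_blur(true, pc), abs=1e-9)


def _blob_pattern(size=128):
    yy, xx = np.mgrid[0:size, 0:size]
    blob = 1 + 3 * np.exp(-(((xx - size / 2) / 8.0) ** 2
                            + ((yy - size / 2) / 8.0) ** 2))
    return blob / blob.mean()


def _cc_offset(img, ref):
    cc = np.fft.ifft2(np.fft.fft2(img) * np.conj(np.fft.fft2(ref))).real
    n = img.shape[0]
    peak = np.unravel_index(cc.argmax(), cc.shape)
    return tuple(int((x + n // 2) % n - n // 2) for x in peak)


class TestApplyTrajectory:
    def test_zero_shifts_equal_plain_rasterization(self, geometry16):
        from conftest import random_movie

        movie = random_movie(np.random.default_rng(0), geometry16, 0.05,
                             4).normalized()
        a, _ = rasterize(movie, RenderSpec(u_grid=4))
        b, _ = apply_trajectory(movie, np.zeros((4, 2)), RenderSpec(u_grid=4))
        assert np.array_equal(a, b)

    def test_true_trajectory_inverts_integer_cell_drift_exactly(self):
        g = DetectorGeometry(32, 32, u=4, frame_rate=100.0)
        blob = _blob_pattern(128)
        drift = TableDrift(np.column_stack([
            (np.arange(50) // 10) * 0.25, np.zeros(50)]))
        res = simulate_movie(SimulationConfig(
            g, exposure_rate=20.0, duration=0.5,
            specimen=ImageSpecimen(blob), trajectory=drift, seed=2))
        corrected, _ = apply_trajectory(
            res.movie.normalized(), res.true_shifts,
            RenderSpec(u_grid=4, target_supersample=4))
        assert _cc_offset(corrected, blob) == (0, 0)

    def test_true_trajectory_inverts_smooth_drift_within_one_cell(self):
        g = DetectorGeometry(32, 32, u=4, frame_rate=100.0)
        blob = _blob_pattern(128)
        drift = TableDrift(np.column_stack([
            np.linspace(0, 4, 50), np.linspace(0, -2, 50)]))
        res = simulate_movie(SimulationConfig(
            g, exposure_rate=20.0, duration=0.5,
            specimen=ImageSpecimen(blob), trajectory=drift, seed=2))
        corrected, _ = apply_trajectory(
            res.movie.normalized(), res.true_shifts,
            RenderSpec(u_grid=4, target_supersample=4))
        dy, dx = _cc_offset(corrected, blob)
        assert abs(dx) <= 1 and abs(dy) <= 1
        # uncorrected image sits at the mean drift instead
        raw, _ = rasterize(res.movie.normalized(),
                           RenderSpec(u_grid=4, target_supersample=4))
        dy0, dx0 = _cc_offset(raw, blob)
        assert abs(dx0 - 8) <= 1 and abs(dy0 + 4) <= 1

    def test_negated_trajectory_doubles_the_displacement(self):
        g = DetectorGeometry(32, 32, u=4, frame_rate=100.0)
        blob = _blob_pattern(128)
        drift = TableDrift(np.column_stack([
            np.full(50, 2.0), np.zeros(50)]))
        res = simulate_movie(SimulationConfig(
            g, exposure_rate=20.0, duration=0.5,
            specimen=ImageSpecimen(blob), trajectory=drift, seed=4))
        wrong, _ = apply_trajectory(
            res.movie.normalized(), -res.true_shifts,
            RenderSpec(u_grid=4, target_supersample=4))
        dy, dx = _cc_offset(wrong, blob)
        assert abs(dx - 16) <= 1 and abs(dy) <= 1  # 2 x 2px drift x 4 cells


class TestExposureWeighting:
    def test_zero_exposure_gives_unit_weights(self):
        k = np.linspace(0, 0.5, 32)
        assert np.allclose(exposure_weights(k, 0.0), 1.0)

    def test_monotone_in_exposure_and_frequency(self):
        k = np.linspace(0.01, 0.5, 64)
        w10 = exposure_weights(k, 10.0)
        w20 = exposure_weights(k, 20.0)
        assert np.all(w20 < w10)
        assert np.all(np.diff(w10) < 0)

    def test_closed_form_spot_check(self):
        params = ExposureWeightParams()
        k, n = 0.25, 12.0
        nc = 0.245 * k ** -1.665 + 2.81
        assert exposure_weights(np.array([k]), n, params)[0] == pytest.approx(
            np.exp(-n / (2 * nc)), rel=1e-12)

    def test_zero_frequency_never_attenuates(self):
        assert critical_exposure(np.array([0.0]),
                                 ExposureWeightParams())[0] == np.inf
        assert exposure_weights(np.array([0.0]), 100.0)[0] == 1.0

    def test_single_unexposed_fraction_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((32, 32))
        out = exposure_weighted_average(img[None], [0.0])
        assert np.allclose(out, img, atol=1e-10)

    def test_unit_weights_reduce_to_plain_sum(self):
        rng = np.random.default_rng(1)
        stack = rng.random((3, 16, 16))
        out = exposure_weighted_average(stack, [0.0, 0.0, 0.0])
        assert np.allclose(out, stack.sum(axis=0), atol=1e-10)

    def test_noise_power_propagates_as_summed_squared_weights(self):
        rng = np.random.default_rng(2)
        sigma = 1.0
        n = 128
        stack = rng.normal(0, sigma, (2, n, n))
        exposures = np.array([5.0, 15.0])
        out = exposure_weighted_average(stack, exposures, pixel_size=1.0)
        ky = np.fft.fftfreq(n)
        kx = np.fft.fftfreq(n)
        kgrid = np.sqrt(ky[:, None] ** 2 + kx[None, :] ** 2)
        wsq = sum(exposure_weights(kgrid, float(e)) ** 2 for e in exposures)
        expected_var = wsq.mean() * sigma ** 2
        assert out.var() == pytest.approx(expected_var, rel=0.05)

    def test_sum_sq_normalization_flattens_noise(self):
        rng = np.random.default_rng(3)
        stack = rng.normal(0, 1.0, (2, 128, 128))
        out = exposure_weighted_average(stack, [5.0, 15.0],
                                        normalize="sum_sq")
        assert out.var() == pytest.approx(1.0, rel=0.05)

    def test_descending_exposures_rejected(self):
        with pytest.raises(ValidationError):
            exposure_weighted_average(np.zeros((2, 8, 8)), [2.0, 1.0])
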