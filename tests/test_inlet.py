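"""Inlet boundary conditions: extraction, refinement, Fourier fits,
flux-matched parabolae and the synthetic healthy composition."""

import numpy as np
import pytest

from aortaflow.errors import FittingError, GeometryError
from aortaflow.flowmri import PlaneROI, TimeCurve
from aortaflow.inlet import (
    InletProfileSeries,
    circular_plane_lumen,
    elliptical_plane_lumen,
    extract_inlet,
    fit_fourier,
    parabolic_inlet,
    refine_space_time,
    secondary_fraction,
    solver_timestep,
    synthesize_healthy_inlet,
    two_phase_schedule,
    PlaneLumen,
)
from aortaflow.synth import SynthConfig, generate_acquisition


class TestSolverTimestep:
    @pytest.mark.parametrize(
        "frame,expected",
        [(0.0102, 0.000255), (0.0446252, 0.00111563)],
    )
    def test_reproduces_printed_step_sizes(self, frame, expected):
        assert solver_timestep(frame) == pytest.approx(expected, abs=1e-12)

    def test_subdivision_one_is_identity(self):
        assert solver_timestep(0.04, subdivision=1) == 0.04

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            solver_timestep(-0.01)
        with pytest.raises(ValueError):
            solver_timestep(0.01, subdivision=0)


class TestExtractInlet:
    def test_matches_analytic_parabola(self, steady_noiseless, midplane):
        cfg, acq, truth = steady_noiseless
        series = extract_inlet(acq, midplane)
        f = series.frame(0)
        uu, vv = np.meshgrid(series.u, series.v, indexing="ij")
        r2 = (uu**2 + vv**2) / cfg.lumen_radius**2
        q_mm3 = truth.analytic_flux[0] * 1000.0
        peak = 2.0 * q_mm3 / (np.pi * cfg.lumen_radius**2)
        expected = np.where(r2 <= 1.0, peak * (1.0 - r2), 0.0)
        inside = r2 <= 0.7  # compare away from the partial-volume rim
        got = f.velocity[..., 2]
        assert np.abs(got[inside & f.in_lumen] - expected[inside & f.in_lumen]).max() \
            < 0.1 * peak

    def test_zero_velocity_acquisition_gives_zero_series(self, midplane, steady_noiseless):
        _, acq, _ = steady_noiseless
        from dataclasses import replace
        zero = replace(acq, phase=np.zeros_like(acq.phase))
        series = extract_inlet(zero, midplane)
        assert np.all(series.fields == 0.0)

    def test_extraction_is_idempotent(self, steady_noiseless, midplane):
        _, acq, _ = steady_noiseless
        s1 = extract_inlet(acq, midplane)
        s2 = extract_inlet(acq, midplane)
        np.testing.assert_array_equal(s1.fields, s2.fields)

    def test_plane_missing_lumen_rejected(self, steady_noiseless):
        _, acq, _ = steady_noiseless
        plane = PlaneROI(label="far", origin=np.array([12.0, 12.0, 12.0]),
                         normal=np.array([0.0, 0.0, 1.0]),
                         basis_u=np.array([1.0, 0.0, 0.0]),
                         basis_v=np.array([0.0, 1.0, 0.0]),
                         extent=(2.0, 2.0), sample_spacing=1.0)
        with pytest.raises(GeometryError):
            extract_inlet(acq, plane)


def _brute_force_separable(series, tu, tv, tt):
    """Independent separable-linear interpolation oracle (nearest clamp in
    space, periodic linear in time)."""
    def lin1d(grid, x):
        x = np.clip(x, grid[0], grid[-1])
        i = int(np.clip(np.searchsorted(grid, x) - 1, 0, len(grid) - 2))
        w = (x - grid[i]) / (grid[i + 1] - grid[i])
        return i, w

    times = series.times
    period = series.period
    t = times[0] + np.mod(tt - times[0], period)
    ext_t = np.concatenate([times, [times[0] + period]])
    it = int(np.clip(np.searchsorted(ext_t, t, side="right") - 1, 0, len(ext_t) - 2))
    wt = (t - ext_t[it]) / (ext_t[it + 1] - ext_t[it])
    fa = series.fields[it]
    fb = series.fields[(it + 1) % len(times)]

    out = np.zeros(3)
    iu, wu = lin1d(series.u, tu)
    iv, wv = lin1d(series.v, tv)
    for f, w_t in ((fa, 1 - wt), (fb, wt)):
        patch = f[iu:iu + 2, iv:iv + 2, :]
        val = ((1 - wu) * (1 - wv) * patch[0, 0]
               + (1 - wu) * wv * patch[0, 1]
               + wu * (1 - wv) * patch[1, 0]
               + wu * wv * patch[1, 1])
        out += w_t * val
    return out


class TestRefineSpaceTime:
    @pytest.fixture
    def random_series(self, midplane):
        rng = np.random.default_rng(4)
        u = np.linspace(-8, 8, 9)
        v = np.linspace(-8, 8, 9)
        times = np.linspace(0.0, 0.72, 10)
        fields = rng.normal(size=(10, 9, 9, 3))
        flags = np.ones((9, 9), dtype=bool)
        return InletProfileSeries(plane=midplane, times=times, u=u, v=v,
                                  fields=fields, lumen_flags=flags, period=0.8)

    def test_exact_at_source_nodes_and_times(self, random_series):
        s = random_series
        out = refine_space_time(s, s.u, s.v, s.times)
        np.testing.assert_allclose(out.fields, s.fields, atol=1e-12)

    def test_time_midpoint_is_arithmetic_mean(self, random_series):
        s = random_series
        tm = 0.5 * (s.times[3] + s.times[4])
        out = refine_space_time(s, s.u, s.v, [tm])
        np.testing.assert_allclose(out.fields[0],
                                   0.5 * (s.fields[3] + s.fields[4]), atol=1e-12)

    def test_matches_brute_force_oracle(self, random_series):
        s = random_series
        rng = np.random.default_rng(9)
        tu = rng.uniform(-8, 8, 20)
        tv = rng.uniform(-8, 8, 20)
        tt = rng.uniform(0.0, 1.6, 20)
        for a, b, c in zip(tu, tv, tt):
            out = refine_space_time(s, [a], [b], [c])
            oracle = _brute_force_separable(s, a, b, c)
            np.testing.assert_allclose(out.fields[0, 0, 0], oracle, atol=1e-12)

    def test_empty_targets_rejected(self, random_series):
        with pytest.raises(ValueError):
            refine_space_time(random_series, [], [0.0], [0.0])


class TestFitFourier:
    def test_constant_samples(self):
        t = np.linspace(0, 0.9, 12)
        fs = fit_fourier(t, np.full(12, 3.7), period=1.0, order=3)
        assert fs.a0 == pytest.approx(3.7, abs=1e-10)
        np.testing.assert_allclose(fs.cosine_coeffs, 0.0, atol=1e-10)
        np.testing.assert_allclose(fs.sine_coeffs, 0.0, atol=1e-10)

    def test_pure_sine_recovered_by_discrete_orthogonality(self):
        n, order = 11, 3
        t = np.arange(n) / n
        y = np.sin(2 * np.pi * t)
        fs = fit_fourier(t, y, period=1.0, order=order)
        # oracle: discrete orthogonality of equispaced harmonics
        assert fs.sine_coeffs[0] == pytest.approx(1.0, abs=1e-10)
        others = np.concatenate([[fs.a0], fs.cosine_coeffs, fs.sine_coeffs[1:]])
        np.testing.assert_allclose(others, 0.0, atol=1e-10)

    def test_interpolating_order_has_zero_residual(self):
        rng = np.random.default_rng(6)
        n = 9
        t = np.arange(n) / n
        y = rng.normal(size=n)
        fs = fit_fourier(t, y, period=1.0, order=(n - 1) // 2)
        # oracle: normal equations of the full design give an exact solve
        assert fs.residual_rms < 1e-9
        np.testing.assert_allclose(fs(t), y, atol=1e-9)

    def test_duplicate_times_rejected(self):
        t = np.array([0.0, 0.1, 0.1, 0.2, 0.3])
        with pytest.raises(FittingError):
            fit_fourier(t, np.ones(5), period=1.0, order=2)

    def test_too_few_samples_rejected(self):
        with pytest.raises(FittingError):
            fit_fourier([0.0, 0.1], [1.0, 2.0], period=1.0, order=2)


class TestParabolicInlet:
    def test_circular_centreline_is_twice_mean(self):
        R, Q = 12.5, 25.0
        lum = circular_plane_lumen(R, 0.25)
        prof = parabolic_inlet(lum, Q)
        expected_peak = 2.0 * Q * 1000.0 / (np.pi * R**2)
        assert prof.max() == pytest.approx(expected_peak, rel=0.02)

    def test_zero_flux_gives_zero_field(self):
        lum = circular_plane_lumen(5.0, 0.5)
        assert np.all(parabolic_inlet(lum, 0.0) == 0.0)

    @pytest.mark.parametrize("lumen_factory", [
        lambda: circular_plane_lumen(9.0, 0.3),
        lambda: elliptical_plane_lumen(15.0, 8.0, 0.3),
        lambda: _crescent_lumen(),
    ])
    def test_flux_matched_on_varied_lumens(self, lumen_factory):
        lum = lumen_factory()
        Q = 13.7
        prof = parabolic_inlet(lum, Q)
        flux = prof.sum() * lum.sample_area / 1000.0
        assert flux == pytest.approx(Q, rel=1e-6)
        assert np.all(prof[~lum.in_lumen] == 0.0)

    def test_zero_area_lumen_rejected(self):
        lum = PlaneLumen(u=np.arange(4.0), v=np.arange(4.0),
                         in_lumen=np.zeros((4, 4), dtype=bool))
        with pytest.raises(GeometryError):
            parabolic_inlet(lum, 1.0)


def _crescent_lumen():
    c = np.arange(-10, 10.01, 0.3)
    uu, vv = np.meshgrid(c, c, indexing="ij")
    disc = np.hypot(uu, vv) <= 9.0
    bite = np.hypot(uu - 5.0, vv) <= 5.0
    return PlaneLumen(u=c, v=c, in_lumen=disc & ~bite)


class TestSecondaryFraction:
    def _axial_series(self, midplane, inplane_scale=0.0):
        lum = circular_plane_lumen(8.0, 0.5)
        times = np.linspace(0.0, 0.72, 10)
        nu, nv = len(lum.u), len(lum.v)
        fields = np.zeros((10, nu, nv, 3))
        fields[..., 2] = 100.0
        fields[..., 0] = inplane_scale * 100.0
        fields[:, ~lum.in_lumen, :] = 0.0
        return InletProfileSeries(plane=midplane, times=times, u=lum.u, v=lum.v,
                                  fields=fields, lumen_flags=lum.in_lumen, period=0.8)

    def test_purely_axial_series_has_zero_fraction(self, midplane):
        sched = secondary_fraction(self._axial_series(midplane))
        np.testing.assert_allclose(sched.fraction, 0.0, atol=1e-12)

    def test_equal_inplane_and_axial_speed_gives_one(self, midplane):
        sched = secondary_fraction(self._axial_series(midplane, inplane_scale=1.0))
        np.testing.assert_allclose(sched.fraction, 1.0, atol=1e-12)

    def test_recovers_generator_helical_fraction(self, midplane):
        cfg = SynthConfig(lumen_radius=8.0, grid_spacing=0.8, lumen_length=8.0,
                          n_frames=4, venc=3000.0, noise_sigma_frac=0.0,
                          helical_frac=0.32,
                          flux_waveform=[(0.0, 60.0), (0.4, 60.0)])
        acq, _ = generate_acquisition(cfg)
        # plane sample grid aligned with voxel centres so the wall rim is
        # not blurred by partial-volume interpolation
        plane = PlaneROI(label="inlet", origin=np.array([0.0, 0.0, 4.0]),
                         normal=np.array([0.0, 0.0, 1.0]),
                         basis_u=np.array([1.0, 0.0, 0.0]),
                         basis_v=np.array([0.0, 1.0, 0.0]),
                         extent=(16.0, 16.0), sample_spacing=0.8)
        series = extract_inlet(acq, plane)
        sched = secondary_fraction(series)
        assert sched.fraction[0] == pytest.approx(0.32, abs=0.01)


class TestSynthesizeHealthyInlet:
    @pytest.fixture
    def setup(self, midplane):
        T, n = 0.8, 20
        times = np.arange(n) * T / n
        t_sys = times[4]
        flux = TimeCurve(times=times,
                         values=15.0 + 10.0 * np.cos(2 * np.pi * (times - t_sys) / T),
                         label="flux")
        lum = circular_plane_lumen(12.5, 0.5)
        sched = two_phase_schedule(T, times, t_sys, 0.32, 1.11)
        return times, t_sys, flux, lum, sched

    def test_zero_schedule_gives_purely_axial_series(self, midplane, setup):
        times, t_sys, flux, lum, _ = setup
        sched = two_phase_schedule(0.8, times, t_sys, 0.0, 0.0)
        series = synthesize_healthy_inlet(flux, sched, midplane, lum, times)
        assert np.all(series.fields[..., :2] == 0.0)

    def test_round_trip_recovers_schedule(self, midplane, setup):
        times, _, flux, lum, sched = setup
        series = synthesize_healthy_inlet(flux, sched, midplane, lum, times)
        recovered = secondary_fraction(series)
        np.testing.assert_allclose(recovered.fraction, sched.fraction, atol=0.01)

    def test_constant_flux_zero_schedule_is_time_invariant_poiseuille(self, midplane):
        times = np.arange(8) * 0.1
        flux = TimeCurve(times=times, values=np.full(8, 20.0), label="flux")
        lum = circular_plane_lumen(10.0, 0.5)
        sched = two_phase_schedule(0.8, times, 0.0, 0.0, 0.0)
        series = synthesize_healthy_inlet(flux, sched, midplane, lum, times)
        for i in range(1, 8):
            np.testing.assert_allclose(series.fields[i], series.fields[0], atol=1e-9)
        flux_num = series.fields[0][..., 2].sum() * lum.sample_area / 1000.0
        assert flux_num == pytest.approx(20.0, rel=1e-6)

    def test_composed_flux_matches_fitted_flux(self, midplane, setup):
        times, _, flux, lum, sched = setup
        series = synthesize_healthy_inlet(flux, sched, midplane, lum, times)
        for i, t in enumerate(times):
            axial = series.fields[i] @ midplane.normal
            flux_num = axial.sum() * lum.sample_area / 1000.0
            assert flux_num == pytest.approx(flux.values[i], rel=1e-6)

    def test_negative_flux_reverses_axial_direction(self, midplane):
        times = np.arange(8) * 0.1
        flux = TimeCurve(times=times, values=np.full(8, -10.0), label="flux")
        lum = circular_plane_lumen(10.0, 0.5)
        sched = two_phase_schedule(0.8, times, 0.0, 0.1, 0.1)
        series = synthesize_healthy_inlet(flux, sched, midplane, lum, times)
        axial = series.fields[0] @ midplane.normal
        assert axial[lum.in_lumen].max() < 0.0
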