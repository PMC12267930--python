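import numpy as np
import pytest

from snflag.chamber import (
    ChamberError,
    FluxEstimate,
    GasTimeSeries,
    SlopeEstimate,
    acetylene_at,
    apparent_photosynthesis,
    bootstrap_npe,
    bootstrap_vmax,
    correct_water_dilution,
    estimate_slope,
    ethylene_to_snf,
    max_moving_slope,
    npe_point,
    subtract_background,
    vmax_point,
)
from snflag.config import ChamberConfig, SpeciesParams
from snflag.simulate import ChamberSimSpec, simulate_incubation


def make_series(t, e, phase="acetylene", h2o=0.0, co2=400.0, a0=20_000.0):
    t = np.asarray(t, dtype=float)
    return GasTimeSeries(
        time_s=t,
        ethylene_ppb=np.asarray(e, dtype=float),
        co2_ppm=np.full_like(t, co2) if np.isscalar(co2) else np.asarray(co2, float),
        h2o_frac=np.full_like(t, h2o) if np.isscalar(h2o) else np.asarray(h2o, float),
        a0_ppm=a0,
        phase=np.full(t.size, phase, dtype=object),
    )


class TestGasTimeSeries:
    def test_time_must_increase(self):
        with pytest.raises(ChamberError, match="increasing"):
            make_series([0, 2, 1], [0, 0, 0])

    def test_h2o_range_guard(self):
        with pytest.raises(ChamberError, match="h2o"):
            make_series([0, 1, 2], [0, 0, 0], h2o=0.5)


class TestWaterDilution:
    def test_dry_air_is_identity(self):
        s = make_series([0, 1, 2], [100.0, 100.0, 100.0], h2o=0.0)
        out = correct_water_dilution(s)
        np.testing.assert_array_equal(out.ethylene_ppb, s.ethylene_ppb)

    def test_two_percent_humidity(self):
        s = make_series([0, 1, 2], [100.0, 100.0, 100.0], h2o=0.02)
        out = correct_water_dilution(s)
        np.testing.assert_allclose(out.ethylene_ppb, 100.0 / 0.98, rtol=1e-12)

    def test_cannot_apply_twice(self):
        s = correct_water_dilution(make_series([0, 1, 2], [1.0, 1.0, 1.0], h2o=0.01))
        with pytest.raises(ChamberError, match="already"):
            correct_water_dilution(s)

    def test_strictly_increasing_in_h2o(self):
        h = np.array([0.0, 0.01, 0.02, 0.05])
        s = make_series([0, 1, 2, 3], [100.0] * 4, h2o=h)
        out = correct_water_dilution(s)
        assert np.all(np.diff(out.ethylene_ppb) > 0)

    def test_missing_h2o_rejected(self):
        s = make_series([0, 1, 2], [1.0, 1.0, 1.0])
        s.h2o_frac = np.array([0.0, np.nan, 0.0])
        with pytest.raises(ChamberError, match="missing"):
            correct_water_dilution(s)


class TestBackgroundSubtraction:
    def test_zero_background_changes_nothing(self):
        t = np.arange(-660.0, 300.0)
        phase = np.where(t < 0, "background", "acetylene").astype(object)
        e = np.where(t < 0, 5.0, 5.0 + 0.1 * t)
        s = GasTimeSeries(t, e, np.full_like(t, 400.0), np.zeros_like(t), 20_000.0, phase)
        out = subtract_background(s)
        assert out.background_slope_ppb_s == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(out.ethylene_ppb, e, atol=1e-9)

    def test_construct_then_remove_round_trip(self):
        rng = np.random.default_rng(1)
        t = np.arange(-660.0, 300.0)
        phase = np.where(t < 0, "background", "acetylene").astype(object)
        clean = np.where(t < 0, 0.0, 0.2 * t)
        b = 0.03  # plant background ethylene production, ppb/s
        noisy = clean + b * t + rng.normal(0, 0.05, t.size)
        s = GasTimeSeries(t, noisy, np.full_like(t, 400.0), np.zeros_like(t), 20_000.0, phase)
        out = subtract_background(s)
        assert out.background_slope_ppb_s == pytest.approx(b, rel=0.05)
        ace = out.mask("acetylene")
        np.testing.assert_allclose(out.ethylene_ppb[ace], clean[ace], atol=0.5)

    def test_background_absent_is_error(self):
        s = make_series([0, 1, 2], [0.0, 1.0, 2.0])
        with pytest.raises(ChamberError, match="background"):
            subtract_background(s)

    def test_short_background_warns_with_zero_correction(self):
        t = np.arange(-60.0, 300.0)
        phase = np.where(t < 0, "background", "acetylene").astype(object)
        e = 0.5 * t
        s = GasTimeSeries(t, e, np.full_like(t, 400.0), np.zeros_like(t), 20_000.0, phase)
        with pytest.warns(UserWarning, match="background"):
            out = subtract_background(s)
        assert out.background_slope_ppb_s == 0.0


class TestEstimateSlope:
    def test_exact_line(self):
        t = np.arange(0.0, 400.0)
        s = make_series(t, 2.0 * t + 1.0)
        sl = estimate_slope(s, "ethylene", 100.0, 399.0)
        assert sl.slope == pytest.approx(2.0, rel=1e-12)
        assert sl.slope_sd == pytest.approx(0.0, abs=1e-9)
        # intercept is the fitted value at the window midpoint
        assert sl.intercept == pytest.approx(2.0 * sl.midpoint + 1.0, rel=1e-9)

    def test_se_matches_closed_form(self):
        # slope SE of y = a + b t + N(0, sigma) is sigma / sqrt(Sxx)
        rng = np.random.default_rng(2)
        t = np.arange(0.0, 2000.0)
        sigma = 3.0
        s = make_series(t, 0.5 * t + rng.normal(0, sigma, t.size))
        sl = estimate_slope(s, "ethylene", 0.0, 1999.0)
        sxx = np.sum((t - t.mean()) ** 2)
        assert sl.slope_sd == pytest.approx(sigma / np.sqrt(sxx), rel=0.1)

    def test_too_few_points(self):
        s = make_series([0.0, 1.0], [0.0, 1.0])
        with pytest.raises(ChamberError):
            estimate_slope(s, "ethylene", 0.0, 1.0)

    def test_default_window_is_last_300s(self):
        t = np.arange(0.0, 900.0)
        s = make_series(t, t.copy())
        sl = estimate_slope(s, "ethylene")
        assert sl.window_start == pytest.approx(599.0)
        assert sl.window_end == pytest.approx(899.0)


class TestMaxMovingSlope:
    def test_pure_line_returns_global_slope(self):
        t = np.arange(0.0, 900.0)
        s = make_series(t, 0.7 * t)
        sl = max_moving_slope(s, "ethylene", window_points=480, equilibration_s=120)
        assert sl.slope == pytest.approx(0.7, rel=1e-9)

    def test_window_precedes_decline(self, species):
        spec = ChamberSimSpec(
            true_vmax=2.0, ethylene_noise_ppb=0.0, co2_noise_ppm=0.0,
            decline_onset_s=500.0, decline_rate_per_h=8.0,
        )
        s = subtract_background(correct_water_dilution(simulate_incubation(spec, 0)))
        sl = max_moving_slope(s, "ethylene", window_points=300, equilibration_s=120)
        assert sl.window_end <= 500.0 + 300.0  # mostly pre-decline
        v = vmax_point(sl, sl.intercept, spec.chamber, species, s.a0_ppm, sl.midpoint)
        assert v == pytest.approx(2.0, rel=0.02)

    def test_phase_shorter_than_window(self):
        t = np.arange(0.0, 100.0)
        s = make_series(t, t.copy())
        with pytest.raises(ChamberError, match="window"):
            max_moving_slope(s, "ethylene", window_points=480)


class TestAcetyleneDecay:
    def test_t_zero_and_sealed_chamber(self):
        assert acetylene_at(20_000.0, 0.0045, 0.0) == 20_000.0
        assert acetylene_at(20_000.0, 0.0, 7200.0) == 20_000.0

    def test_one_hour_decay(self):
        assert acetylene_at(20_000.0, 0.0045, 3600.0) == pytest.approx(
            20_000.0 * np.exp(-0.0045), rel=1e-12
        )

    def test_negative_time_rejected(self):
        with pytest.raises(ChamberError):
            acetylene_at(20_000.0, 0.0045, -10.0)


class TestVmaxPoint:
    def test_zero_slope_zero_ethylene(self, chamber_cfg, species):
        sl = SlopeEstimate(0.0, 0.0, 0.0, 0.0, 300.0, 300)
        assert vmax_point(sl, 0.0, chamber_cfg, species, 20_000.0, 150.0) == 0.0

    def test_sealed_chamber_limit(self, chamber_cfg, species):
        # keff = 0: Vmax = slope * (Km/A0 + 1) * n; with Km = A0 that is 2*slope*n
        sl = SlopeEstimate(1e-3, 0.0, 50.0, 0.0, 300.0, 300)
        n = chamber_cfg.molar_content
        slope_ppm_h = 1e-3 * 3600 / 1e3
        v = vmax_point(sl, 50.0, chamber_cfg, species, 20_000.0, 150.0, keff=0.0)
        assert v == pytest.approx(slope_ppm_h * (species.km / 20_000.0 + 1.0) * n, rel=1e-12)
        sp_eq = SpeciesParams("eq", 20_000.0, (10_000.0, 35_000.0), 3.0,
                              "rhizobial", "tropical")
        v2 = vmax_point(sl, 50.0, chamber_cfg, sp_eq, 20_000.0, 150.0, keff=0.0)
        assert v2 == pytest.approx(2.0 * slope_ppm_h * n, rel=1e-12)

    def test_forward_inverse_round_trip(self, noiseless_trace, noiseless_spec, species):
        """Noiseless chamber ODE with Vmax*=2 inverted to within 1%."""
        sl = estimate_slope(noiseless_trace, "ethylene")
        v = vmax_point(sl, sl.intercept, noiseless_spec.chamber, species,
                       noiseless_trace.a0_ppm, sl.midpoint)
        assert v == pytest.approx(2.0, rel=0.01)

    def test_round_trip_at_other_windows(self, noiseless_trace, noiseless_spec, species):
        """The inversion holds at any acetylene-phase evaluation time."""
        for start, end in [(0.0, 300.0), (300.0, 600.0)]:
            sl = estimate_slope(noiseless_trace, "ethylene", start, end)
            v = vmax_point(sl, sl.intercept, noiseless_spec.chamber, species,
                           noiseless_trace.a0_ppm, sl.midpoint)
            assert v == pytest.approx(2.0, rel=0.01)


class TestBootstrapVmax:
    def test_degenerate_distributions_collapse(self, species):
        cfg = ChamberConfig(keff_ci=(0.004499, 0.004501), a0_rel_sd=0.0)
        sp = SpeciesParams(species.species, species.km,
                          (species.km * 0.9999, species.km * 1.0001),
                          species.conversion_factor, species.symbiosis, species.biome)
        sl = SlopeEstimate(1e-3, 0.0, 50.0, 0.0, 300.0, 300)
        s = make_series(np.arange(0.0, 301.0), np.zeros(301))
        est = bootstrap_vmax(sl, s, cfg, sp, n_draws=500, seed=0)
        np.testing.assert_allclose(est.draws, est.point, rtol=1e-2)

    def test_ci_contains_point(self, chamber_cfg, species, noiseless_trace):
        sl = estimate_slope(noiseless_trace, "ethylene")
        est = bootstrap_vmax(sl, noiseless_trace, chamber_cfg, species, 10_000, seed=1)
        assert est.ci[0] <= est.point <= est.ci[1]
        assert est.ci[0] <= np.median(est.draws) <= est.ci[1]

    def test_seed_determinism_and_stability(self, chamber_cfg, species, noiseless_trace):
        sl = estimate_slope(noiseless_trace, "ethylene")
        a = bootstrap_vmax(sl, noiseless_trace, chamber_cfg, species, 10_000, seed=5)
        b = bootstrap_vmax(sl, noiseless_trace, chamber_cfg, species, 10_000, seed=5)
        np.testing.assert_array_equal(a.draws, b.draws)
        c = bootstrap_vmax(sl, noiseless_trace, chamber_cfg, species, 10_000, seed=6)
        assert abs(c.ci[0] - a.ci[0]) / abs(a.ci[0]) < 0.03
        assert abs(c.ci[1] - a.ci[1]) / abs(a.ci[1]) < 0.03

    def test_draw_mean_converges_to_point(self, chamber_cfg, species, noiseless_trace):
        """Monte-Carlo mean ~ all-means evaluation at the study dispersions."""
        sl = estimate_slope(noiseless_trace, "ethylene")
        est = bootstrap_vmax(sl, noiseless_trace, chamber_cfg, species, 100_000, seed=2)
        assert np.mean(est.draws) == pytest.approx(est.point, rel=0.01)

    def test_small_n_draws_warns(self, chamber_cfg, species, noiseless_trace):
        sl = estimate_slope(noiseless_trace, "ethylene")
        with pytest.warns(UserWarning, match="n_draws"):
            bootstrap_vmax(sl, noiseless_trace, chamber_cfg, species, 50, seed=0)


class TestNpe:
    def test_ambient_equilibrium_is_zero_flux(self, chamber_cfg):
        sl = SlopeEstimate(0.0, 0.0, chamber_cfg.ambient_co2, 0.0, 300.0, 300)
        assert npe_point(sl, chamber_cfg.ambient_co2, chamber_cfg) == 0.0
        # sealed empty chamber at ambient: zero for any keff
        for keff in (0.0, 0.0045, 0.1):
            assert npe_point(sl, chamber_cfg.ambient_co2, chamber_cfg, keff=keff) == 0.0

    def test_sealed_chamber_limit(self, chamber_cfg):
        sl = SlopeEstimate(-0.002, 0.0, 390.0, 0.0, 300.0, 300)
        expected = -0.002 * 3600 * chamber_cfg.molar_content
        assert npe_point(sl, 390.0, chamber_cfg, keff=0.0) == pytest.approx(expected, rel=1e-12)

    def test_forward_inverse_uptake_round_trip(self, chamber_cfg):
        spec = ChamberSimSpec(ethylene_noise_ppb=0.0, co2_noise_ppm=0.0, npe=-20.0)
        s = correct_water_dilution(simulate_incubation(spec, 0))
        sl = estimate_slope(s, "co2")
        v = npe_point(sl, sl.intercept, chamber_cfg)
        assert v == pytest.approx(-20.0, rel=0.01)

    def test_ci_width_grows_with_slope_sd(self, chamber_cfg):
        sl1 = SlopeEstimate(-0.002, 1e-5, 390.0, 0.0, 300.0, 300)
        sl2 = SlopeEstimate(-0.002, 4e-5, 390.0, 0.0, 300.0, 300)
        e1 = bootstrap_npe(sl1, chamber_cfg, 5000, seed=0)
        e2 = bootstrap_npe(sl2, chamber_cfg, 5000, seed=0)
        assert (e2.ci[1] - e2.ci[0]) > (e1.ci[1] - e1.ci[0])

    def test_degenerate_draws_equal_point(self):
        cfg = ChamberConfig(keff_ci=(0.004499, 0.004501))
        sl = SlopeEstimate(-0.002, 0.0, 390.0, 0.0, 300.0, 300)
        est = bootstrap_npe(sl, cfg, 500, seed=0)
        np.testing.assert_allclose(est.draws, est.point, rtol=1e-2)


class TestApparentPhotosynthesis:
    def _flux(self, point, draws):
        draws = np.asarray(draws, dtype=float)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        return FluxEstimate(point, draws, (lo, hi), 0.0, "npe_light")

    def test_zero_dark_equals_light(self):
        light = self._flux(-10.0, np.linspace(-12, -8, 100))
        dark = self._flux(0.0, np.zeros(100))
        ap = apparent_photosynthesis(light, dark)
        assert ap.point == light.point
        np.testing.assert_array_equal(ap.draws, light.draws)

    def test_light_equals_dark_gives_zero(self):
        d = np.linspace(-12, -8, 100)
        ap = apparent_photosynthesis(self._flux(-10.0, d), self._flux(-10.0, d))
        assert ap.point == 0.0
        np.testing.assert_array_equal(ap.draws, np.zeros(100))

    def test_paired_difference_matches_brute_force(self):
        rng = np.random.default_rng(0)
        dl = rng.normal(-15.0, 2.0, 4000)
        dd = rng.normal(5.0, 1.0, 4000)
        ap = apparent_photosynthesis(self._flux(-15.0, dl), self._flux(5.0, dd))
        brute = np.percentile([a - b for a, b in zip(dl, dd)], [2.5, 97.5])
        np.testing.assert_allclose(ap.ci, brute, rtol=1e-9)

    def test_mismatched_draws_rejected(self):
        with pytest.raises(ChamberError):
            apparent_photosynthesis(self._flux(0, np.zeros(10)), self._flux(0, np.zeros(20)))


class TestEthyleneToSnf:
    def test_unit_factor_is_identity(self, chamber_cfg):
        est = FluxEstimate(2.0, np.array([1.9, 2.0, 2.1]), (1.9, 2.1), 0.0, "vmax")
        sp = SpeciesParams("x", 100.0, (50.0, 200.0), 1.0, "rhizobial", "tropical")
        out = ethylene_to_snf(est, sp)
        assert out.point == est.point
        np.testing.assert_array_equal(out.draws, est.draws)
        assert out.kind == "snf"

    def test_scaling(self, species):
        est = FluxEstimate(3.5, np.array([3.0, 3.5, 4.0]), (3.0, 4.0), 0.0, "vmax")
        out = ethylene_to_snf(est, species)  # conversion factor 3.5
        assert out.point == pytest.approx(1.0)
        np.testing.assert_allclose(out.draws, est.draws / 3.5)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(Exception):
            SpeciesParams("x", 100.0, (50.0, 200.0), 0.0, "rhizobial", "tropical")
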