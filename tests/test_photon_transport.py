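"""Monte Carlo engine: samplers, boundaries, tallies, depth responses."""

import math

import numpy as np
import pytest
from scipy import integrate, optimize

from shgscatter import (
    DetectionGeometry,
    EmissionParams,
    OpticalProperties,
    SimulationConfig,
    TissueSlab,
    ballistic_focal_weight,
    collimated_transmission,
    propagate_shg_photons,
    sample_free_path,
    sample_hg_deflection,
    simulate_depth_response,
)
from shgscatter.photon_transport import normalize_topk


class TestFreePathSampler:
    def test_closed_form(self):
        assert sample_free_path(100.0, math.exp(-1.0)) == pytest.approx(0.01)

    def test_mean_matches_exponential(self):
        rng = np.random.default_rng(0)
        draws = rng.random(1_000_000)
        mean = np.mean(sample_free_path(50.0, draws))
        # exponential mean 1/mu_t, sd 1/mu_t; 3 sigma sampling band
        assert abs(mean - 0.02) < 3 * 0.02 / 1000.0

    def test_limit_and_domain(self):
        assert sample_free_path(10.0, 1.0 - 1e-12) < 1e-11
        with pytest.raises(ValueError):
            sample_free_path(0.0, 0.5)
        with pytest.raises(ValueError):
            sample_free_path(10.0, 0.0)


def hg_cdf(cos_theta, g):
    """Brute-force HG CDF by numerical integration (independent oracle)."""
    def pdf(mu):
        return 0.5 * (1 - g**2) / (1 + g**2 - 2 * g * mu) ** 1.5

    val, _ = integrate.quad(pdf, -1.0, cos_theta)
    return val


class TestHenyeyGreenstein:
    def test_isotropic_mean(self):
        rng = np.random.default_rng(1)
        mean = np.mean(sample_hg_deflection(0.0, rng.random(1_000_000)))
        assert abs(mean) < 0.002

    def test_mean_cosine_equals_g(self):
        rng = np.random.default_rng(2)
        mean = np.mean(sample_hg_deflection(0.9, rng.random(1_000_000)))
        assert abs(mean - 0.9) < 0.001

    @pytest.mark.parametrize("u", [0.05, 0.3, 0.7, 0.95])
    def test_inverse_cdf_against_numeric_inversion(self, u):
        """Sampler output solves CDF(cos) = u for the HG density."""
        g = 0.9
        sampled = sample_hg_deflection(g, u)
        oracle = optimize.brentq(lambda c: hg_cdf(c, g) - u, -1.0, 1.0, xtol=1e-12)
        assert sampled == pytest.approx(oracle, abs=1e-9)

    def test_domain(self):
        with pytest.raises(ValueError):
            sample_hg_deflection(1.0, 0.5)


class TestBallisticFocalWeight:
    def test_surface_and_closed_form(self, scattering_slab):
        assert ballistic_focal_weight(scattering_slab, 0.0, 988.0) == 1.0
        # mu_s,ex = 50: exp(-2 * 50 * 0.005) = exp(-0.5)
        assert ballistic_focal_weight(scattering_slab, 0.005, 988.0) == pytest.approx(
            math.exp(-0.5)
        )

    def test_transparent_medium(self, transparent_slab):
        for d in [0.0, 0.005, 0.01]:
            assert ballistic_focal_weight(transparent_slab, d, 988.0) == 1.0

    def test_missing_wavelength(self, scattering_slab):
        with pytest.raises(KeyError):
            ballistic_focal_weight(scattering_slab, 0.005, 780.0)


class TestPropagation:
    def test_ballistic_limit_preserves_emission_ratio(
        self, transparent_slab, geometry
    ):
        config = SimulationConfig(depth_grid=[0.005], n_photons=11000, rng_seed=3)
        tally = propagate_shg_photons(
            transparent_slab, 0.005, EmissionParams(988.0, 4.0), geometry, config
        )
        assert tally.detected_forward / tally.detected_backward == pytest.approx(4.0)
        assert tally.escaped_undetected == 0.0

    def test_mirror_symmetry_gives_unit_ratio(self):
        """Intrinsic F/B = 1 with mirror-symmetric slab and detectors."""
        slab = TissueSlab(
            thickness=0.01,
            properties_by_wavelength={
                988.0: OpticalProperties(wavelength=988.0, n=1.4, mu_s=50.0, g=0.9),
                494.0: OpticalProperties(wavelength=494.0, n=1.4, mu_s=150.0, g=0.9),
            },
        )
        geometry = DetectionGeometry(na_backward=0.8, na_forward=0.8)
        config = SimulationConfig(depth_grid=[0.005], n_photons=40000, rng_seed=4)
        tally = propagate_shg_photons(
            slab, 0.005, EmissionParams(988.0, 1.0), geometry, config
        )
        f, b = tally.detected_forward, tally.detected_backward
        # 3 sigma binomial band on the detected split
        p = f / (f + b)
        sigma = math.sqrt(0.25 / (f + b))
        assert abs(p - 0.5) < 3 * sigma

    @pytest.mark.parametrize("mu_a", [0.0, 1.0])
    def test_weight_conservation(self, geometry, mu_a):
        slab = TissueSlab(
            thickness=0.01,
            properties_by_wavelength={
                988.0: OpticalProperties(
                    wavelength=988.0, n=1.4, mu_s=50.0, g=0.9, mu_a=mu_a
                ),
                494.0: OpticalProperties(
                    wavelength=494.0, n=1.4, mu_s=200.0, g=0.9, mu_a=mu_a
                ),
            },
        )
        config = SimulationConfig(depth_grid=[0.005], n_photons=20000, rng_seed=5)
        tally = propagate_shg_photons(
            slab, 0.005, EmissionParams(988.0, 5.0), geometry, config
        )
        assert tally.conservation_error() < 1e-6
        if mu_a > 0:
            assert tally.absorbed > 0

    def test_depth_outside_slab_rejected(self, scattering_slab, geometry):
        config = SimulationConfig(depth_grid=[0.005], n_photons=100, rng_seed=0)
        with pytest.raises(ValueError):
            propagate_shg_photons(
                scattering_slab, 0.02, EmissionParams(988.0, 5.0), geometry, config
            )

    def test_shrinking_forward_na_reduces_forward_detection(self, scattering_slab):
        config = SimulationConfig(depth_grid=[0.005], n_photons=20000, rng_seed=6)
        detected = []
        for na in [0.9, 0.45, 0.1]:
            geometry = DetectionGeometry(na_forward=na)
            tally = propagate_shg_photons(
                scattering_slab, 0.005, EmissionParams(988.0, 5.0), geometry, config
            )
            detected.append(tally.detected_forward)
        assert detected[0] > detected[1] > detected[2]


class TestDepthResponse:
    def test_transparent_slab_flat_response(self, transparent_slab, geometry):
        config = SimulationConfig(
            depth_grid=np.linspace(0, 0.01, 5), n_photons=11000, rng_seed=7
        )
        sim = simulate_depth_response(
            transparent_slab, EmissionParams(988.0, 4.0), geometry, config
        )
        assert np.allclose(sim.measured_fb, 4.0)
        assert np.allclose(sim.normalized_forward, sim.normalized_forward[0])

    def test_efficiency_scales_forward_only(self, scattering_slab, geometry, depth_grid):
        config = SimulationConfig(depth_grid=depth_grid, n_photons=2000, rng_seed=8)
        base = simulate_depth_response(
            scattering_slab, EmissionParams(988.0, 5.0, 1.0), geometry, config
        )
        doubled = simulate_depth_response(
            scattering_slab, EmissionParams(988.0, 5.0, 2.0), geometry, config
        )
        assert np.allclose(doubled.forward_detected, 2.0 * base.forward_detected)
        assert np.allclose(doubled.measured_fb, base.measured_fb, equal_nan=True)
        assert np.allclose(doubled.normalized_forward, base.normalized_forward)

    def test_fixed_seed_bitwise_reproducible(self, scattering_slab, geometry, depth_grid):
        config = SimulationConfig(depth_grid=depth_grid, n_photons=2000, rng_seed=9)
        a = simulate_depth_response(
            scattering_slab, EmissionParams(988.0, 5.0), geometry, config
        )
        b = simulate_depth_response(
            scattering_slab, EmissionParams(988.0, 5.0), geometry, config
        )
        assert np.array_equal(a.forward_detected, b.forward_detected)
        assert np.array_equal(a.backward_detected, b.backward_detected)

    def test_seeds_agree_within_monte_carlo_error(
        self, scattering_slab, geometry, depth_grid
    ):
        config_a = SimulationConfig(depth_grid=depth_grid, n_photons=20000, rng_seed=10)
        config_b = SimulationConfig(depth_grid=depth_grid, n_photons=20000, rng_seed=11)
        a = simulate_depth_response(
            scattering_slab, EmissionParams(988.0, 5.0), geometry, config_a
        )
        b = simulate_depth_response(
            scattering_slab, EmissionParams(988.0, 5.0), geometry, config_b
        )
        # F/B relative MC error per depth ~ sqrt(1/Nf + 1/Nb); stay within 4x
        for fa, fb_, ta, tb in zip(
            a.measured_fb, b.measured_fb, a.tallies, b.tallies
        ):
            rel = math.sqrt(
                1.0 / ta.detected_forward + 1.0 / ta.detected_backward
            )
            assert abs(fa - fb_) / fa < 4 * rel

    def test_depth_trend_matches_high_precision_rerun(
        self, scattering_slab, geometry
    ):
        """Shallow-vs-deep F/B trend agrees with a 10x-photon self-oracle."""
        grid = np.array([0.0, 0.01])
        low = simulate_depth_response(
            scattering_slab,
            EmissionParams(988.0, 5.0),
            geometry,
            SimulationConfig(depth_grid=grid, n_photons=5000, rng_seed=12),
        )
        high = simulate_depth_response(
            scattering_slab,
            EmissionParams(988.0, 5.0),
            geometry,
            SimulationConfig(depth_grid=grid, n_photons=50000, rng_seed=13),
        )
        assert np.sign(np.diff(low.measured_fb)) == np.sign(np.diff(high.measured_fb))

    def test_empty_depth_grid_rejected(self, scattering_slab, geometry):
        config = SimulationConfig(depth_grid=[], n_photons=100, rng_seed=0)
        with pytest.raises(ValueError):
            simulate_depth_response(
                scattering_slab, EmissionParams(988.0, 5.0), geometry, config
            )


class TestBeerLambertOracle:
    @pytest.mark.parametrize("tau", [0.5, 2.0])
    def test_unscattered_fraction(self, tau):
        n = 50000
        frac = collimated_transmission(
            mu_s=tau / 0.01, thickness=0.01, n_photons=n, seed=14
        )
        expected = math.exp(-tau)
        sigma = math.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * sigma


def test_normalize_topk_contract():
    curve = np.array([10.0, 8.0, 6.0, 4.0])
    assert np.allclose(normalize_topk(curve, k=1), curve / 10.0)
    assert np.allclose(normalize_topk(np.full(5, 3.0)), np.ones(5))
    with pytest.raises(ValueError):
        normalize_topk(np.zeros(4))
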