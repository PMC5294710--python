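"""Inversion of depth responses: lookup tables, chi-square fits, sweeps."""

import logging

import numpy as np
import pandas as pd
import pytest

from shgscatter import (
    DetectionGeometry,
    EmissionParams,
    OpticalProperties,
    SimulationConfig,
    TissueSlab,
    build_fb_lookup,
    extract_conversion_efficiency,
    extract_emission,
    extract_fb,
    normalize_efficiency_table,
    simulate_depth_response,
    wavelength_sweep,
)
from shgscatter.depth_profiles import DepthResponse
from shgscatter.shg_extraction import default_fb_grid, interpolate_properties


def sim_to_measured(sim, scale=1.0):
    """Wrap a simulated response as a measured DepthResponse (depths in um)."""
    return DepthResponse(
        depths=sim.depths * 1e4,
        forward=sim.forward_detected * scale,
        backward=sim.backward_detected * scale,
        fb_ratio=sim.measured_fb,
    )


@pytest.fixture(scope="module")
def lookup(request):
    """One shared lookup table for the module (module-scoped: ~3 s)."""
    slab = TissueSlab(
        thickness=0.01,
        properties_by_wavelength={
            988.0: OpticalProperties(wavelength=988.0, n=1.40, mu_s=50.0, g=0.9),
            494.0: OpticalProperties(wavelength=494.0, n=1.40, mu_s=150.0, g=0.9),
        },
    )
    geometry = DetectionGeometry()
    config = SimulationConfig(
        depth_grid=np.linspace(0, 0.01, 11), n_photons=4000, rng_seed=21
    )
    table = build_fb_lookup(slab, geometry, config)
    return slab, geometry, config, table


class TestBuildLookup:
    def test_single_candidate_degenerate_grid(
        self, transparent_slab, geometry
    ):
        config = SimulationConfig(depth_grid=[0.005], n_photons=1000, rng_seed=1)
        table = build_fb_lookup(transparent_slab, geometry, config, fb_grid=[1.0])
        assert len(table.responses) == 1

    def test_ballistic_grid_reproduces_candidates_exactly(
        self, transparent_slab, geometry
    ):
        # n divisible by 3, 6, and 11 so each fb/(1+fb) split is integral
        config = SimulationConfig(
            depth_grid=[0.002, 0.008], n_photons=6600, rng_seed=2
        )
        table = build_fb_lookup(
            transparent_slab, geometry, config, fb_grid=[2.0, 5.0, 10.0]
        )
        for fb, resp in zip([2.0, 5.0, 10.0], table.responses):
            assert np.allclose(resp.measured_fb, fb)

    def test_fingerprint_keyed_on_optical_properties(self, geometry):
        def make(g):
            return TissueSlab(
                thickness=0.01,
                properties_by_wavelength={
                    988.0: OpticalProperties(988.0, n=1.4, mu_s=50.0, g=g),
                    494.0: OpticalProperties(494.0, n=1.4, mu_s=150.0, g=g),
                },
            )

        config = SimulationConfig(depth_grid=[0.005], n_photons=500, rng_seed=3)
        t1 = build_fb_lookup(make(0.90), geometry, config, fb_grid=[2.0])
        t2 = build_fb_lookup(make(0.85), geometry, config, fb_grid=[2.0])
        assert t1.fingerprint != t2.fingerprint

    def test_table_round_trip_via_directory(self, lookup, tmp_path):
        _, _, _, table = lookup
        table.to_dir(tmp_path / "lut")
        loaded = type(table).from_dir(tmp_path / "lut")
        assert loaded.fingerprint == table.fingerprint
        assert np.allclose(loaded.candidate_fb_values, table.candidate_fb_values)
        assert np.allclose(
            loaded.responses[5].measured_fb, table.responses[5].measured_fb
        )


class TestExtractFB:
    def test_identity_curve_gives_zero_chi_square(self, lookup):
        _, _, _, table = lookup
        measured = sim_to_measured(table.responses[20])
        result = extract_fb(measured, table)
        assert result.intrinsic_fb == table.candidate_fb_values[20]
        assert result.chi_square == 0.0
        assert result.accepted

    def test_gross_mismatch_rejected_not_raised(self, lookup):
        _, _, _, table = lookup
        sim = table.responses[10]
        measured = DepthResponse(
            depths=sim.depths * 1e4,
            forward=sim.forward_detected * 1e3,
            backward=sim.backward_detected,
            fb_ratio=sim.measured_fb * 1e3,
        )
        result = extract_fb(measured, table)
        assert not result.accepted

    def test_scale_invariance_of_recovered_fb(self, lookup):
        slab, geometry, _, table = lookup
        config = SimulationConfig(
            depth_grid=np.linspace(0, 0.01, 11), n_photons=8000, rng_seed=77
        )
        sim = simulate_depth_response(slab, EmissionParams(988.0, 5.0), geometry, config)
        r1 = extract_fb(sim_to_measured(sim, scale=1.0), table)
        r2 = extract_fb(sim_to_measured(sim, scale=137.5), table)
        assert r1.intrinsic_fb == r2.intrinsic_fb

    def test_parameter_recovery_within_one_grid_step(self, lookup):
        """Generate with known F/B (independent seeds), re-extract."""
        slab, geometry, _, table = lookup
        grid = table.candidate_fb_values
        hits = 0
        trials = 0
        for rep in range(5):
            for true_fb in (2.0, 5.0, 10.0):
                config = SimulationConfig(
                    depth_grid=np.linspace(0, 0.01, 11),
                    n_photons=8000,
                    rng_seed=1000 + rep,
                )
                sim = simulate_depth_response(
                    slab, EmissionParams(988.0, true_fb), geometry, config
                )
                result = extract_fb(sim_to_measured(sim), table)
                i_true = int(np.argmin(np.abs(np.log(grid) - np.log(true_fb))))
                i_rec = int(np.argmin(np.abs(grid - result.intrinsic_fb)))
                hits += abs(i_rec - i_true) <= 1
                trials += 1
        assert hits == trials

    def test_uncertainty_covers_grid_neighborhood(self, lookup):
        _, _, _, table = lookup
        result = extract_fb(sim_to_measured(table.responses[15]), table)
        assert result.fb_uncertainty >= 0.0

    def test_empty_table_is_state_error(self, lookup):
        _, _, _, table = lookup
        with pytest.raises(ValueError):
            type(table)(
                candidate_fb_values=np.array([]),
                responses=[],
                fingerprint="x",
                excitation_wavelength=988.0,
            )

    def test_measured_depths_must_lie_within_table_span(self, lookup):
        _, _, _, table = lookup
        sim = table.responses[0]
        measured = DepthResponse(
            depths=sim.depths * 1e4 + 50.0,
            forward=sim.forward_detected,
            backward=sim.backward_detected,
            fb_ratio=sim.measured_fb,
        )
        with pytest.raises(ValueError, match="span"):
            extract_fb(measured, table)


class TestEfficiency:
    def test_zero_curve_gives_zero_efficiency(self, lookup):
        slab, geometry, config, _ = lookup
        measured = DepthResponse(
            depths=np.linspace(0, 100, 11),
            forward=np.zeros(11),
            backward=np.zeros(11),
            fb_ratio=np.full(11, np.nan),
        )
        fit = extract_conversion_efficiency(measured, slab, geometry, config, 5.0)
        assert fit.efficiency == 0.0

    def test_known_efficiency_recovered(self, lookup):
        slab, geometry, _, _ = lookup
        extract_config = SimulationConfig(
            depth_grid=np.linspace(0, 0.01, 11), n_photons=8000, rng_seed=5
        )
        recovered = []
        for seed in range(5):
            gen_config = SimulationConfig(
                depth_grid=np.linspace(0, 0.01, 11),
                n_photons=8000,
                rng_seed=3000 + seed,
            )
            sim = simulate_depth_response(
                slab, EmissionParams(988.0, 5.0, relative_efficiency=2.0),
                geometry, gen_config,
            )
            fit = extract_conversion_efficiency(
                sim_to_measured(sim), slab, geometry, extract_config, 5.0
            )
            recovered.append(fit.efficiency)
        assert np.mean(recovered) == pytest.approx(2.0, rel=0.10)

    def test_efficiency_ratio_between_two_tissues(self, lookup):
        """Two samples identical except a 2:1 efficiency ratio."""
        slab, geometry, _, _ = lookup
        extract_config = SimulationConfig(
            depth_grid=np.linspace(0, 0.01, 11), n_photons=8000, rng_seed=6
        )
        ratios = []
        for seed in range(3):
            effs = []
            for eff_true in (1.0, 0.5):
                gen_config = SimulationConfig(
                    depth_grid=np.linspace(0, 0.01, 11),
                    n_photons=8000,
                    rng_seed=4000 + seed,
                )
                sim = simulate_depth_response(
                    slab, EmissionParams(988.0, 5.0, eff_true), geometry, gen_config
                )
                fit = extract_conversion_efficiency(
                    sim_to_measured(sim), slab, geometry, extract_config, 5.0
                )
                effs.append(fit.efficiency)
            ratios.append(effs[0] / effs[1])
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.10)


class TestNormalizeEfficiencyTable:
    def test_global_maximum_becomes_one(self):
        table = pd.DataFrame({"a": [4.0, 2.0], "b": [1.0, 3.0]})
        normed = normalize_efficiency_table(table)
        assert normed.to_numpy().max() == 1.0
        assert normed.loc[0, "a"] == 1.0
        assert normed.loc[1, "b"] == pytest.approx(0.75)

    def test_single_entry(self):
        normed = normalize_efficiency_table(pd.DataFrame({"a": [7.0]}))
        assert normed.loc[0, "a"] == 1.0

    def test_idempotent(self):
        table = pd.DataFrame({"a": [4.0, 2.0, 1.0]})
        once = normalize_efficiency_table(table)
        twice = normalize_efficiency_table(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_efficiency_table(pd.DataFrame({"a": [0.0, 0.0]}))


class TestInterpolation:
    def test_log_linear_mu_s_exact_on_power_law(self):
        props = {
            wl: OpticalProperties(wl, n=1.4, mu_s=100.0 * (wl / 390.0) ** -1.5, g=0.9)
            for wl in (390.0, 535.0, 780.0, 1070.0)
        }
        q = interpolate_properties(props, 445.0)
        assert q.mu_s == pytest.approx(100.0 * (445.0 / 390.0) ** -1.5, rel=1e-3)

    def test_linear_g_and_n(self):
        props = {
            390.0: OpticalProperties(390.0, n=1.40, mu_s=100.0, g=0.88),
            1070.0: OpticalProperties(1070.0, n=1.44, mu_s=50.0, g=0.92),
        }
        q = interpolate_properties(props, 1070.0)
        assert q.g == pytest.approx(0.92) and q.n == pytest.approx(1.44)
        mid = interpolate_properties(props, 646.0)
        assert 0.88 < mid.g < 0.92 and 1.40 < mid.n < 1.44


class TestWavelengthSweep:
    def test_empty_responses_warns_and_returns_empty(self, caplog):
        props = {
            494.0: OpticalProperties(494.0, n=1.4, mu_s=150.0, g=0.9),
            988.0: OpticalProperties(988.0, n=1.4, mu_s=50.0, g=0.9),
        }
        with caplog.at_level(logging.WARNING):
            out = wavelength_sweep(
                {}, props, 0.01, DetectionGeometry(),
                SimulationConfig(depth_grid=[0.005], n_photons=100, rng_seed=0),
            )
        assert out == {}
        assert "empty wavelength list" in caplog.text

    def test_flat_intrinsic_fb_recovered_flat(self):
        """Wavelength-independent F/B comes back constant within the grid."""
        props = {
            wl: OpticalProperties(wl, n=1.4, mu_s=120.0 * (wl / 494.0) ** -1.5, g=0.9)
            for wl in (494.0, 535.0, 988.0, 1070.0)
        }
        geometry = DetectionGeometry()
        grid_depths = np.linspace(0, 0.01, 9)
        responses = {}
        for wl in (988.0, 1070.0):
            slab = TissueSlab(
                thickness=0.01,
                properties_by_wavelength={
                    wl: interpolate_properties(props, wl),
                    wl / 2: interpolate_properties(props, wl / 2),
                },
            )
            sim = simulate_depth_response(
                slab,
                EmissionParams(wl, 4.0),
                geometry,
                SimulationConfig(depth_grid=grid_depths, n_photons=6000, rng_seed=9),
            )
            responses[wl] = sim_to_measured(sim)
        results = wavelength_sweep(
            responses, props, 0.01, geometry,
            SimulationConfig(depth_grid=grid_depths, n_photons=4000, rng_seed=10),
        )
        fbs = [results[wl].intrinsic_fb for wl in (988.0, 1070.0)]
        grid = default_fb_grid()
        step = np.log(grid[1] / grid[0])
        assert abs(np.log(fbs[0]) - np.log(fbs[1])) <= 1.5 * step


def test_refinement_pass_narrows_grid(lookup):
    slab, geometry, _, table = lookup
    config = SimulationConfig(
        depth_grid=np.linspace(0, 0.01, 11), n_photons=8000, rng_seed=55
    )
    sim = simulate_depth_response(slab, EmissionParams(988.0, 5.0), geometry, config)
    coarse = extract_emission(
        sim_to_measured(sim), slab, geometry, config, table=table, refine=False
    )
    fine = extract_emission(
        sim_to_measured(sim), slab, geometry, config, table=table, refine=True
    )
    assert fine.chi_square <= coarse.chi_square
    assert fine.relative_efficiency is not None
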