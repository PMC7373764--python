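"""Batch-culture simulator: dynamics, noise model, reproducibility."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from conftest import random_valid_params
from phenokin.kinetics import haldane_rate
from phenokin.rates import specific_growth_rate
from phenokin.simulate import (
    SimulationScenario,
    _noise_factors,
    generate_rate_points,
    simulate_batch,
    simulate_scenario,
)


def noiseless(**kwargs) -> SimulationScenario:
    kwargs.setdefault("noise_cv", 0.0)
    kwargs.setdefault("replicates", 1)
    return SimulationScenario(**kwargs)


class TestDynamics:
    def test_no_degradation_keeps_substrate_constant(self, growth_params):
        scn = noiseless(
            growth_params=growth_params, degradation_params=None, s0_grid=(100.0,)
        )
        curve = simulate_batch(scn, 100.0)[0]
        assert np.allclose(curve.substrate, 100.0, rtol=1e-12)
        # with S pinned, biomass grows exponentially at exactly mu(s0)
        est = specific_growth_rate(curve)
        assert est.rate == pytest.approx(haldane_rate(100.0, growth_params), rel=1e-6)

    def test_mass_monotonicity_noise_off(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            scn = noiseless(
                growth_params=random_valid_params(rng, "growth"),
                degradation_params=random_valid_params(rng, "degradation"),
                s0_grid=(500.0,),
            )
            curve = simulate_batch(scn, 500.0)[0]
            assert np.all(np.diff(curve.substrate) <= 1e-12)
            assert np.all(np.diff(curve.biomass) >= -1e-12)

    def test_study_parameters_deplete_high_phenol_within_horizon(
        self, growth_params, degradation_params
    ):
        scn = noiseless(
            growth_params=growth_params,
            degradation_params=degradation_params,
            s0_grid=(1000.0,),
        )
        curve = simulate_batch(scn, 1000.0)[0]
        assert np.all(np.diff(curve.substrate) <= 0)
        assert curve.substrate[-1] < 1.0  # exhausted within 120 h
        growing = curve.substrate[:-1] > 0
        assert np.all(np.diff(curve.biomass)[growing] > 0)

    def test_matches_independent_integrator(self, growth_params, degradation_params):
        """The fixed-step RK4 agrees with an adaptive reference integration."""
        scn = noiseless(
            growth_params=growth_params,
            degradation_params=degradation_params,
            s0_grid=(800.0,),
        )
        curve = simulate_batch(scn, 800.0)[0]

        def rhs(_t, y):
            x, s = y
            s = max(s, 0.0)
            return [
                haldane_rate(s, growth_params) * x,
                -haldane_rate(s, degradation_params) * s,
            ]

        ref = solve_ivp(
            rhs,
            (0.0, scn.horizon),
            [scn.x0, 800.0],
            t_eval=curve.times,
            rtol=1e-11,
            atol=1e-12,
            method="DOP853",
        )
        assert np.allclose(curve.biomass, ref.y[0], rtol=1e-6)
        assert np.allclose(curve.substrate, ref.y[1], rtol=1e-6, atol=1e-9)

    def test_halving_internal_step_changes_little(self, growth_params, degradation_params):
        kwargs = dict(
            growth_params=growth_params,
            degradation_params=degradation_params,
            s0_grid=(600.0,),
        )
        coarse = simulate_batch(noiseless(substeps=200, **kwargs), 600.0)[0]
        fine = simulate_batch(noiseless(substeps=400, **kwargs), 600.0)[0]
        assert np.allclose(coarse.biomass, fine.biomass, rtol=1e-6)
        assert np.allclose(coarse.substrate, fine.substrate, rtol=1e-6, atol=1e-12)

    def test_lag_freezes_state_at_high_phenol(self, growth_params, degradation_params):
        scn = noiseless(
            growth_params=growth_params,
            degradation_params=degradation_params,
            s0_grid=(1117.0,),
        )
        curve = simulate_batch(scn, 1117.0)[0]
        # default rule: 12 h lag above 1000 mg/L -> samples at 0 and 12 h frozen
        assert curve.biomass[0] == curve.biomass[1] == scn.x0
        assert curve.substrate[0] == curve.substrate[1] == 1117.0
        assert curve.substrate[2] < 1117.0

    def test_s0_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            simulate_batch(noiseless(), 123.0)


class TestReproducibility:
    def test_same_seed_bit_identical(self):
        a = simulate_batch(SimulationScenario(seed=42), 100.0)
        b = simulate_batch(SimulationScenario(seed=42), 100.0)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.biomass, cb.biomass)
            assert np.array_equal(ca.substrate, cb.substrate)

    def test_different_seeds_differ(self):
        a = simulate_batch(SimulationScenario(seed=1), 100.0)[0]
        b = simulate_batch(SimulationScenario(seed=2), 100.0)[0]
        assert not np.array_equal(a.biomass, b.biomass)

    def test_replicates_share_truth_but_not_noise(self):
        curves = simulate_batch(SimulationScenario(seed=0, replicates=3), 100.0)
        assert len(curves) == 3
        assert not np.array_equal(curves[0].biomass, curves[1].biomass)

    def test_scenario_covers_grid(self):
        scn = SimulationScenario(replicates=2, s0_grid=(41.0, 100.0))
        curves = simulate_scenario(scn)
        assert [(c.s0, c.replicate) for c in curves] == [
            (41.0, "r1"), (41.0, "r2"), (100.0, "r1"), (100.0, "r2"),
        ]


class TestNoiseModel:
    def test_multiplicative_noise_is_unbiased(self):
        rng = np.random.default_rng(123)
        cv = 0.05
        n = 10_000
        factors = _noise_factors(rng, cv, n)
        assert np.all(factors > 0)
        assert abs(factors.mean() - 1.0) < 3 * cv / np.sqrt(n)
        assert factors.std() == pytest.approx(cv, rel=0.05)

    def test_zero_cv_is_exact(self):
        rng = np.random.default_rng(0)
        assert np.all(_noise_factors(rng, 0.0, 5) == 1.0)


class TestRatePoints:
    def test_zero_noise_gives_exact_haldane_values(self, growth_params):
        scn = SimulationScenario(replicates=1, seed=0)
        pts = generate_rate_points(scn, 0.0, "growth")
        for p in pts:
            assert p.rate == haldane_rate(p.s0, growth_params)

    def test_noise_is_seeded_and_reproducible(self):
        a = generate_rate_points(SimulationScenario(seed=9), 0.05, "degradation")
        b = generate_rate_points(SimulationScenario(seed=9), 0.05, "degradation")
        assert [p.rate for p in a] == [p.rate for p in b]
        assert all(p.rate >= 0 for p in a)

    def test_missing_branch_parameters_rejected(self):
        scn = SimulationScenario(degradation_params=None)
        with pytest.raises(ValueError, match="degradation"):
            generate_rate_points(scn, 0.0, "degradation")
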