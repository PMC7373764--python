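"""Log-linear rate extraction and exponential-window selection."""

import numpy as np
import pytest

from phenokin.errors import InsufficientDataError
from phenokin.kinetics import haldane_rate
from phenokin.rates import (
    BatchCurve,
    select_exponential_window,
    specific_degradation_rate,
    specific_growth_rate,
)
from phenokin.simulate import SimulationScenario, simulate_batch


def exponential_curve(rate=0.2, x0=50.0, t_end=48.0, dt=12.0, s0=100.0):
    t = np.arange(0.0, t_end + 1e-9, dt)
    return BatchCurve(s0=s0, times=t, biomass=x0 * np.exp(rate * t))


class TestGrowthRate:
    def test_exact_exponential_recovers_rate_exactly(self):
        est = specific_growth_rate(exponential_curve(rate=0.2))
        assert est.rate == pytest.approx(0.2, rel=1e-10)
        assert est.r2_loglinear == pytest.approx(1.0, abs=1e-12)
        assert est.branch == "growth"

    def test_rate_independent_of_window_on_exact_exponential(self):
        curve = exponential_curve(rate=0.31, t_end=96.0)
        for window in [(0, 48), (24, 96), (12, 60)]:
            est = specific_growth_rate(curve, window=window)
            assert est.rate == pytest.approx(0.31, rel=1e-10)

    def test_constant_biomass_gives_zero_rate_and_zero_r2(self):
        t = np.arange(0, 60, 12.0)
        est = specific_growth_rate(BatchCurve(s0=100, times=t, biomass=np.full(t.size, 7.0)))
        assert est.rate == 0.0
        assert est.r2_loglinear == 0.0

    def test_nonpositive_biomass_rejected(self):
        t = np.array([0.0, 12.0, 24.0])
        with pytest.raises(ValueError, match="logarithm"):
            specific_growth_rate(BatchCurve(s0=10, times=t, biomass=[1.0, 0.0, 2.0]))

    def test_too_few_points_in_window(self):
        with pytest.raises(InsufficientDataError):
            specific_growth_rate(exponential_curve(), window=(0.0, 12.0))

    def test_growth_rate_nonnegative_when_biomass_nondecreasing(self):
        t = np.arange(0, 72, 12.0)
        x = np.array([10, 12, 20, 21, 40, 41.0])
        est = specific_growth_rate(BatchCurve(s0=50, times=t, biomass=x))
        assert est.rate >= 0


class TestDegradationRate:
    def test_exact_first_order_decay(self):
        t = np.arange(0.0, 60 + 1e-9, 12.0)
        curve = BatchCurve(s0=1000, times=t, substrate=1000 * np.exp(-0.05 * t))
        est = specific_degradation_rate(curve)
        assert est.rate == pytest.approx(0.05, rel=1e-10)
        assert est.branch == "degradation"

    def test_constant_substrate_gives_zero(self):
        t = np.arange(0, 48, 12.0)
        est = specific_degradation_rate(BatchCurve(s0=200, times=t, substrate=np.full(t.size, 200.0)))
        assert est.rate == 0.0

    def test_points_below_detection_are_excluded(self):
        t = np.arange(0.0, 72 + 1e-9, 12.0)
        s = 1000 * np.exp(-0.05 * t)
        s[-2:] = 1.0  # below 1% of s0: exhausted, would bend the log line
        est = specific_degradation_rate(BatchCurve(s0=1000, times=t, substrate=s))
        assert est.n_points == t.size - 2
        assert est.rate == pytest.approx(0.05, rel=1e-10)

    def test_fully_exhausted_series_is_an_error(self):
        t = np.array([0.0, 12.0, 24.0])
        with pytest.raises(InsufficientDataError, match="detection"):
            specific_degradation_rate(BatchCurve(s0=1000, times=t, substrate=[5.0, 4.0, 3.0]))

    def test_rate_nonnegative_when_substrate_nonincreasing(self):
        t = np.arange(0, 72, 12.0)
        s = np.array([500, 400, 350, 100, 60, 50.0])
        est = specific_degradation_rate(BatchCurve(s0=500, times=t, substrate=s))
        assert est.rate >= 0


class TestWindowSelection:
    def test_lag_phase_is_excluded(self):
        # flat 12 h lag, then clean exponential growth: the selected window
        # must start where the exponential does
        t = np.arange(0.0, 96 + 1e-9, 12.0)
        x = np.where(t < 12.0, 50.0, 50.0 * np.exp(0.2 * (t - 12.0)))
        sel = select_exponential_window(BatchCurve(s0=1100, times=t, biomass=x), "growth")
        assert sel.t_start == 12.0
        assert sel.t_end == 96.0
        assert not sel.low_quality
        est = specific_growth_rate(
            BatchCurve(s0=1100, times=t, biomass=x), window=(sel.t_start, sel.t_end)
        )
        assert est.rate == pytest.approx(0.2, rel=1e-10)

    def test_pure_exponential_keeps_full_series(self):
        curve = exponential_curve(rate=0.15, t_end=120.0)
        sel = select_exponential_window(curve, "growth")
        assert (sel.t_start, sel.t_end) == (0.0, 120.0)
        assert sel.n_points == curve.times.size

    def test_pure_noise_flagged_low_quality(self):
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 120 + 1e-9, 12.0)
        x = rng.uniform(10, 20, t.size)
        # 3-point windows can be spuriously collinear in pure noise, so ask
        # for a window of at least 5 points
        sel = select_exponential_window(
            BatchCurve(s0=100, times=t, biomass=x), "growth", min_points=5
        )
        assert sel.low_quality

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 120 + 1e-9, 12.0)
        x = 30 * np.exp(0.1 * t) * rng.lognormal(0, 0.1, t.size)
        curve = BatchCurve(s0=500, times=t, biomass=x)
        sel = select_exponential_window(curve, "growth")
        # independent brute force over every contiguous window of >= 3 points
        from scipy.stats import linregress

        best = max(
            (
                (round(linregress(t[i:j], np.log(x[i:j])).rvalue ** 2, 12), j - i, -t[i], (t[i], t[j - 1]))
                for i in range(t.size - 2)
                for j in range(i + 3, t.size + 1)
            ),
        )
        assert (sel.t_start, sel.t_end) == best[3]

    def test_needs_at_least_four_points(self):
        t = np.array([0.0, 12.0, 24.0])
        with pytest.raises(InsufficientDataError):
            select_exponential_window(
                BatchCurve(s0=10, times=t, biomass=[1.0, 2.0, 4.0]), "growth"
            )


class TestAgainstSimulator:
    """Short-window slope estimates converge to the instantaneous Haldane rate."""

    def test_growth_rate_matches_haldane_at_s0(self, growth_params, degradation_params):
        scn = SimulationScenario(
            growth_params=growth_params,
            degradation_params=degradation_params,
            s0_grid=(100.0,),
            noise_cv=0.0,
            replicates=1,
            sampling_interval=0.02,
            horizon=0.06,
        )
        curve = simulate_batch(scn, 100.0)[0]
        est = specific_growth_rate(curve)
        assert est.rate == pytest.approx(haldane_rate(100.0, growth_params), rel=0.02)

    def test_degradation_rate_matches_haldane_at_s0(self, growth_params, degradation_params):
        scn = SimulationScenario(
            growth_params=growth_params,
            degradation_params=degradation_params,
            s0_grid=(60.0,),
            noise_cv=0.0,
            replicates=1,
            sampling_interval=0.05,
            horizon=0.15,
        )
        curve = simulate_batch(scn, 60.0)[0]
        est = specific_degradation_rate(curve)
        assert est.rate == pytest.approx(haldane_rate(60.0, degradation_params), rel=0.02)


class TestBatchCurveValidation:
    def test_times_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            BatchCurve(s0=10, times=[0.0, 12.0, 12.0], biomass=[1, 2, 3])

    def test_some_series_required(self):
        with pytest.raises(ValueError):
            BatchCurve(s0=10, times=[0.0, 12.0, 24.0])

    def test_s0_mismatch_warns(self):
        with pytest.warns(UserWarning, match="10%"):
            BatchCurve(s0=100.0, times=[0.0, 12, 24], substrate=[80.0, 50, 20])

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            BatchCurve(s0=10, times=[0.0, 12, 24], biomass=[1.0, -2.0, 3.0])
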