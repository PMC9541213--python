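"""Shape fitting, model comparison and the bootstrap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acclimate.core import lambda_point_exponential
from acclimate.errors import BootstrapError, FitError, NoDeclineError
from acclimate.fitting import (
    bootstrap_lambda,
    compare_models,
    fit_exponential,
    fit_segmented_linear,
)
from acclimate.simulate import SimulationConfig, default_times, simulate_time_course

from conftest import grid_search_lambda, make_dataset, make_series


class TestFitExponential:
    def test_recovers_generating_rate_on_noiseless_data(
            self, noiseless_exponential_series):
        fit = fit_exponential(noiseless_exponential_series)
        assert fit.lam == pytest.approx(0.1, rel=1e-6)
        assert fit.rse <= 1e-8
        assert fit.converged
        assert fit.half_time == pytest.approx(math.log(2.0) / fit.lam)

    def test_rse_degrees_of_freedom_identity(self):
        t = np.array([0.0, 2.0, 5.0, 9.0, 14.0])
        d = np.array([1.0, 0.83, 0.55, 0.43, 0.28])
        fit = fit_exponential(make_series(t, d))
        ss = float(np.sum(np.square(fit.residuals)))
        assert fit.rse**2 * (fit.n_points - 1) == pytest.approx(ss, rel=1e-12)

    def test_no_decline_is_an_error(self):
        with pytest.raises(NoDeclineError):
            fit_exponential(make_series([0.0, 3.0, 6.0], [1.0, 1.01, 1.2]))

    def test_fitted_rate_lies_between_extreme_point_estimates(self):
        t = np.array([0.0, 2.0, 4.0, 8.0, 16.0])
        d = np.array([1.0, 0.75, 0.62, 0.35, 0.15])
        fit = fit_exponential(make_series(t, d))
        pts = [lambda_point_exponential(di, ti) for ti, di in zip(t[1:], d[1:])]
        assert min(pts) <= fit.lam <= max(pts)

    def test_rse_invariant_to_point_order(self):
        t = np.array([0.0, 2.0, 5.0, 9.0])
        d = np.array([1.0, 0.8, 0.5, 0.3])
        base = fit_exponential(make_series(t, d))
        perm = np.array([2, 0, 3, 1])
        shuffled = make_series(t, d)
        shuffled.times, shuffled.d = t[perm], d[perm]  # unsorted on purpose
        other = fit_exponential(shuffled)
        assert other.rse == pytest.approx(base.rse, rel=1e-9)
        assert other.lam == pytest.approx(base.lam, rel=1e-9)


class TestFitSegmentedLinear:
    def test_recovers_generating_rate_on_noiseless_data(
            self, noiseless_linear_series):
        fit = fit_segmented_linear(noiseless_linear_series)
        assert fit.lam == pytest.approx(0.05, rel=1e-6)
        assert fit.rse <= 1e-8
        assert fit.half_time == pytest.approx(10.0, rel=1e-6)

    def test_plateau_beyond_breakpoint_is_zero_not_negative(self):
        # points past t = 1/lam must be compared to 0, not to 1 - lam t
        t = np.array([0.0, 5.0, 10.0, 40.0, 80.0])
        d = np.array([1.0, 0.75, 0.5, 0.0, 0.0])
        fit = fit_segmented_linear(make_series(t, d))
        assert fit.lam == pytest.approx(0.05, rel=1e-6)
        assert fit.rse <= 1e-8


@st.composite
def noisy_series(draw):
    n = draw(st.integers(4, 9))
    lam = draw(st.floats(0.02, 0.5))
    sigma = draw(st.floats(0.0, 0.15))
    seed = draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0.5, 3.0 / lam, size=n - 1))
    t = np.concatenate([[0.0], t])
    d = np.exp(-lam * t) + sigma * rng.standard_normal(n)
    d[0] = 1.0
    return make_series(np.round(t, 6), d)


@given(noisy_series())
@settings(max_examples=30, deadline=None)
def test_both_fitters_match_brute_force_grid_search(series):
    """The bounded 1-D optimizer lands on the global SSE minimum found by an
    exhaustive log-spaced grid, within one grid step, for both shapes."""
    for shape, fitter in (("exponential", fit_exponential),
                          ("linear", fit_segmented_linear)):
        try:
            fit = fitter(series)
        except FitError:
            continue
        lam_grid, grid = grid_search_lambda(shape, series.times, series.d,
                                            n=20_000)
        step = grid[1] / grid[0]
        if grid[0] < fit.lam < grid[-1] * 0.99:
            within_step = lam_grid / step <= fit.lam <= lam_grid * step
            t, d = series.times, series.d
            sse_fit = np.sum((d - (np.exp(-fit.lam * t) if shape == "exponential"
                                   else np.maximum(1 - fit.lam * t, 0))) ** 2)
            sse_grid = np.sum((d - (np.exp(-lam_grid * t) if shape == "exponential"
                                    else np.maximum(1 - lam_grid * t, 0))) ** 2)
            # flat-SSE draws: fitted minimum must be at least as deep
            assert within_step or sse_fit <= sse_grid * (1 + 1e-12)


class TestCompareModels:
    def test_noiseless_exponential_selects_exponential(
            self, noiseless_exponential_series):
        cmp = compare_models(noiseless_exponential_series)
        assert cmp.selected == "exponential"
        assert cmp.rse_margin > 0
        assert cmp.rse_margin == pytest.approx(
            cmp.fit_linear.rse - cmp.fit_exponential.rse)

    def test_noiseless_linear_selects_linear(self, noiseless_linear_series):
        cmp = compare_models(noiseless_linear_series)
        assert cmp.selected == "linear"
        assert cmp.rse_margin < 0

    def test_exact_tie_reported_as_indistinguishable(self):
        # two points anchor + one observation: both one-parameter curves
        # pass exactly through (t1, d1), so the RSEs tie at zero
        series = make_series([0.0, 10.0], [1.0, 0.5])
        cmp = compare_models(series)
        assert cmp.selected == "indistinguishable"
        assert cmp.fit_exponential.rse == pytest.approx(0.0, abs=1e-7)
        assert cmp.fit_linear.rse == pytest.approx(0.0, abs=1e-7)

    def test_fit_failure_names_the_failing_shape(self):
        series = make_series([0.0, 3.0, 6.0], [1.0, 1.05, 1.1])
        with pytest.raises(FitError, match="exponential"):
            compare_models(series)


class TestBootstrap:
    @pytest.fixture()
    def dataset(self):
        cfg = SimulationConfig(lam_true=0.1, noise_sd=0.05, n_replicates=5,
                               times=default_times(0.1), seed=42)
        return simulate_time_course(cfg)

    def test_zero_noise_gives_degenerate_interval(self):
        cfg = SimulationConfig(lam_true=0.1, noise_sd=0.0, n_replicates=3, seed=0)
        ds = simulate_time_course(cfg)
        b = bootstrap_lambda(ds, "exponential", n_boot=50, seed=1)
        assert b.ci_low == pytest.approx(b.lam_hat, rel=1e-9)
        assert b.ci_high == pytest.approx(b.lam_hat, rel=1e-9)

    def test_same_seed_is_bit_identical(self, dataset):
        b1 = bootstrap_lambda(dataset, "exponential", n_boot=100, seed=7)
        b2 = bootstrap_lambda(dataset, "exponential", n_boot=100, seed=7)
        assert b1.lam_hat == b2.lam_hat
        assert b1.ci_low == b2.ci_low and b1.ci_high == b2.ci_high
        np.testing.assert_array_equal(b1.samples, b2.samples)

    def test_different_seed_moves_the_interval(self, dataset):
        b1 = bootstrap_lambda(dataset, "exponential", n_boot=100, seed=7)
        b2 = bootstrap_lambda(dataset, "exponential", n_boot=100, seed=8)
        assert not np.array_equal(b1.samples, b2.samples)

    def test_point_estimate_inside_interval(self, dataset):
        b = bootstrap_lambda(dataset, "exponential", n_boot=200, seed=3)
        assert b.ci_low <= b.lam_hat <= b.ci_high
        assert not b.lam_hat_outside_ci

    def test_single_replicate_time_points_are_rejected(self):
        ds = make_dataset({0.0: [1.0], 5.0: [0.6], 10.0: [0.3]},
                          new=[0.0, 0.01])
        with pytest.raises(BootstrapError, match="replicates"):
            bootstrap_lambda(ds, "exponential", n_boot=10, seed=0)
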