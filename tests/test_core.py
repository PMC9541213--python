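"""Normalization to D and the closed-form rate relations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acclimate.core import (
    half_time,
    lambda_point_exponential,
    lambda_point_linear,
    normalize_series,
)
from acclimate.errors import (
    DesignError,
    EstimatorDomainError,
    NonMonotoneWarning,
    NoPlasticResponseError,
    SingleControlWarning,
)

from conftest import make_dataset


class TestNormalizeSeries:
    def test_midpoint_and_endpoints_of_the_ratio(self):
        # z0=10, z_inf=20: shifted mean 15 is half-way -> D = 0.5
        ds = make_dataset({0.0: [10.0], 5.0: [15.0], 10.0: [20.0]},
                          new=[20.0, 20.0])
        s = normalize_series(ds)
        assert s.z0 == 10.0 and s.z_inf == 20.0
        assert s.d == pytest.approx([1.0, 0.5, 0.0])

    def test_noiseless_exponential_trajectory(self):
        # z(t) = z_inf + (z0 - z_inf) exp(-0.1 t) at t = 0, 5, 10
        z0, zinf, lam = 10.0, 20.0, 0.1
        ds = make_dataset(
            {t: [zinf + (z0 - zinf) * math.exp(-lam * t)] for t in (0.0, 5.0, 10.0)},
            new=[zinf])
        s = normalize_series(ds)
        assert s.d == pytest.approx([1.0, math.exp(-0.5), math.exp(-1.0)])
        assert s.d[1] == pytest.approx(0.6065, abs=1e-4)
        assert s.d[2] == pytest.approx(0.3679, abs=1e-4)

    def test_times_rereferenced_to_earliest_shifted_measurement(self):
        ds = make_dataset({2.0: [10.0], 7.0: [15.0]}, new=[20.0])
        s = normalize_series(ds)
        assert s.times[0] == 0.0 and s.times[1] == 5.0
        assert s.d[0] == 1.0

    def test_d_from_per_time_point_means(self):
        ds = make_dataset({0.0: [9.0, 11.0], 5.0: [14.0, 16.0]}, new=[20.0, 20.0])
        s = normalize_series(ds)
        assert s.d == pytest.approx([1.0, 0.5])
        assert list(s.n_per_point) == [2, 2]

    def test_missing_new_control_is_a_design_error(self):
        ds = make_dataset({0.0: [10.0], 5.0: [15.0]}, initial=[10.0])
        with pytest.raises(DesignError, match="control group"):
            normalize_series(ds)

    def test_last_shifted_fallback_warns_about_single_control(self):
        ds = make_dataset({0.0: [10.0], 5.0: [15.0], 30.0: [20.0]})
        with pytest.warns(SingleControlWarning):
            s = normalize_series(ds, zinf_policy="last_shifted")
        assert s.z_inf == 20.0

    def test_no_detectable_response_is_rejected(self):
        ds = make_dataset({0.0: [10.0, 10.2], 5.0: [10.1, 9.9]},
                          new=[10.0, 10.2])
        with pytest.raises(NoPlasticResponseError):
            normalize_series(ds)

    def test_non_monotone_series_warns(self):
        # clear drop then clear rebound, noise-free replicates
        ds = make_dataset({0.0: [10.0, 10.0], 5.0: [14.0, 14.0],
                           10.0: [11.0, 11.0]}, new=[20.0, 20.0])
        with pytest.warns(NonMonotoneWarning):
            normalize_series(ds)

    def test_initial_control_z0_policy(self):
        ds = make_dataset({0.0: [10.5], 5.0: [15.0]}, initial=[10.0, 10.0],
                          new=[20.0, 20.0])
        s = normalize_series(ds, z0_policy="initial_control")
        assert s.z0 == 10.0
        assert s.d[0] == pytest.approx((10.5 - 20.0) / (10.0 - 20.0))

    def test_replicate_level_mode_emits_one_point_per_replicate(self):
        ds = make_dataset({0.0: [10.0, 10.0], 5.0: [14.0, 16.0]}, new=[20.0, 20.0])
        s = normalize_series(ds, replicate_level=True)
        assert len(s) == 4
        assert s.d[2:] == pytest.approx([0.6, 0.4])


class TestPointEstimators:
    @pytest.mark.parametrize("d, t, lam", [
        (math.exp(-1.0), 1.0, 1.0),
        (1.0, 5.0, 0.0),
        (0.5, math.log(2.0) / 0.03021, 0.03021),
    ])
    def test_exponential_estimator(self, d, t, lam):
        assert lambda_point_exponential(d, t) == pytest.approx(lam, rel=1e-12)

    @pytest.mark.parametrize("d, t, lam", [
        (0.5, 10.0, 0.05),
        (1.0, 7.0, 0.0),
        (0.0, 4.0, 0.25),
    ])
    def test_linear_estimator(self, d, t, lam):
        assert lambda_point_linear(d, t) == pytest.approx(lam, rel=1e-12)

    def test_exponential_domain_errors(self):
        with pytest.raises(EstimatorDomainError):
            lambda_point_exponential(0.0, 1.0)
        with pytest.raises(EstimatorDomainError):
            lambda_point_exponential(-0.1, 1.0)
        with pytest.raises(EstimatorDomainError):
            lambda_point_exponential(0.5, 0.0)
        with pytest.raises(EstimatorDomainError):
            lambda_point_exponential(1.2, 1.0)  # D > 1 needs opt-in

    def test_overshoot_opt_in_returns_negative_rate_with_warning(self):
        with pytest.warns(UserWarning):
            lam = lambda_point_exponential(1.2, 2.0, allow_negative=True)
        assert lam == pytest.approx(-math.log(1.2) / 2.0)

    def test_linear_domain_errors(self):
        with pytest.raises(EstimatorDomainError):
            lambda_point_linear(0.5, 0.0)
        with pytest.raises(EstimatorDomainError):
            lambda_point_linear(1.5, 1.0)

    @given(st.floats(0.01, 0.999), st.floats(0.1, 100.0))
    @settings(max_examples=100, deadline=None)
    def test_exponential_estimate_exceeds_linear_for_interior_d(self, d, t):
        # -ln D > 1 - D on (0, 1), so the exponential rate is always larger
        assert lambda_point_exponential(d, t) > lambda_point_linear(d, t)

    def test_estimators_agree_in_the_no_change_limit(self):
        for d in (1 - 1e-6, 1 - 1e-9):
            le = lambda_point_exponential(d, 3.0)
            ll = lambda_point_linear(d, 3.0)
            assert le == pytest.approx(ll, rel=1e-5)
            assert le < 1e-5


class TestHalfTime:
    def test_published_conversion(self):
        # lambda = 0.03021 per h corresponds to a 22.9 h half-time (3 s.f.)
        ht = half_time(0.03021, "exponential")
        assert float(f"{ht:.3g}") == 22.9

    def test_trivial_values(self):
        assert half_time(math.log(2.0), "exponential") == pytest.approx(1.0)
        assert half_time(0.05, "linear") == pytest.approx(10.0)

    @given(st.floats(1e-6, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_halftime_lambda_product_is_ln2(self, lam):
        assert half_time(lam, "exponential") * lam == pytest.approx(math.log(2.0))

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(EstimatorDomainError):
            half_time(0.0)
        with pytest.raises(EstimatorDomainError):
            half_time(-1.0, "linear")


@given(a=st.floats(-5, 5).filter(lambda a: abs(a) > 1e-3),
       b=st.floats(-100, 100))
@settings(max_examples=50, deadline=None)
def test_affine_invariance_of_normalization(a, b):
    """D is a ratio of differences: z -> a z + b leaves it unchanged."""
    base = {0.0: [10.0, 10.4], 4.0: [13.0, 13.4], 8.0: [16.0, 15.6],
            12.0: [18.0, 18.4]}
    new = [20.0, 19.8, 20.2]
    ds1 = make_dataset(base, new=new)
    ds2 = make_dataset({t: [a * z + b for z in v] for t, v in base.items()},
                       new=[a * z + b for z in new])
    s1 = normalize_series(ds1)
    s2 = normalize_series(ds2)
    np.testing.assert_allclose(s1.d, s2.d, rtol=1e-9, atol=1e-12)
    np.testing.assert_allclose(s1.times, s2.times)


def test_reference_point_invariance_on_noiseless_exponential_data():
    """Dropping the first k points and re-normalizing from the new earliest
    point yields the same rate from every single-point estimator: the decay
    rate does not depend on when observation starts."""
    lam, z0, zinf = 0.2, 5.0, -3.0
    times = np.arange(0.0, 25.0, 3.0)
    traj = {t: [zinf + (z0 - zinf) * math.exp(-lam * t)] for t in times}
    for k in (0, 1, 2, 3):
        sub = {t: v for t, v in traj.items() if t >= times[k]}
        s = normalize_series(make_dataset(sub, new=[zinf]))
        for t, d in zip(s.times[1:], s.d[1:]):
            assert lambda_point_exponential(d, t) == pytest.approx(lam, rel=1e-9)
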