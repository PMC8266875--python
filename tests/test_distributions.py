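"""Distribution specs: sampling, moments, quantiles, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from fluorisk import (
    DegenerateInputError,
    DistributionSpec,
    InsufficientDataError,
    ValidationError,
    analytic_mean_var,
    cdf,
    fit_triangular,
    lognormal,
    normal,
    point,
    quantile,
    sample,
    triangular,
    uniform,
)

SEED = 0

FAMILY_SPECS = [
    point(2.54),
    uniform(0.0, 1.0),
    triangular(0.0, 1.0, 2.0),
    normal(0.0, 1.0),
    lognormal(0.0, 1.0),
    normal(0.0, 1.0, truncate=(0.0, None)),
    lognormal(0.5, 0.4, truncate=(1.0, 4.0)),
    uniform(0.0, 2.0, truncate=(0.5, 1.5)),
]


class TestValidation:
    @pytest.mark.parametrize(
        "bad",
        [
            lambda: uniform(1.0, 1.0),
            lambda: triangular(0.0, 3.0, 2.0),
            lambda: triangular(1.0, 1.0, 1.0),
            lambda: normal(0.0, 0.0),
            lambda: lognormal(0.0, -1.0),
            lambda: uniform(0.0, 1.0, truncate=(2.0, 3.0)),  # zero mass
            lambda: DistributionSpec("point", (1.0,), truncate=(2.0, 3.0)),
            lambda: DistributionSpec("gamma", (1.0, 1.0)),
        ],
    )
    def test_invalid_specs_rejected_before_sampling(self, bad):
        with pytest.raises(ValidationError):
            bad()

    def test_serialization_round_trip(self):
        spec = triangular(1.12, 2.54, 3.87, truncate=(0.0, None))
        payload = spec.to_dict()
        assert payload == {
            "family": "triangular",
            "a": 1.12,
            "c": 2.54,
            "b": 3.87,
            "truncate": [0.0, None],
        }
        assert DistributionSpec.from_dict(payload) == spec

    def test_from_dict_rejects_missing_and_extra_keys(self):
        with pytest.raises(ValidationError, match="missing"):
            DistributionSpec.from_dict({"family": "normal", "mean": 0.0})
        with pytest.raises(ValidationError, match="unexpected"):
            DistributionSpec.from_dict({"family": "point", "value": 1.0, "mode": 2.0})


class TestSampling:
    def test_point_mass_is_constant(self):
        assert np.all(sample(point(2.54), 5, SEED) == 2.54)

    def test_identical_seed_bit_identical_different_seed_differs(self):
        spec = triangular(0.0, 0.7, 2.0)
        assert np.array_equal(sample(spec, 1000, 42), sample(spec, 1000, 42))
        assert sample(spec, 1000, 42).mean() != sample(spec, 1000, 43).mean()

    def test_triangular_mean_within_monte_carlo_error(self):
        n = 100_000
        draws = sample(triangular(0.0, 1.0, 2.0), n, SEED)
        mean, var = 1.0, 1.0 / 6.0
        assert abs(draws.mean() - mean) < 3 * math.sqrt(var / n)

    def test_half_normal_mean_from_truncation(self):
        # Normal(0,1) truncated to [0, inf) has mean sqrt(2/pi)
        n = 100_000
        draws = sample(normal(0.0, 1.0, truncate=(0.0, None)), n, SEED)
        expected = math.sqrt(2 / math.pi)
        sd = math.sqrt(1 - 2 / math.pi)
        assert np.all(draws >= 0)
        assert abs(draws.mean() - expected) < 3 * sd / math.sqrt(n)

    def test_truncation_never_shortens_output(self):
        draws = sample(normal(0.0, 1.0, truncate=(2.5, None)), 500, SEED)
        assert draws.shape == (500,) and np.all(draws >= 2.5)

    @pytest.mark.parametrize("spec", FAMILY_SPECS, ids=lambda s: f"{s.family}-{s.truncate}")
    def test_empirical_moments_match_analytic(self, spec):
        n = 200_000
        draws = sample(spec, n, SEED)
        mean, var = analytic_mean_var(spec)
        if spec.family == "point":
            assert np.all(draws == mean) and var == 0.0
            return
        se_mean = math.sqrt(var / n)
        assert abs(draws.mean() - mean) < 4 * se_mean
        # variance of the sample variance ~ (mu4 - var^2)/n; use a generous 4-SE
        mu4 = float(np.mean((draws - draws.mean()) ** 4))
        se_var = math.sqrt(max(mu4 - var**2, 0.0) / n)
        assert abs(draws.var() - var) < 4 * se_var + 1e-12


class TestMomentsAndQuantiles:
    def test_textbook_closed_forms(self):
        assert analytic_mean_var(point(3.0)) == (3.0, 0.0)
        assert analytic_mean_var(uniform(0.0, 1.0)) == pytest.approx((0.5, 1 / 12))
        assert analytic_mean_var(triangular(0.0, 1.0, 2.0)) == pytest.approx((1.0, 1 / 6))

    def test_lognormal_moments(self):
        mean, var = analytic_mean_var(lognormal(0.0, 1.0))
        assert mean == pytest.approx(math.exp(0.5))
        assert var == pytest.approx((math.e - 1) * math.e)

    def test_truncated_triangular_moments_not_implemented(self):
        with pytest.raises(NotImplementedError):
            analytic_mean_var(triangular(0.0, 1.0, 2.0, truncate=(0.5, None)))

    def test_trivial_truncation_treated_as_absent(self):
        mean, var = analytic_mean_var(lognormal(0.0, 1.0, truncate=(0.0, None)))
        assert mean == pytest.approx(math.exp(0.5))

    def test_symmetric_triangular_median(self):
        assert quantile(triangular(0.0, 1.0, 2.0), 0.5) == pytest.approx(1.0)

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_uniform_quantile_is_linear(self, q):
        a, b = 1.5, 4.0
        assert quantile(uniform(a, b), q) == pytest.approx(a + q * (b - a))

    def test_lognormal_tail_quantile(self):
        z95 = sps.norm.ppf(0.95)  # 1.6449
        assert quantile(lognormal(0.0, 1.0), 0.95) == pytest.approx(math.exp(z95), rel=1e-6)
        assert quantile(lognormal(0.0, 1.0), 0.95) == pytest.approx(5.180, abs=5e-3)

    def test_quantile_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            quantile(uniform(0, 1), 1.5)

    @pytest.mark.parametrize(
        "spec",
        [s for s in FAMILY_SPECS if s.family != "point"],
        ids=lambda s: f"{s.family}-{s.truncate}",
    )
    def test_quantile_cdf_round_trip_on_support_interior(self, spec):
        lo, hi = spec.support()
        lo = lo if math.isfinite(lo) else quantile(spec, 0.001)
        hi = hi if math.isfinite(hi) else quantile(spec, 0.999)
        for frac in (0.1, 0.37, 0.5, 0.82):
            x = lo + frac * (hi - lo)
            assert quantile(spec, cdf(spec, x)) == pytest.approx(x, abs=1e-9)


class TestTriangularFit:
    def test_printed_black_tea_range_recovers_mode_by_hand(self):
        # min/mean/max 1.12 / 2.51 / 3.87 -> c = 3*2.51 - 1.12 - 3.87 = 2.54
        spec = fit_triangular([1.12, 2.54, 3.87])
        p = spec.named_params
        assert p["a"] == 1.12 and p["b"] == 3.87
        assert p["c"] == pytest.approx(2.54)

    def test_symmetric_sample_puts_mode_at_midpoint(self):
        spec = fit_triangular([1.0, 2.0, 3.0, 2.0])
        assert spec.named_params["c"] == pytest.approx(2.0)

    def test_mode_clamped_into_interval(self):
        # heavily left-packed sample pushes the raw moment mode below the min
        spec = fit_triangular([1.0, 1.0, 1.0, 1.0, 10.0])
        p = spec.named_params
        assert p["a"] <= p["c"] <= p["b"]
        assert p["c"] == p["a"]

    def test_parameter_recovery_from_draws(self):
        truth = triangular(0.0, 0.7, 2.0)
        refit = fit_triangular(sample(truth, 10_000, SEED))
        p = refit.named_params
        assert abs(p["a"] - 0.0) < 0.05
        assert abs(p["c"] - 0.7) < 0.1
        assert abs(p["b"] - 2.0) < 0.05

    def test_insufficient_and_degenerate_inputs(self):
        with pytest.raises(InsufficientDataError):
            fit_triangular([1.0, 2.0])
        with pytest.raises(DegenerateInputError, match="point"):
            fit_triangular([2.0, 2.0, 2.0])
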