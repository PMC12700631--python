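import math

import numpy as np
import pytest
from scipy.stats import cauchy, norm

from cauchytl import (
    CalibrationParams,
    PriorSpec,
    TargetData,
    integral_bound,
    log_posterior,
    loglik_term_binary,
    loglik_term_continuous,
    loglik_vector,
)
from cauchytl.likelihood import _loglik_binary_vec, _loglik_continuous_vec


def brute_force_continuous(y, f, params, n=2_000_001):
    """Dense trapezoid over the union of the Cauchy core and Gaussian windows."""
    d, g, s = params.delta, params.gamma, params.sigma
    windows = [
        (d - 1e4 * g, d + 1e4 * g),
        (y / f - 10 * s / abs(f), y / f + 10 * s / abs(f)),
    ]
    windows.sort()
    if windows[0][1] >= windows[1][0]:  # merge overlap to avoid double counting
        windows = [(windows[0][0], max(windows[0][1], windows[1][1]))]
    total = 0.0
    for lo, hi in windows:
        beta = np.linspace(lo, hi, n)
        vals = norm.pdf(y, loc=beta * f, scale=s) * cauchy.pdf(beta, loc=d, scale=g)
        total += np.trapezoid(vals, beta)
    return math.log(total)


def brute_force_binary(y, f, params, n=2_000_001):
    """Dense trapezoid over beta across the Cauchy core and logistic transition."""
    d, g = params.delta, params.gamma
    lo = min(d - 1e4 * g, -80 / max(abs(f), 1e-12))
    hi = max(d + 1e4 * g, 80 / max(abs(f), 1e-12))
    beta = np.linspace(lo, hi, n)
    sign = 1.0 if y == 1 else -1.0
    s = 1 / (1 + np.exp(-np.clip(sign * beta * f, -700, 700)))
    core = np.trapezoid(s * cauchy.pdf(beta, loc=d, scale=g), beta)
    # saturated Cauchy tails outside the window
    from scipy.special import expit

    tail_lo = cauchy.cdf(lo, loc=d, scale=g) * float(expit(sign * lo * f))
    tail_hi = cauchy.sf(hi, loc=d, scale=g) * float(expit(sign * hi * f))
    return math.log(core + tail_lo + tail_hi)


class TestIntegralBound:
    def test_bound_is_39(self):
        assert integral_bound() == 39

    def test_39_is_smallest_underflow_integer(self):
        # the standard normal density is subnormal-positive at 38 and exactly
        # zero at 39 in IEEE double precision
        for z in range(1, 39):
            assert norm.pdf(z) > 0.0
        assert norm.pdf(38) > 0.0
        assert norm.pdf(39) == 0.0


class TestContinuousTerm:
    def test_degenerate_cauchy_collapses_to_normal(self):
        # gamma -> 0: the mixture collapses to N(y | delta*f, sigma^2)
        params = CalibrationParams(delta=0.5, gamma=1e-12, sigma=1.0)
        got = loglik_term_continuous(1.0, 2.0, params)
        want = norm.logpdf(1.0, loc=0.5 * 2.0, scale=1.0)
        assert got == pytest.approx(want, abs=1e-6)

    def test_generic_point_against_brute_force(self):
        params = CalibrationParams(delta=1.1, gamma=0.4, sigma=0.9)
        got = loglik_term_continuous(0.7, -1.3, params)
        assert got == pytest.approx(brute_force_continuous(0.7, -1.3, params), abs=1e-8)

    def test_sign_symmetry(self):
        params = CalibrationParams(delta=0.8, gamma=0.3, sigma=0.7)
        assert loglik_term_continuous(1.4, 2.2, params) == pytest.approx(
            loglik_term_continuous(-1.4, -2.2, params), abs=1e-10
        )

    def test_zero_f_raises(self):
        with pytest.raises(ValueError):
            loglik_term_continuous(1.0, 0.0, CalibrationParams(1.0, 1.0, 1.0))

    def test_nonfinite_y_raises(self):
        with pytest.raises(ValueError):
            loglik_term_continuous(np.nan, 1.0, CalibrationParams(1.0, 1.0, 1.0))

    def test_heavy_tail_dominates_far_from_center(self):
        # far outside the Gaussian range the Cauchy tail keeps terms finite
        # and monotonically decreasing in |y|
        params = CalibrationParams(delta=1.0, gamma=0.05, sigma=0.5)
        ys = np.array([50.0, 100.0, 400.0, 1000.0])
        terms = [loglik_term_continuous(y, 1.0, params) for y in ys]
        assert np.all(np.isfinite(terms))
        assert np.all(np.diff(terms) < 0)


class TestBinaryTerm:
    def test_zero_structural_value_is_coin_flip(self):
        params = CalibrationParams(delta=1.0, gamma=0.5)
        for y in (0.0, 1.0):
            assert loglik_term_binary(y, 0.0, params) == pytest.approx(math.log(0.5))

    def test_symmetric_law_is_label_symmetric(self):
        params = CalibrationParams(delta=0.0, gamma=0.7)
        assert loglik_term_binary(1.0, 1.3, params) == pytest.approx(
            loglik_term_binary(0.0, 1.3, params), abs=1e-10
        )

    def test_generic_point_against_brute_force(self):
        params = CalibrationParams(delta=1.0, gamma=0.5)
        got = loglik_term_binary(1.0, 0.8, params)
        assert got == pytest.approx(brute_force_binary(1.0, 0.8, params), abs=1e-8)

    def test_terms_are_log_probabilities(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            params = CalibrationParams(rng.normal(1, 1), 10 ** rng.uniform(-2, 1))
            val = loglik_term_binary(float(rng.integers(2)), rng.normal(0, 5), params)
            assert val <= 0.0


class TestQuadratureAgreement:
    """The fast vectorized path agrees with the adaptive reference path."""

    def test_continuous_vectorized_matches_scalar(self):
        rng = np.random.default_rng(10)
        for _ in range(60):
            y, f = rng.normal(0, 10), rng.normal(0, 10)
            if abs(f) < 1e-2:
                continue
            params = CalibrationParams(
                rng.normal(1, 1), 10 ** rng.uniform(-6, 1.5), 10 ** rng.uniform(-1, 1)
            )
            scalar = loglik_term_continuous(y, f, params)
            vec = _loglik_continuous_vec(
                np.array([y]), np.array([f]),
                params.delta, params.gamma, params.sigma,
            )[0]
            assert vec == pytest.approx(scalar, abs=2e-7)

    def test_binary_vectorized_matches_scalar(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            y, f = float(rng.integers(2)), rng.normal(0, 10)
            if abs(f) < 1e-2:
                continue
            params = CalibrationParams(rng.normal(1, 1), 10 ** rng.uniform(-4, 1.5))
            scalar = loglik_term_binary(y, f, params)
            vec = _loglik_binary_vec(
                np.array([y]), np.array([f]), params.delta, params.gamma
            )[0]
            assert vec == pytest.approx(scalar, abs=2e-4)

    def test_scalar_tolerance_stability(self):
        # halving the adaptive tolerance leaves log terms essentially unchanged
        from cauchytl import likelihood as L

        rng = np.random.default_rng(12)
        cases = []
        for _ in range(100):
            y, f = rng.normal(0, 5), rng.normal(0, 5)
            if abs(f) < 0.05:
                continue
            cases.append(
                (y, f, CalibrationParams(rng.normal(1, 1), 10 ** rng.uniform(-2, 1),
                                         10 ** rng.uniform(-0.5, 0.5)))
            )
        base = [loglik_term_continuous(y, f, p) for y, f, p in cases]
        old = dict(L._QUAD_OPTS)
        try:
            L._QUAD_OPTS["epsrel"] = old["epsrel"] / 2
            halved = [loglik_term_continuous(y, f, p) for y, f, p in cases]
        finally:
            L._QUAD_OPTS.update(old)
        np.testing.assert_allclose(base, halved, atol=1e-9)


class TestLogPosterior:
    def _continuous_data(self, n):
        rng = np.random.default_rng(20)
        f = rng.normal(0, 3, n)
        f[f == 0] = 1.0
        y = 1.2 * f + rng.normal(0, 0.5, n)
        X = rng.standard_normal((n, 2))
        return TargetData(X=X, y=y, f_vals=f, response_kind="continuous")

    def test_empty_data_returns_prior(self):
        data = TargetData(
            X=np.empty((0, 2)), y=np.empty(0), f_vals=np.empty(0),
            response_kind="continuous",
        )
        prior = PriorSpec()
        params = CalibrationParams(1.0, 0.5, 1.0)
        assert log_posterior(params, data, prior) == pytest.approx(
            prior.logpdf(params)
        )

    def test_doubling_data_doubles_loglik_part(self):
        data = self._continuous_data(17)
        doubled = TargetData(
            X=np.vstack([data.X, data.X]),
            y=np.concatenate([data.y, data.y]),
            f_vals=np.concatenate([data.f_vals, data.f_vals]),
            response_kind="continuous",
        )
        prior = PriorSpec()
        params = CalibrationParams(1.1, 0.3, 0.6)
        lp = prior.logpdf(params)
        single = log_posterior(params, data, prior) - lp
        double = log_posterior(params, doubled, prior) - lp
        assert double == pytest.approx(2 * single, rel=1e-10)

    def test_composition_matches_scalar_terms(self):
        data = self._continuous_data(3)
        prior = PriorSpec()
        params = CalibrationParams(0.9, 0.4, 0.8)
        expected = prior.logpdf(params) + sum(
            loglik_term_continuous(y, f, params)
            for y, f in zip(data.y, data.f_vals)
        )
        assert log_posterior(params, data, prior) == pytest.approx(expected, abs=1e-6)

    def test_invalid_parameters_give_minus_inf_not_error(self):
        data = self._continuous_data(5)
        prior = PriorSpec()
        assert log_posterior(CalibrationParams(1.0, -1.0, 1.0), data, prior) == -math.inf
        assert log_posterior(CalibrationParams(1.0, 0.5, -1.0), data, prior) == -math.inf

    def test_zero_f_in_continuous_data_rejected(self):
        with pytest.raises(ValueError, match="f"):
            TargetData(
                X=np.zeros((2, 1)), y=np.ones(2), f_vals=np.array([1.0, 0.0]),
                response_kind="continuous",
            )

    def test_binary_vector_path(self):
        rng = np.random.default_rng(21)
        f = rng.normal(0, 3, 7)
        y = (rng.uniform(size=7) < 0.5).astype(float)
        data = TargetData(X=np.zeros((7, 1)), y=y, f_vals=f, response_kind="binary")
        params = CalibrationParams(1.0, 0.4)
        terms = loglik_vector(params, data)
        expected = [loglik_term_binary(yy, ff, params) for yy, ff in zip(y, f)]
        np.testing.assert_allclose(terms, expected, atol=1e-6)
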