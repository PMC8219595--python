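"""Engine-level tests: frozen closed-form values, invariances, and
agreement with the independent quadrature / Monte-Carlo oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles as oracles
from bfoptstop.models import (
    DEFAULT_G_SCALE,
    DegenerateDataError,
    DesignMatrix,
    InvalidDesignError,
    InvalidInputError,
    ModelSpec,
    OddsValue,
    bf_bernoulli_jeffreys,
    bf_gprior_regression,
    bf_jzs_ttest,
    gprior_log_bf,
    gprior_marginal_density,
    jzs_log_bf,
    log_odds_normal_known_var,
    odds_normal_jeffreys_var,
    odds_normal_known_var,
)
from bfoptstop.synthetic_data import fertilizer_design


class TestOddsValue:
    def test_log_and_value_consistent(self):
        ov = OddsValue.from_value(3.5)
        assert ov.value == pytest.approx(math.exp(ov.log_value), rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(InvalidInputError):
            OddsValue.from_value(0.0)


class TestNormalKnownVar:
    def test_zero_mean_gives_inverse_sqrt(self):
        # exponent vanishes at xbar = 0, leaving 1/sqrt(n+1)
        assert odds_normal_known_var(3, 0.0).value == pytest.approx(0.5, abs=1e-14)

    def test_matches_prior_quadrature(self):
        # frozen from the 1-d marginal-likelihood-ratio quadrature oracle
        assert odds_normal_known_var(10, 0.5).value == pytest.approx(
            0.9393341554, rel=1e-9)
        assert odds_normal_known_var(10, 0.5).value == pytest.approx(
            oracles.oracle_normal_known_var(10, 0.5), rel=1e-9)

    def test_monotone_in_absolute_mean(self):
        xbars = np.linspace(0.0, 4.0, 30)
        vals = log_odds_normal_known_var(10, xbars)
        assert np.all(np.diff(vals) > 0)
        assert odds_normal_known_var(10, 3.0).value > 10

    def test_invalid_n(self):
        with pytest.raises(InvalidInputError):
            odds_normal_known_var(0, 1.0)

    @given(st.floats(min_value=-1e6, max_value=1e6),
           st.integers(min_value=1, max_value=10**6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_log_never_overflows(self, xbar, n):
        log_odds = float(log_odds_normal_known_var(n, xbar))
        assert np.isfinite(log_odds)


class TestNormalJeffreysVar:
    def test_antisymmetric_pair(self):
        # sum x = 0 kills the second factor, leaving 1/sqrt(3)
        assert odds_normal_jeffreys_var([1.0, -1.0]).value == pytest.approx(
            1 / math.sqrt(3), abs=1e-14)

    def test_matches_two_dim_quadrature(self):
        # frozen from the (mu, sigma) double-integral oracle with widened
        # sigma cutoffs
        assert odds_normal_jeffreys_var([1, 2, 3]).value == pytest.approx(
            2.342648074, rel=1e-8)

    @pytest.mark.parametrize("c", [0.1, 1.0, 7.0])
    def test_scale_invariance_exact(self, c):
        data = np.array([0.4, -1.3, 2.2, 0.9])
        a = odds_normal_jeffreys_var(data).log_value
        b = odds_normal_jeffreys_var(c * data).log_value
        assert a == pytest.approx(b, abs=1e-12)

    def test_degenerate_and_short_inputs(self):
        with pytest.raises(DegenerateDataError):
            odds_normal_jeffreys_var([0.0, 0.0, 0.0])
        with pytest.raises(InvalidInputError):
            odds_normal_jeffreys_var([1.0])


class TestJZSTTest:
    @pytest.mark.parametrize("c", [0.1, 1.0, 7.0])
    def test_scale_invariance_of_effect_size(self, c, jzs_spec):
        data = np.array([1.4, 0.2, 2.6, 1.1, 0.8])
        scaled = jzs_spec.mu0 + c * (data - jzs_spec.mu0)
        a = bf_jzs_ttest(data, jzs_spec).log_value
        b = bf_jzs_ttest(scaled, jzs_spec).log_value
        assert a == pytest.approx(b, abs=1e-12)

    def test_location_invariance(self):
        data = np.array([0.3, -0.7, 1.2, 0.1, -0.4, 0.9])
        a = bf_jzs_ttest(data, ModelSpec("jzs_ttest", mu0=0.0)).log_value
        b = bf_jzs_ttest(data + 5.0, ModelSpec("jzs_ttest", mu0=5.0)).log_value
        assert a == pytest.approx(b, abs=1e-10)

    def test_null_centered_data_favor_null(self, jzs_spec):
        # symmetric deviations: sample mean equals mu0 exactly, t = 0
        data = jzs_spec.mu0 + np.array([1, -1, 2, -2, 0.5, -0.5, 1.5, -1.5, 0.3, -0.3])
        odds = bf_jzs_ttest(data, jzs_spec)
        assert odds.value < 1
        assert odds.value == pytest.approx(oracles.oracle_jzs(data, jzs_spec.mu0, 1.0),
                                           rel=1e-6)

    def test_agrees_with_effect_size_route_oracle(self, rng):
        for _ in range(5):
            n = int(rng.integers(3, 12))
            data = rng.standard_normal(n) * rng.uniform(0.5, 2) + rng.uniform(-1, 1)
            mu0 = float(rng.uniform(-0.5, 0.5))
            r = float(rng.uniform(0.4, 2.0))
            spec = ModelSpec("jzs_ttest", mu0=mu0, cauchy_scale=r)
            mine = bf_jzs_ttest(data, spec).value
            assert mine == pytest.approx(oracles.oracle_jzs(data, mu0, r), rel=1e-6)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        for t, n, r in [(0.0, 10, 1.0), (2.5, 10, 1.0), (-3.0, 15, 0.5),
                        (5.0, 30, 1.0), (1.2, 4, 0.707)]:
            mine = math.exp(float(jzs_log_bf(t, n, r)))
            ref = float(pg.bayesfactor_ttest(t, n, r=r))
            assert mine == pytest.approx(ref, rel=1e-8)

    def test_degenerate_variance(self, jzs_spec):
        with pytest.raises(DegenerateDataError):
            bf_jzs_ttest([2.0, 2.0, 2.0], jzs_spec)


class TestGPriorRegression:
    def setup_method(self):
        self.spec = ModelSpec("gprior_regression")
        self.X20 = fertilizer_design(20)

    def test_null_data_favor_null_in_median(self):
        # Monte-Carlo oracle: with beta = 0 the median odds over replicates
        # sit below 1 (the prior spreads H1's likelihood thin)
        rng = np.random.default_rng(11)
        vals = [gprior_log_bf(rng.standard_normal(20), self.X20, self.X20, self.spec)
                for _ in range(2000)]
        assert np.median(np.exp(vals)) < 1.0

    def test_prior_design_changes_odds(self):
        # the prior is scaled by n_p (Xp'Xp)^{-1}: a 23-row design scales it
        # differently from the realized 20-row design, so the odds differ
        rng = np.random.default_rng(5)
        y = 0.4 * self.X20.x[:, 0] + rng.standard_normal(20)
        cur = bf_gprior_regression(y, self.X20, self.X20, self.spec).log_value
        planned = bf_gprior_regression(y, self.X20, fertilizer_design(23),
                                       self.spec).log_value
        assert cur != pytest.approx(planned, rel=1e-6)

    def test_cyclic_replication_leaves_prior_invariant(self):
        # n (X'X)^{-1} is invariant under duplicating the design, so a
        # 40-row cyclic plan scales the prior exactly like the 20-row one
        rng = np.random.default_rng(6)
        y = 0.4 * self.X20.x[:, 0] + rng.standard_normal(20)
        cur = bf_gprior_regression(y, self.X20, self.X20, self.spec).log_value
        rep = bf_gprior_regression(y, self.X20, fertilizer_design(40),
                                   self.spec).log_value
        assert cur == pytest.approx(rep, rel=1e-12)

    def test_quadrature_matches_g_sampling_oracle(self):
        rng = np.random.default_rng(9)
        y = 0.5 * self.X20.x[:, 0] + rng.standard_normal(20)
        quad = math.exp(gprior_log_bf(y, self.X20, self.X20, self.spec))
        mc, se = oracles.oracle_gprior_mc(y, self.X20.x, n_draws=10**6, seed=3)
        assert abs(quad - mc) < 3 * se

    def test_singular_design_rejected(self):
        X = DesignMatrix(np.ones((10, 1)))
        with pytest.raises(InvalidDesignError):
            bf_gprior_regression(np.arange(10.0), X, X, self.spec)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(InvalidInputError):
            bf_gprior_regression(np.arange(5.0), self.X20, self.X20, self.spec)


class TestGPriorMarginalDensity:
    def setup_method(self):
        self.spec = ModelSpec("gprior_regression")

    def test_normalizes_to_one(self):
        from scipy import integrate

        X = fertilizer_design(20)
        val, _ = integrate.quad(
            lambda b: float(gprior_marginal_density(b, X, 1.0, self.spec)),
            -np.inf, np.inf, limit=200)
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_symmetric(self):
        X = fertilizer_design(23)
        beta = np.array([0.3, 1.7, 4.0])
        assert gprior_marginal_density(beta, X, 1.0, self.spec) == pytest.approx(
            gprior_marginal_density(-beta, X, 1.0, self.spec), rel=1e-12)

    def test_peak_flattens_as_design_grows(self):
        d20 = float(gprior_marginal_density(0.0, fertilizer_design(20), 1.0, self.spec))
        d34 = float(gprior_marginal_density(0.0, fertilizer_design(34), 1.0, self.spec))
        assert d20 > d34

    def test_matches_closed_form_cauchy(self):
        # N(0, g s^2) mixed over g ~ IG(1/2, b) is Cauchy(0, s sqrt(2 b))
        from scipy import stats

        X = fertilizer_design(20)
        xc = X.centered().ravel()
        s = math.sqrt(X.n / float(xc @ xc))
        scale = s * math.sqrt(2.0 * DEFAULT_G_SCALE)
        beta = np.linspace(-3, 3, 13)
        assert gprior_marginal_density(beta, X, 1.0, self.spec) == pytest.approx(
            stats.cauchy(0, scale).pdf(beta), rel=1e-9)

    def test_rejects_multicolumn_design(self):
        X = DesignMatrix(np.random.default_rng(0).standard_normal((8, 2)))
        with pytest.raises(InvalidInputError):
            gprior_marginal_density(0.0, X, 1.0, self.spec)


class TestBernoulliJeffreys:
    def test_single_observation_is_even(self):
        assert bf_bernoulli_jeffreys(1, 0).value == pytest.approx(1.0, abs=1e-12)

    def test_two_heads(self):
        # frozen from the quadrature oracle of the Jeffreys marginal
        assert bf_bernoulli_jeffreys(2, 0).value == pytest.approx(1.5, rel=1e-12)
        assert bf_bernoulli_jeffreys(2, 0).value == pytest.approx(
            oracles.oracle_bernoulli(2, 0), rel=1e-8)

    def test_balanced_counts_decay(self):
        vals = [bf_bernoulli_jeffreys(k, k).value for k in (5, 10, 20)]
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < 0.3

    def test_invalid_counts(self):
        with pytest.raises(InvalidInputError):
            bf_bernoulli_jeffreys(-1, 2)
        with pytest.raises(InvalidInputError):
            bf_bernoulli_jeffreys(0, 0)

    @given(st.integers(min_value=0, max_value=500),
           st.integers(min_value=0, max_value=500))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_odds_finite_and_positive(self, n1, n0):
        if n1 + n0 == 0:
            return
        assert np.isfinite(bf_bernoulli_jeffreys(n1, n0).log_value)
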