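"""Brute-force quadrature / Monte-Carlo oracles, independent of the package
engines: each one integrates the defining ratio of marginal likelihoods
directly, in the parameterization the model is stated in (no reuse of the
engines' sufficient-statistic reductions or integration routes)."""

import math

import numpy as np
from scipy import integrate, stats


def oracle_normal_known_var(n, xbar):
    """1-d quadrature over the N(0,1) prior on mu of the likelihood ratio
    for N(mu,1) vs N(0,1) data with sample mean xbar."""
    s = n * xbar

    def integrand(mu):
        return math.exp(mu * s - 0.5 * n * mu * mu) * stats.norm.pdf(mu)

    val, _ = integrate.quad(integrand, -np.inf, np.inf)
    return val


def oracle_normal_jeffreys_var(data, widen=1.0):
    """2-d quadrature over (mu, sigma) of the ratio of integrals defining
    the unknown-variance test, with finite sigma cutoffs widened until the
    ratio stabilizes (the improper 1/sigma prior appears in both the
    numerator and the denominator, so the cutoffs cancel in the limit)."""
    x = np.asarray(data, dtype=float)
    n = x.size
    scale = math.sqrt(np.mean(x * x))
    lo, hi = scale * 1e-3 / widen, scale * 1e3 * widen

    def loglik(mu, sigma):
        return -n * math.log(sigma) - 0.5 * np.sum((x - mu) ** 2) / sigma**2

    def num_inner(sigma):
        ref = loglik(float(np.mean(x)), sigma)
        val, _ = integrate.quad(
            lambda mu: math.exp(loglik(mu, sigma) - ref - 0.5 * mu * mu / sigma**2)
            / math.sqrt(2 * math.pi * sigma**2),
            -np.inf, np.inf, epsabs=0.0, epsrel=1e-11, limit=400)
        return math.exp(ref + math.log(val)) / sigma if val > 0 else 0.0

    def den_inner(sigma):
        return math.exp(loglik(0.0, sigma)) / sigma

    num, _ = integrate.quad(num_inner, lo, hi, limit=400, epsabs=0.0, epsrel=1e-10)
    den, _ = integrate.quad(den_inner, lo, hi, limit=400, epsabs=0.0, epsrel=1e-10)
    return num / den


def oracle_jzs(data, mu0=0.0, r=1.0):
    """Effect-size-route oracle for the JZS one-sample test: integrate sigma
    out for each delta (substituting u = 1/sigma), then integrate the
    Cauchy(0, r) weight over delta.  Independent of the (t, n) g-mixture
    route used by the implementation."""
    z = np.asarray(data, dtype=float) - mu0
    n = z.size
    q = float(z @ z)
    s = float(z.sum())

    def log_inner(delta):
        # log int_0^inf u^{n-1} exp(-q u^2/2 + delta s u) du, factoring the
        # exponent's maximum out so the quadrature never overflows
        peak = max(delta * s, 0.0) ** 2 / (2.0 * q)
        val, _ = integrate.quad(
            lambda u: u ** (n - 1)
            * math.exp(-0.5 * q * u * u + delta * s * u - peak),
            0.0, np.inf, limit=400, epsabs=0.0, epsrel=1e-11)
        return peak + math.log(val) if val > 0 else -math.inf

    def num_integrand(delta):
        log_val = (stats.cauchy(0.0, r).logpdf(delta)
                   - 0.5 * n * delta * delta + log_inner(delta))
        return math.exp(log_val)

    num, _ = integrate.quad(num_integrand, -np.inf, np.inf, limit=600,
                            epsabs=0.0, epsrel=1e-10, points=None)
    den = math.gamma(n / 2.0) * 2 ** (n / 2.0 - 1.0) * q ** (-n / 2.0)
    return num / den


def oracle_bernoulli(n1, n0):
    """1-d quadrature of the Jeffreys-prior marginal likelihood over theta,
    divided by the theta = 1/2 likelihood."""
    def integrand(theta):
        return theta ** (n1 - 0.5) * (1 - theta) ** (n0 - 0.5) / math.pi

    num, _ = integrate.quad(integrand, 0.0, 1.0)
    return num / 0.5 ** (n1 + n0)


def oracle_gprior_mc(y, x, n_draws, seed, g_shape=0.5, g_scale=math.sqrt(2) / 8):
    """Monte-Carlo oracle for the scalar g-prior regression Bayes factor:
    average, over g draws from the inverse-gamma mixing distribution, the
    conditional Bayes factor computed from its own first principles
    (determinant and quadratic form of the marginal covariance).

    Returns (estimate, standard error) on the BF scale.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    n = y.size
    rng = np.random.default_rng(seed)
    g = g_scale / rng.gamma(g_shape, 1.0, size=n_draws)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = xc @ xc
    v = n / sxx
    r0 = yc @ yc
    u2 = (xc @ yc) ** 2 / sxx  # squared projection onto the unit design direction
    det = 1.0 + g * v * sxx
    rg = r0 - (g * v * sxx / det) * u2
    bf_g = det ** -0.5 * (rg / r0) ** (-(n - 1) / 2.0)
    return float(bf_g.mean()), float(bf_g.std(ddof=1) / math.sqrt(n_draws))
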