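"""Nominal-vs-observed posterior-odds calibration diagnostics.

The diagnostic: run many replicates under H0 and equally many under H1,
histogram the final log posterior odds of both sets on a common grid of
bins (width 0.1 in natural log odds), and form the *observed* posterior
odds in each bin as the ratio of H1 to H0 counts.  If the reported odds
mean what they claim, the observed odds match the *nominal* odds (the bin
center): the curve lies on the identity line.  This holds at fixed n and —
for prior-sampled parameters with proper priors, or for nuisance parameters
with right-Haar ("type 0") priors — under any optional stopping rule; it
fails under optional stopping when the interesting parameter is held at a
fixed value under a default prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    InvalidInputError,
    ModelSpec,
    OddsValue,
    jzs_log_bf,
    log_odds_bernoulli_jeffreys,
    log_odds_normal_jeffreys_var,
    log_odds_normal_known_var,
)
from .sequential import StoppingRule, run_sequential_batch
from .synthetic_data import (
    SamplingRegime,
    gen_bernoulli,
    gen_normal,
    gen_ttest_effect,
    replicate_matrix,
)

__all__ = [
    "InsufficientDataError",
    "CalibrationCurve",
    "CalibrationResult",
    "build_curve",
    "calibration_slope",
    "check_prior_calibration",
    "check_strong_calibration",
    "batch_log_odds",
]


class InsufficientDataError(InvalidInputError):
    """Too few unmasked bins to summarize a calibration curve."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Binned nominal-vs-observed posterior odds.

    ``observed[i] = counts_H1[i] / counts_H0[i]``; ``nominal[i]`` is the
    geometric center of bin i on the odds scale.  Bins where either
    histogram holds fewer than ``min_count`` replicates are masked: the
    ratio of small counts is not just noisy but biased (a bin is only
    usable when its denominator count is at least 1, which inflates small
    denominators), so sparse tail bins would systematically bend the curve.
    """

    bin_edges: np.ndarray = field(repr=False)
    counts_H0: np.ndarray = field(repr=False)
    counts_H1: np.ndarray = field(repr=False)
    reps: int
    min_count: int

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def log_nominal(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def nominal(self) -> np.ndarray:
        return np.exp(self.log_nominal)

    @property
    def masked(self) -> np.ndarray:
        return (self.counts_H0 < self.min_count) | (self.counts_H1 < self.min_count)

    @property
    def observed(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.counts_H0 > 0,
                            self.counts_H1 / np.maximum(self.counts_H0, 1), np.nan)

    @property
    def log_deviation(self) -> np.ndarray:
        """log observed - log nominal per unmasked bin (nan where masked)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = np.log(self.observed) - self.log_nominal
        return np.where(self.masked, np.nan, dev)

    @property
    def deviation_se(self) -> np.ndarray:
        """Propagated binomial (Poisson-count) standard error of the log
        observed odds per bin: sqrt(1/counts_H1 + 1/counts_H0)."""
        with np.errstate(divide="ignore"):
            return np.sqrt(1.0 / np.maximum(self.counts_H1, 1)
                           + 1.0 / np.maximum(self.counts_H0, 1))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo": self.bin_edges[:-1],
            "bin_hi": self.bin_edges[1:],
            "nominal": self.nominal,
            "counts_H0": self.counts_H0,
            "counts_H1": self.counts_H1,
            "observed": self.observed,
            "masked": self.masked,
        })


def _as_log_array(odds) -> np.ndarray:
    arr = np.asarray([o.log_value if isinstance(o, OddsValue) else float(o)
                      for o in np.atleast_1d(odds)], dtype=float)
    return arr


def build_curve(odds_H0, odds_H1, bin_width: float = 0.1,
                min_count: int = 10) -> CalibrationCurve:
    """Histogram final odds from H0 and H1 replicates into common log-odds
    bins of width ``bin_width`` (natural log) and form their ratio.

    Accepts sequences of :class:`OddsValue` or raw *log* odds.  Bin edges
    are aligned so that log-odds 0 is an edge, making the binning a pure,
    permutation-invariant function of the inputs.
    """
    if min_count < 1:
        raise InvalidInputError("min_count must be >= 1")
    l0 = _as_log_array(odds_H0)
    l1 = _as_log_array(odds_H1)
    if l0.size == 0 or l1.size == 0:
        raise InvalidInputError("need odds from both hypotheses")
    if l0.size != l1.size:
        raise InvalidInputError("the design uses equal replicates per hypothesis")
    lo = math.floor(min(l0.min(), l1.min()) / bin_width) * bin_width
    hi = math.ceil(max(l0.max(), l1.max()) / bin_width) * bin_width
    nbins = max(int(round((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(nbins + 1)
    c0, _ = np.histogram(l0, bins=edges)
    c1, _ = np.histogram(l1, bins=edges)
    return CalibrationCurve(edges, c0, c1, reps=l0.size, min_count=min_count)


def calibration_slope(curve: CalibrationCurve) -> tuple[float, float]:
    """Least-squares slope of log observed on log nominal over unmasked
    bins, and the maximum absolute log deviation.  Perfect calibration is
    (1.0, 0.0)."""
    keep = ~curve.masked
    if keep.sum() < 3:
        raise InsufficientDataError("need at least 3 unmasked bins")
    x = curve.log_nominal[keep]
    with np.errstate(divide="ignore"):
        y = np.log(curve.observed[keep])
    slope = float(np.polyfit(x, y, 1)[0])
    max_dev = float(np.nanmax(np.abs(curve.log_deviation)))
    return slope, max_dev


@dataclass(frozen=True)
class CalibrationResult:
    curve: CalibrationCurve
    slope: float
    max_abs_log_deviation: float
    log_odds_H0: np.ndarray = field(repr=False)
    log_odds_H1: np.ndarray = field(repr=False)
    tau_H0: np.ndarray | None = field(default=None, repr=False)
    tau_H1: np.ndarray | None = field(default=None, repr=False)


# -- vectorized per-family running odds --------------------------------------

def batch_log_odds(family: str, obs: np.ndarray, spec: ModelSpec):
    """Return a ``log_odds_fn(n, active)`` closure over a (reps, n_max)
    observation matrix for the given family, computing the running log
    posterior odds from cumulative sufficient statistics."""
    if family == "normal_known_var":
        csum = np.cumsum(obs, axis=1)

        def fn(n, active):
            return log_odds_normal_known_var(n, csum[active, n - 1] / n)

    elif family == "normal_jeffreys_var":
        csum = np.cumsum(obs, axis=1)
        csum2 = np.cumsum(obs * obs, axis=1)

        def fn(n, active):
            return log_odds_normal_jeffreys_var(n, csum[active, n - 1],
                                                csum2[active, n - 1])

    elif family == "jzs_ttest":
        z = obs - spec.mu0
        csum = np.cumsum(z, axis=1)
        csum2 = np.cumsum(z * z, axis=1)

        def fn(n, active):
            s = csum[active, n - 1]
            ss = csum2[active, n - 1]
            mean = s / n
            var = np.maximum(ss - n * mean * mean, 0.0) / (n - 1)
            var = np.maximum(var, 1e-300)
            t = mean / np.sqrt(var / n)
            return jzs_log_bf(t, n, spec.cauchy_scale)

    elif family == "bernoulli_jeffreys":
        csum = np.cumsum(obs, axis=1)

        def fn(n, active):
            n1 = csum[active, n - 1]
            return log_odds_bernoulli_jeffreys(n1, n - n1)

    else:
        raise InvalidInputError(f"no batch odds engine for family {family!r}")
    return fn


_GENERATORS = {
    "normal_known_var": gen_normal,
    "normal_jeffreys_var": gen_normal,
    "jzs_ttest": gen_ttest_effect,
    "bernoulli_jeffreys": gen_bernoulli,
}


def _simulate_final_odds(spec: ModelSpec, regime: SamplingRegime, rule, reps, seed):
    gen = _GENERATORS.get(spec.family)
    if gen is None:
        raise InvalidInputError(
            f"calibration checks are not defined for family {spec.family!r} "
            "(the g-prior depends on the design, so prior calibration under "
            "optional stopping is ill-defined)")
    if isinstance(rule, StoppingRule):
        n_max = rule.horizon
    else:
        n_max = int(rule)
        if n_max < 1:
            raise InvalidInputError("fixed n must be >= 1")
    obs = replicate_matrix(gen, regime, spec, reps, n_max, seed)
    fn = batch_log_odds(spec.family, obs, spec)
    if isinstance(rule, StoppingRule):
        res = run_sequential_batch(fn, reps, rule)
        return res.final_log_odds, res.tau
    return np.asarray(fn(n_max, np.arange(reps)), dtype=float), None


def _check(spec, regime_H0, regime_H1, rule, reps, seed, bin_width, min_count):
    if reps < 1:
        raise InvalidInputError("reps must be >= 1")
    root = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s0, s1 = root.spawn(2)
    l0, tau0 = _simulate_final_odds(spec, regime_H0, rule, reps, s0)
    l1, tau1 = _simulate_final_odds(spec, regime_H1, rule, reps, s1)
    curve = build_curve(l0, l1, bin_width=bin_width, min_count=min_count)
    slope, max_dev = calibration_slope(curve)
    return CalibrationResult(curve, slope, max_dev, l0, l1, tau0, tau1)


def check_prior_calibration(spec: ModelSpec, rule, reps: int, seed,
                            sigma: float = 1.0, bin_width: float = 0.1,
                            min_count: int = 10) -> CalibrationResult:
    """Run the prior-calibration experiment: H1 parameters drawn from their
    prior, H0 from the null, both monitored under ``rule`` (a
    :class:`StoppingRule`) or evaluated at a fixed sample size (an int).

    ``sigma`` fixes the nuisance scale where the family has one (it cannot
    be sampled — its Jeffreys prior is improper)."""
    regime_H0 = SamplingRegime("H0", "from_prior", {"sigma": sigma})
    regime_H1 = SamplingRegime("H1", "from_prior", {"sigma": sigma})
    return _check(spec, regime_H0, regime_H1, rule, reps, seed, bin_width, min_count)


def check_strong_calibration(spec: ModelSpec, fixed_params: dict, rule,
                             reps: int, seed, bin_width: float = 0.1,
                             min_count: int = 10) -> CalibrationResult:
    """Run the strong-calibration experiment: H1 parameters held at the
    fixed values in ``fixed_params`` (which should lie in a region of large
    prior density), H0 from the null at the same nuisance values."""
    sigma = float(fixed_params.get("sigma", 1.0))
    regime_H0 = SamplingRegime("H0", "fixed", {"sigma": sigma})
    regime_H1 = SamplingRegime("H1", "fixed", dict(fixed_params))
    return _check(spec, regime_H0, regime_H1, rule, reps, seed, bin_width, min_count)
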