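"""Frequentist operating characteristics of Bayes-factor stopping rules.

Two classical facts are exercised here.  First, under a *simple* null the
running Bayes factor is a nonnegative martingale with unit expectation, so
by the universal bound (Doob's maximal inequality) the probability that it
ever exceeds 1/alpha is at most alpha — rejecting whenever the posterior
odds in favor of H0 drop below alpha controls the type-I error at alpha
under any stopping rule.  Second, the sequential Bayesian t-test design
(collect at least n_min observations, then stop as soon as the Bayes factor
leaves [1/B, B]) has a small type-II error when the true standardized
effect is moderate; this module measures it by simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import batch_log_odds
from .models import InvalidInputError, ModelSpec
from .sequential import StoppingRule, run_sequential_batch
from .synthetic_data import SamplingRegime, gen_normal, gen_bernoulli, gen_ttest_effect, replicate_matrix

__all__ = ["OperatingCharacteristics", "type1_under_stopping", "type2_schonbrodt"]

_SIMPLE_H0_FAMILIES = ("normal_known_var", "bernoulli_jeffreys")


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Empirical error rates and stopping-time summaries for one sequential
    design cell.  Standard errors are binomial at ``reps``."""

    reps: int
    seed: int | None
    alpha_nominal: float | None = None
    type1_rate: float | None = None
    type1_se: float | None = None
    type2_rate: float | None = None
    type2_se: float | None = None
    mean_tau: float | None = None
    median_tau: float | None = None
    cap_fraction: float = 0.0
    unreliable: bool = False
    extra: dict | None = None

    def row(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "extra"}
        if self.extra:
            d.update(self.extra)
        return d


def _binom_se(p: float, n: int) -> float:
    return math.sqrt(max(p * (1.0 - p), 0.0) / n)


def type1_under_stopping(spec: ModelSpec, alpha: float, n_cap: int, reps: int,
                         seed, sigma: float = 1.0) -> OperatingCharacteristics:
    """Empirical type-I error of continuous monitoring under a simple H0.

    Data are generated under H0; H0 is rejected the first time the
    posterior odds in favor of H0 drop below ``alpha`` — i.e. the H1-vs-H0
    odds exceed 1/alpha — at any n <= n_cap.  The universal bound guarantees
    a rate of at most alpha.  ``normal_jeffreys_var`` and ``jzs_ttest`` are
    also accepted: their free null parameter sigma carries the right-Haar
    (type 0) prior, for which the same guarantee holds at any fixed sigma.
    """
    if not 0.0 < alpha <= 1.0:
        raise InvalidInputError("alpha must lie in (0, 1]")
    if spec.family not in _SIMPLE_H0_FAMILIES + ("normal_jeffreys_var", "jzs_ttest"):
        raise InvalidInputError(
            f"type-I monitoring is not supported for family {spec.family!r}: "
            "composite H0 without a type 0 prior has no universal bound")
    if alpha == 1.0:
        # Degenerate bound: odds in favor of H0 are always < 1/0 ... i.e.
        # any odds value rejects at the first look.
        return OperatingCharacteristics(reps=reps, seed=seed, alpha_nominal=1.0,
                                        type1_rate=1.0, type1_se=0.0,
                                        mean_tau=1.0, median_tau=1.0)
    gen = gen_bernoulli if spec.family == "bernoulli_jeffreys" else gen_normal
    regime = SamplingRegime("H0", "fixed", {"sigma": sigma})
    obs = replicate_matrix(gen, regime, spec, reps, n_cap, seed)
    fn = batch_log_odds(spec.family, obs, spec)
    n_min = 1 if spec.family in _SIMPLE_H0_FAMILIES else 2
    rule = StoppingRule(threshold_a=1.0 / alpha, one_sided=True,
                        n_min=n_min, n_max=n_cap)
    res = run_sequential_batch(fn, reps, rule)
    reject = res.stop_reason == "upper"
    rate = float(reject.mean())
    tau_rej = res.tau[reject]
    return OperatingCharacteristics(
        reps=reps, seed=seed, alpha_nominal=alpha,
        type1_rate=rate, type1_se=_binom_se(rate, reps),
        mean_tau=float(tau_rej.mean()) if tau_rej.size else float("nan"),
        median_tau=float(np.median(tau_rej)) if tau_rej.size else float("nan"),
        extra={"n_cap": n_cap, "rejection_time": res.tau, "rejected": reject},
    )


def type2_schonbrodt(delta: float, B: float, n_min: int = 20,
                     n_cap: int = 5000, reps: int = 2000, seed=0,
                     cauchy_scale: float = 1.0) -> OperatingCharacteristics:
    """Type-II error of the sequential one-sample Bayesian t-test design.

    Take at least ``n_min`` observations, then after every observation stop
    as soon as the JZS Bayes factor exceeds ``B`` (reject H0) or falls
    below ``1/B`` (accept H0).  Data are N(delta, 1): the true standardized
    effect is ``delta`` > 0, so accepting H0 is the type-II error.  Runs
    reaching ``n_cap`` are counted in ``cap_fraction``; a cap fraction
    above 1% flags the estimate as unreliable.
    """
    if delta <= 0:
        raise InvalidInputError("delta must be positive")
    if B <= 1:
        raise InvalidInputError("B must exceed 1")
    spec = ModelSpec("jzs_ttest", mu0=0.0, cauchy_scale=cauchy_scale)
    regime = SamplingRegime("H1", "fixed", {"delta": delta, "sigma": 1.0})
    obs = replicate_matrix(gen_ttest_effect, regime, spec, reps, n_cap, seed)
    fn = batch_log_odds("jzs_ttest", obs, spec)
    rule = StoppingRule(threshold_a=B, one_sided=False, n_min=n_min,
                        n_max=None, cap=n_cap)
    res = run_sequential_batch(fn, reps, rule)
    accept_h0 = res.stop_reason == "lower"
    rate = float(accept_h0.mean())
    cap_fraction = float((res.stop_reason == "cap").mean())
    return OperatingCharacteristics(
        reps=reps, seed=seed,
        type2_rate=rate, type2_se=_binom_se(rate, reps),
        mean_tau=float(res.tau.mean()), median_tau=float(np.median(res.tau)),
        cap_fraction=cap_fraction, unreliable=cap_fraction > 0.01,
        extra={"delta": delta, "B": B, "n_min": n_min, "n_cap": n_cap,
               "tau": res.tau, "stop_reason": res.stop_reason},
    )
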