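"""Replicate data generators for every model family.

Each generator returns a :class:`ReplicateStream`: the replicate's parameters
are drawn once (from the prior, or fixed), then observations accrue from that
single parameter draw — the property that makes optional stopping meaningful.
Streams are seeded with :class:`numpy.random.SeedSequence` spawning, so a root
seed reproduces every replicate bit-for-bit in any execution order.

Two sampling regimes are supported.  ``from_prior`` draws the H1 parameter
from its prior (the prior-calibration experiments); ``fixed`` holds it at a
stated value (the strong-calibration experiments).  The improper Jeffreys
prior on sigma can never be sampled — sigma is always a fixed, explicit
input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .models import DesignMatrix, InvalidInputError, ModelSpec

__all__ = [
    "IllegalRegimeError",
    "SamplingRegime",
    "ReplicateStream",
    "RegressionStream",
    "gen_normal",
    "gen_ttest_effect",
    "gen_regression",
    "gen_bernoulli",
    "fertilizer_design",
    "spawn_streams",
    "replicate_matrix",
    "streams_to_frame",
    "draw_inverse_gamma",
]


class IllegalRegimeError(InvalidInputError):
    """Requested sampling regime is not defined (e.g. sampling sigma from
    the improper Jeffreys prior)."""


@dataclass(frozen=True)
class SamplingRegime:
    """Which hypothesis to sample under and where its parameters come from.

    ``fixed_params`` may contain ``mu``, ``sigma``, ``delta`` (standardized
    effect size), ``beta`` (regression slope vector) and ``theta``
    (Bernoulli probability).  ``sigma`` is always a fixed input (default 1):
    it has an improper prior and cannot be sampled.
    """

    hypothesis: str = "H0"
    parameter_source: str = "from_prior"
    fixed_params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.hypothesis not in ("H0", "H1"):
            raise InvalidInputError("hypothesis must be 'H0' or 'H1'")
        if self.parameter_source not in ("from_prior", "fixed"):
            raise InvalidInputError("parameter_source must be 'from_prior' or 'fixed'")

    @property
    def sigma(self) -> float:
        sigma = float(self.fixed_params.get("sigma", 1.0))
        if sigma <= 0:
            raise InvalidInputError("sigma must be positive")
        return sigma

    def require(self, key: str) -> object:
        if key not in self.fixed_params:
            raise InvalidInputError(
                f"regime with parameter_source='fixed' requires fixed_params[{key!r}]"
            )
        return self.fixed_params[key]


class ReplicateStream:
    """One replicate: a parameter draw held fixed while observations accrue.

    ``next(k)`` returns k further observations; ``params`` exposes the
    underlying draw for audit.  Equal seeds give bit-identical streams.
    """

    def __init__(self, seed, params: dict, sampler: Callable[[np.random.Generator, int], np.ndarray]):
        self.seed = seed
        self.params = dict(params)
        self._sampler = sampler
        self._rng = np.random.default_rng(seed)
        self.n_drawn = 0

    def next(self, k: int = 1) -> np.ndarray:
        if k < 1:
            raise InvalidInputError("k must be >= 1")
        out = self._sampler(self._rng, self.n_drawn, k)
        self.n_drawn += k
        return out


class RegressionStream(ReplicateStream):
    """Stream of (x, y) rows following the fixed design order; ``next(k)``
    returns an array of shape (k, 2)."""


def _param_rng(seed) -> np.random.Generator:
    # Parameters and observations use separate child streams of the same
    # seed so that the parameter draw does not shift the observation noise.
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return np.random.default_rng(ss.spawn(1)[0]), ss


def gen_normal(regime: SamplingRegime, spec: ModelSpec, seed) -> ReplicateStream:
    """Normal observations for the known-variance, Jeffreys-variance and
    t-test families.

    H0: N(mu0, sigma^2).  H1: mean drawn from the family's prior
    (N(0,1) for ``normal_known_var``; mu = sigma * N(0,1) effect for
    ``normal_jeffreys_var``; mu = mu0 + sigma * Cauchy(0, r) for
    ``jzs_ttest``) or fixed via ``fixed_params['mu']``.
    """
    if regime.fixed_params.get("sigma") == "from_prior":
        raise IllegalRegimeError("sigma has an improper prior and cannot be sampled")
    if spec.family == "normal_known_var":
        sigma = 1.0
    elif spec.sigma_known is not None and "sigma" not in regime.fixed_params:
        sigma = spec.sigma_known
    else:
        sigma = regime.sigma
    prng, ss = _param_rng(seed)
    if regime.hypothesis == "H0":
        mu = spec.mu0
    elif regime.parameter_source == "fixed":
        mu = float(regime.require("mu"))
    elif spec.family == "normal_known_var":
        mu = float(prng.standard_normal())
    elif spec.family == "normal_jeffreys_var":
        mu = sigma * float(prng.standard_normal())
    elif spec.family == "jzs_ttest":
        mu = spec.mu0 + sigma * spec.cauchy_scale * float(prng.standard_cauchy())
    else:
        raise IllegalRegimeError(f"gen_normal does not support family {spec.family!r}")

    def sampler(rng, _start, k):
        return mu + sigma * rng.standard_normal(k)

    return ReplicateStream(ss, {"mu": mu, "sigma": sigma}, sampler)


def gen_ttest_effect(regime: SamplingRegime, spec: ModelSpec, seed) -> ReplicateStream:
    """t-test data indexed by the standardized effect size delta.

    H1 draws delta from Cauchy(0, cauchy_scale) (``from_prior``) or holds it
    at ``fixed_params['delta']``; observations are N(mu0 + delta*sigma,
    sigma^2).  H0 is delta = 0.
    """
    sigma = regime.sigma
    prng, ss = _param_rng(seed)
    if regime.hypothesis == "H0":
        delta = 0.0
    elif regime.parameter_source == "fixed":
        delta = float(regime.require("delta"))
    else:
        delta = spec.cauchy_scale * float(prng.standard_cauchy())
    mu = spec.mu0 + delta * sigma

    def sampler(rng, _start, k):
        return mu + sigma * rng.standard_normal(k)

    return ReplicateStream(ss, {"delta": delta, "mu": mu, "sigma": sigma}, sampler)


def draw_inverse_gamma(rng: np.random.Generator, shape: float, scale: float, size=None):
    """Draw from IG(shape, scale) (density ∝ g^{-shape-1} e^{-scale/g})."""
    return scale / rng.gamma(shape, 1.0, size=size)


def fertilizer_design(n: int, doses: np.ndarray | None = None) -> DesignMatrix:
    """Dose design of the fertilizer regression example: doses 0.1, 0.2,
    ..., 2.0 for the first 20 rows, then the cycle repeats (rows 21-23 carry
    doses 0.1, 0.2, 0.3, and so on)."""
    if doses is None:
        doses = np.round(np.arange(1, 21) * 0.1, 10)
    doses = np.asarray(doses, dtype=float).ravel()
    reps = int(np.ceil(n / doses.size))
    return DesignMatrix(np.tile(doses, reps)[:n].reshape(-1, 1))


def gen_regression(regime: SamplingRegime, X, spec: ModelSpec, seed,
                   mu: float = 0.0) -> RegressionStream:
    """Fixed-design regression data following the g-prior generative chain.

    Per replicate: g ~ IG(g_shape, g_scale), then beta | g ~ N(0,
    g sigma^2 n (X'X)^{-1}) on the centered initial design (or beta fixed),
    then y_i = mu + x_i beta + N(0, sigma^2).  Rows beyond the initial
    design repeat its rows in order (the stated extension order).
    """
    X = X if isinstance(X, DesignMatrix) else DesignMatrix(np.asarray(X, dtype=float))
    sigma = regime.sigma
    prng, ss = _param_rng(seed)
    g = None
    if regime.hypothesis == "H0":
        beta = np.zeros(X.d)
    elif regime.parameter_source == "fixed":
        beta = np.atleast_1d(np.asarray(regime.require("beta"), dtype=float))
        if beta.size != X.d:
            raise InvalidInputError("fixed beta must match the design width")
    else:
        g = float(draw_inverse_gamma(prng, spec.g_shape, spec.g_scale))
        Xc = X.centered()
        cov = g * sigma * sigma * X.n * np.linalg.inv(Xc.T @ Xc)
        beta = prng.multivariate_normal(np.zeros(X.d), cov)
    x_all = X.x

    def sampler(rng, start, k):
        idx = np.arange(start, start + k) % x_all.shape[0]
        xk = x_all[idx]
        y = mu + xk @ beta + sigma * rng.standard_normal(k)
        return np.column_stack([xk, y])

    return RegressionStream(ss, {"g": g, "beta": beta, "mu": mu, "sigma": sigma}, sampler)


def gen_bernoulli(regime: SamplingRegime, spec: ModelSpec, seed) -> ReplicateStream:
    """Bernoulli sequences: H0 has theta = 1/2; H1 draws theta from the
    Jeffreys Beta(1/2, 1/2) prior or holds it at ``fixed_params['theta']``."""
    prng, ss = _param_rng(seed)
    if regime.hypothesis == "H0":
        theta = 0.5
    elif regime.parameter_source == "fixed":
        theta = float(regime.require("theta"))
        if not 0.0 <= theta <= 1.0:
            raise InvalidInputError("theta must lie in [0, 1]")
    else:
        theta = float(prng.beta(0.5, 0.5))

    def sampler(rng, _start, k):
        return (rng.random(k) < theta).astype(float)

    return ReplicateStream(ss, {"theta": theta}, sampler)


# ---------------------------------------------------------------------------
# Batch plumbing for the replicate experiments
# ---------------------------------------------------------------------------

def spawn_streams(generator: Callable, regime: SamplingRegime, spec: ModelSpec,
                  reps: int, seed, **kwargs) -> list[ReplicateStream]:
    """Spawn ``reps`` independent replicate streams from one root seed."""
    if reps < 1:
        raise InvalidInputError("reps must be >= 1")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [generator(regime, spec=spec, seed=child, **kwargs)
            for child in root.spawn(reps)]


def replicate_matrix(generator: Callable, regime: SamplingRegime, spec: ModelSpec,
                     reps: int, n_max: int, seed, **kwargs) -> np.ndarray:
    """(reps, n_max) observation matrix: row i is replicate i's first n_max
    observations.  For regression streams the result has shape
    (reps, n_max, 2) with (x, y) pairs."""
    streams = spawn_streams(generator, regime, spec, reps, seed, **kwargs)
    return np.stack([s.next(n_max) for s in streams])


def streams_to_frame(streams: list[ReplicateStream], n: int) -> pd.DataFrame:
    """Export replicate datasets for audit: columns replicate_id, obs_index,
    x (regression only), y."""
    rows = []
    for i, s in enumerate(streams):
        obs = s.next(n)
        if obs.ndim == 2:
            for j in range(n):
                rows.append({"replicate_id": i, "obs_index": j,
                             "x": obs[j, 0], "y": obs[j, 1]})
        else:
            for j in range(n):
                rows.append({"replicate_id": i, "obs_index": j, "y": obs[j]})
    return pd.DataFrame(rows)
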