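"""Optional-stopping engine.

Feeds a replicate stream into a posterior-odds engine one observation at a
time (continuous monitoring) and stops the first time the running odds cross
a threshold: at odds >= a, or — unless the rule is one-sided — at odds <=
1/a.  Unbounded rules carry a hard cap, and runs that hit it are flagged,
never dropped.

:func:`run_sequential` handles one replicate through an arbitrary engine;
:func:`run_sequential_batch` is the vectorized workhorse used by the
calibration and operating-characteristic experiments, where the per-look
odds for all still-active replicates are computed in one array operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .models import DesignMatrix, InvalidInputError, ModelSpec, OddsValue, gprior_log_bf
from .synthetic_data import ReplicateStream

__all__ = [
    "StoppingRule",
    "SequentialRun",
    "BatchSequentialResult",
    "run_sequential",
    "run_sequential_batch",
    "run_sequential_gprior",
]

DEFAULT_CAP = 10_000

STOP_REASONS = ("upper", "lower", "n_max", "cap")


@dataclass(frozen=True)
class StoppingRule:
    """Stop when the running posterior odds reach ``threshold_a`` (or fall
    to ``1/threshold_a`` unless ``one_sided``), monitoring every observation
    from ``n_min``; give up at ``n_max`` (or at ``cap`` if unbounded)."""

    threshold_a: float = 10.0
    one_sided: bool = False
    n_min: int = 1
    n_max: int | None = 25
    cap: int = DEFAULT_CAP

    def __post_init__(self) -> None:
        if self.threshold_a <= 1.0:
            raise InvalidInputError("threshold_a must exceed 1")
        if self.n_min < 1:
            raise InvalidInputError("n_min must be >= 1")
        if self.n_max is not None and self.n_max < self.n_min:
            raise InvalidInputError("n_max must be >= n_min")
        if self.cap < self.n_min:
            raise InvalidInputError("cap must be >= n_min")

    @property
    def horizon(self) -> int:
        """Last sample size that will ever be evaluated."""
        return self.n_max if self.n_max is not None else self.cap

    @property
    def log_a(self) -> float:
        return float(np.log(self.threshold_a))


@dataclass(frozen=True)
class SequentialRun:
    """One replicate's trajectory: odds per look (from ``n_min`` to ``tau``),
    the stopping time, and why the run ended."""

    tau: int
    final_odds: OddsValue
    log_trajectory: np.ndarray = field(repr=False)
    stop_reason: str
    n_min: int
    meta: dict = field(default_factory=dict, repr=False)

    @property
    def trajectory(self) -> list[OddsValue]:
        return [OddsValue(float(v)) for v in self.log_trajectory]


def _stop_reason(log_odds: float, rule: StoppingRule, n: int) -> str | None:
    if log_odds >= rule.log_a:
        return "upper"
    if not rule.one_sided and log_odds <= -rule.log_a:
        return "lower"
    return None


def run_sequential(stream: ReplicateStream, engine: Callable[[np.ndarray], OddsValue],
                   rule: StoppingRule) -> SequentialRun:
    """Run one replicate: evaluate ``engine`` on the growing data prefix
    after each observation from ``rule.n_min`` on, stop at the first
    threshold crossing, at ``n_max``, or at the cap."""
    horizon = rule.horizon
    data = np.empty(0)
    logs: list[float] = []
    for n in range(1, horizon + 1):
        data = np.concatenate([data, np.atleast_1d(stream.next(1)).ravel()])
        if n < rule.n_min:
            continue
        log_odds = engine(data).log_value
        logs.append(log_odds)
        reason = _stop_reason(log_odds, rule, n)
        if reason is not None:
            return SequentialRun(n, OddsValue(log_odds), np.array(logs), reason, rule.n_min)
    reason = "n_max" if rule.n_max is not None else "cap"
    return SequentialRun(horizon, OddsValue(logs[-1]), np.array(logs), reason, rule.n_min)


@dataclass(frozen=True)
class BatchSequentialResult:
    """Vectorized analogue of a list of :class:`SequentialRun`: per-replicate
    stopping time, final log odds and stop reason."""

    tau: np.ndarray
    final_log_odds: np.ndarray
    stop_reason: np.ndarray  # array of strings from STOP_REASONS
    reps: int

    def frame(self):
        import pandas as pd

        return pd.DataFrame({
            "replicate_id": np.arange(self.reps),
            "tau": self.tau,
            "log_final_odds": self.final_log_odds,
            "stop_reason": self.stop_reason,
        })


def run_sequential_batch(log_odds_fn: Callable[[int, np.ndarray], np.ndarray],
                         reps: int, rule: StoppingRule) -> BatchSequentialResult:
    """Run many replicates at once.

    ``log_odds_fn(n, active)`` must return the running log posterior odds at
    prefix length ``n`` for the replicate indices in ``active``.  The caller
    owns the data (typically pre-generated matrices plus cumulative sums);
    this function owns the stopping logic.
    """
    tau = np.full(reps, -1, dtype=int)
    final = np.full(reps, np.nan)
    reason = np.full(reps, "", dtype=object)
    active = np.arange(reps)
    horizon = rule.horizon
    for n in range(rule.n_min, horizon + 1):
        lo = np.asarray(log_odds_fn(n, active), dtype=float)
        hit_upper = lo >= rule.log_a
        if rule.one_sided:
            hit_lower = np.zeros_like(hit_upper)
        else:
            hit_lower = lo <= -rule.log_a
        stopped = hit_upper | hit_lower
        last = n == horizon
        if last:
            idx_last = active[~stopped]
            tau[idx_last] = n
            final[idx_last] = lo[~stopped]
            reason[idx_last] = "n_max" if rule.n_max is not None else "cap"
        idx = active[stopped]
        tau[idx] = n
        final[idx] = lo[stopped]
        reason[idx] = np.where(hit_upper[stopped], "upper", "lower")
        active = active[~stopped]
        if last or active.size == 0:
            break
    return BatchSequentialResult(tau, final, reason.astype(str), reps)


def run_sequential_gprior(stream, rule: StoppingRule, prior_convention: str,
                          planned_X: DesignMatrix | None = None,
                          spec: ModelSpec | None = None) -> SequentialRun:
    """Sequential g-prior regression run under one of the two stopping-time
    prior conventions the design question admits:

    ``current_n``
        at each look the prior is scaled by the design realized so far;
    ``max_n``
        the prior is held at the planned maximum design (``planned_X``).

    Looks where the realized design is not yet usable (fewer than three
    rows, or a singular centered X'X) are skipped and recorded in
    ``meta['skipped_looks']``.
    """
    if prior_convention not in ("current_n", "max_n"):
        raise InvalidInputError("prior_convention must be 'current_n' or 'max_n'")
    if prior_convention == "max_n" and planned_X is None:
        raise InvalidInputError("max_n convention requires planned_X")
    spec = spec or ModelSpec("gprior_regression")
    horizon = rule.horizon
    xs: list[np.ndarray] = []
    ys: list[float] = []
    logs: list[float] = []
    skipped: list[int] = []
    log_odds = np.nan
    for n in range(1, horizon + 1):
        row = np.atleast_2d(stream.next(1))
        xs.append(row[0, :-1])
        ys.append(row[0, -1])
        if n < rule.n_min:
            continue
        X = DesignMatrix(np.vstack(xs))
        Xc = X.centered()
        if n < 3 or np.linalg.matrix_rank(Xc.T @ Xc) < X.d:
            skipped.append(n)
            continue
        prior_X = X if prior_convention == "current_n" else planned_X
        try:
            log_odds = gprior_log_bf(np.array(ys), X, prior_X, spec)
        except InvalidInputError:
            skipped.append(n)
            continue
        logs.append(log_odds)
        reason = _stop_reason(log_odds, rule, n)
        if reason is not None:
            return SequentialRun(n, OddsValue(log_odds), np.array(logs), reason,
                                 rule.n_min, {"skipped_looks": skipped,
                                              "prior_convention": prior_convention})
    reason = "n_max" if rule.n_max is not None else "cap"
    return SequentialRun(horizon, OddsValue(logs[-1]), np.array(logs), reason,
                         rule.n_min, {"skipped_looks": skipped,
                                      "prior_convention": prior_convention})
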