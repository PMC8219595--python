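# Methods

## Models and engines

All engines return posterior odds of H1 over H0 with prior odds 1-to-1
(configurable via `ModelSpec.prior_odds`), carried as natural logs so that
extreme inputs never overflow: `log_value` is authoritative and `value =
exp(log_value)`.

**Normal mean, known variance.** Data `x_i ~ N(μ, 1)`; H0: μ = 0; H1:
μ ~ N(0, 1).  The odds are closed form, `exp(n²x̄²/(2(n+1)))/√(n+1)`,
evaluated in the log domain.  The N(0,1) prior keeps the effect scale of
the observations, so the mean equals the effect size.

**Normal mean, unknown variance.** Jeffreys prior 1/σ on σ in both
hypotheses; under H1 the mean has prior N(0, σ²) (standard normal on the
effect size).  The (μ, σ) double integral reduces to
`(n+1)^{-1/2} (1 − (Σx)²/((n+1)Σx²))^{-n/2}`.  The improper prior is never
sampled or normalized: it appears only inside a ratio of integrals over
identical σ ranges, which is well defined in the limit.  The odds are
exactly invariant under rescaling all observations — the group structure
that makes 1/σ a right-Haar (type 0) prior.

**JZS one-sample t-test.** Jeffreys prior on σ in both hypotheses; under
H1 a Cauchy(0, r) prior on the standardized effect δ = (μ − μ0)/σ, r = 1
by default.  Using the scale-mixture representation δ|g ~ N(0, g),
g ~ IG(1/2, r²/2), the (μ absent, σ, δ) integrals collapse analytically
and the Bayes factor depends on the data only through (t, n):

    BF10 = ∫ (1+ng)^{-1/2} [ (1 + t²/((1+ng)ν)) / (1 + t²/ν) ]^{-n/2}
           IG(g; 1/2, r²/2) dg,   ν = n − 1.

This route was chosen over direct quadrature of the Cauchy-weighted
δ-integral because (a) it is a smooth 1-d integral with no heavy-tailed
integrand, and (b) a (t, n)-only engine vectorizes across thousands of
sequential replicates at each look, which the calibration and
operating-characteristic simulations rely on.  The independent test oracle
integrates the δ-route directly (inner σ-integrals via the u = 1/σ
substitution), so the two derivations check each other; the engine also
agrees with pingouin's JZS implementation to ~1e-11 relative.

**g-prior regression.** Fixed design X (covariates only; the intercept μ
and σ carry the Jeffreys prior 1/σ and are removed analytically by
centering y and X — the standard treatment of the common location/scale).
Under H1, β|g ~ N(0, g σ² n_p (X_p'X_p)⁻¹) scaled by a *prior design* X_p
with n_p rows, and g ~ IG(1/2, √2/8).  Conditional on g the marginal
likelihood ratio is closed form through the SVD of the whitened design;
the g-mixture is integrated numerically.  `prior_X` is an explicit
argument with no default at the engine level: under sequential data the
choice between "the design realized so far" and "the planned maximum
design" is exactly the ill-posedness of this (type II) prior, and
`run_sequential_gprior` implements both conventions.  Note that the scaled
prior n(X'X)⁻¹ is invariant under duplicating a design cycle, so a planned
design of two full dose cycles coincides with one cycle; the conventions
genuinely differ at intermediate sample sizes such as 23 of 40 pots.

**Bernoulli, Jeffreys prior.** H0: θ = 1/2; H1: θ ~ Beta(1/2, 1/2).  The
odds are `B(n1+1/2, n0+1/2)/B(1/2,1/2) · 2^{n1+n0}` via log-Beta
functions.  The case n1 = n0 = 0 is rejected rather than defined as 1.

### Numerical integration

All g-integrals (JZS, g-prior BF, g-prior marginal density) use a fixed
600-node Gauss–Legendre rule on w = log g over [−13, 40], evaluated in the
log domain and combined by logsumexp.  The integrand decays like
exp(−b e^{−w}) on the left and e^{−w} on the right, so this range covers
every (t, n) arising in the simulations with error far below the 1e-6
relative tolerance the oracle-equivalence tests demand; agreement with
adaptive quadrature and with external implementations is verified in the
test suite rather than assumed.  The g-prior marginal density of a scalar
slope is also available in closed form (the mixture is a Cauchy with scale
`s·√(2·√2/8)`), which the tests use as a cross-check.

## Synthetic data

Generators mirror the generative reading of each hypothesis pair.  Each
replicate is a `ReplicateStream`: parameters are drawn once (H1 parameters
either `from_prior` or `fixed`), then observations accrue i.i.d. from that
draw — the property that makes a stopping time well defined.  One root
seed spawns per-replicate `SeedSequence` children, so any experiment is
bit-reproducible in any execution order; within a stream, parameters and
observations use separate child generators so the parameter draw does not
shift the observation noise.

σ can never be sampled (its Jeffreys prior is improper); it is a fixed
input, default 1, with σ² ∈ {1, 2} exercised in tests because type 0
calibration must hold at *any* value.  Strong-calibration defaults follow
the stated policy of fixing parameters in a region of large prior density:
μ = 1.3 against μ0 = 1 (δ = 0.3) for the t-test.  The regression stream
follows the dose design 0.1, 0.2, …, 2.0 and extends it by repeating the
cycle (rows 21–23 carry doses 0.1, 0.2, 0.3).

What the generators emulate is exactly the stylized simulation protocol:
i.i.d. normal or Bernoulli observations with parameters from conjugate or
default priors.  Real data violate these assumptions in ways the
experiments deliberately ignore (non-normality, drift, dependence between
observations, measurement error), so passing calibration here demonstrates
properties of the *inference machinery*, not robustness on real data.

## Sequential engine

Continuous monitoring: the odds are evaluated after every observation from
`n_min` (1 where the engine is defined at n = 1; 2 where a variance must
be estimated) and the run stops the first time odds ≥ a, or ≤ 1/a unless
the rule is one-sided, or at `n_max`.  Unbounded rules carry a hard cap
(default 10,000) and cap hits are flagged, never dropped.  Two
implementations exist deliberately — a scalar per-replicate loop and a
vectorized batch runner over pre-generated observation matrices — and the
test suite asserts they agree replicate-by-replicate; the batch runner
powers every large experiment.

## Calibration diagnostics

Final log odds from equally many H0 and H1 replicates are histogrammed on
a common grid of width 0.1 (natural log; the width is configurable, so
base-10 replication is a flag away).  Edges are aligned so that log-odds 0
is always an edge, making binning a pure function of the inputs.  The
observed odds per bin is the count ratio H1/H0; the nominal odds is the
bin's geometric center (deterministic and data-independent, rather than a
count-weighted mean).  Bins where either histogram holds fewer than
`min_count = 10` replicates are masked: a bin enters the curve only when
its denominator is nonzero, so sparse denominators are biased upward and
would systematically flatten the curve, not just add noise.  The summary
is the least-squares slope of log observed on log nominal over unmasked
bins plus the maximum absolute log deviation; per-bin standard errors are
the Poisson-propagated `sqrt(1/c1 + 1/c0)`.

Under optional stopping at threshold a, the final odds pile up just
outside a and 1/a; bins stay uniform in log odds with no special boundary
treatment, matching how the histograms are meant to be read.

## Frequentist operating characteristics

**Type-I under stopping.** With a simple H0 (or a composite H0 whose only
free parameter carries its type 0 prior), rejecting whenever the posterior
odds in favor of H0 drop below α is rejected with probability at most α
under any stopping rule — the universal bound / Doob's maximal inequality
applied to the likelihood-ratio martingale.  The simulation monitors every
n up to `n_cap` and reports the empirical rate with its binomial standard
error; nested caps share streams so the monotone-in-looks property is
testable exactly.

**Sequential t-test type-II error.** The design: collect `n_min = 20`
observations, then stop as soon as the JZS Bayes factor leaves [1/B, B];
accepting H0 below 1/B under a true effect δ is the type-II error.
Defaults δ = 0.3, B = 7, cap 5,000 (cap hits above 1% flag the estimate
unreliable).  The engine's (t, n) form lets each look evaluate all active
replicates in one quadrature pass, which keeps 2,000-replicate runs under
ten seconds.

A sensitivity worth knowing: at δ = 0.3, B = 7 this design's type-II error
is ≈ 21% with the standard Cauchy prior (r = 1, this package's default,
matching the t-test engine), ≈ 4.8% with the narrower r = √2/2 scale that
common software defaults to, and ≈ 0.05% at r = 1/2.  Published type-II
tables for such designs are tied to a specific prior scale (and sometimes
to directional priors); quoting them without the scale is not meaningful.
The acceptance script reports the r = 1 number.

## Experiment scale

Headline experiments default to 20,000 replicates per hypothesis; the
acceptance suite runs scaled-down versions at 5,000 replicates (2,000 for
the type-II design point, 10,000 for the type-I bound) with the
correspondingly widened tolerances stated in the tests — calibration
slopes are asserted in [0.9, 1.1], and qualitative classifications
("calibrated"/"violated") use a [0.85, 1.15] slope band plus a −3·SE rule
on the mean log deviation of high-odds bins.  These sizes were chosen so
the full suite completes in a couple of minutes while keeping binomial
errors well inside the asserted bands.

## Known limitations

- Two-sample t-tests, ANOVA and contingency-table Bayes factors are out of
  scope; so are posterior inference on parameters, group-sequential
  alpha-spending designs, and E-variable/safe-test constructions.
- The Bernoulli Jeffreys prior is implemented in its fixed-n form only;
  the stopping-rule-dependent variant (which becomes improper under rules
  like "stop after three consecutive ones") is noted but not constructed.
- `check_prior_calibration` refuses the g-prior family: with a
  design-dependent prior the experiment is ill-defined, and the refusal is
  deliberate API behavior, demonstrated instead through the two-convention
  sequential runs.
- Calibration is summarized by slope and deviations, not by a formal
  hypothesis test of calibration.
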