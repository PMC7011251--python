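# Methods

## Model and assumptions

A tray holds `n` seeds whose emergence times are independent and
identically distributed. Each seed is viable with probability `alpha`
(the emergence yield); non-viable seeds never emerge no matter how long
the observation runs. A viable seed's emergence time T follows the
Gompertz / Gumbel-minimum distribution

    F(t) = exp(-exp(-B (t - C))),   t in days,

which is increasing in t with F(C) = 1/e. `B` (1/day) controls how
synchronous the emergence wave is; `C` (days) locates it. The name
"half-time" for C is kept because it is the customary label for this
parameter in emergence assays, but note that under this parameterization
the median of a viable seed's emergence time is

    t50 = C - log(log 2) / B  >  C,

so summary tables also report `t50` derived per posterior draw.

Observation is interval-censored: the instrument reports only the 2-h
interval in which each emergence happened (times are stored in hours in
all files and containers; the single hours-to-days conversion lives in
the likelihood). A seed not seen to emerge by the horizon t_T is either
non-viable or merely late, giving the mixture factor
`1 - alpha F(t_T)`. The full tray likelihood is the product of one such
factor per censored seed and one factor `alpha (F(t_{i+1}) - F(t_i))` per
emerged seed; intervals with zero counts contribute a factor of one.
A tray where nothing emerged is legal: its posterior for alpha simply
concentrates below the prior mean.

Priors are independent: `alpha ~ Beta(alpha_a, alpha_b)`, and `B`, `C`
Gaussian truncated to (0, inf) with the truncation constant included so
each prior integrates to one (an untruncated Gaussian would put mass on
negative rates and times). Defaults: Beta(1, 9), `B ~ N(2, 0.5^2)`,
`C ~ N(5, 2^2)`. The Beta(1, 9) default has mean 0.1, far below the
yields (~0.95) of healthy maize trays, and visibly pulls the posterior
mean of alpha down by ~0.05 at n = 110; it is retained as the package
default for continuity with the prior specification this model family is
usually quoted with, and every interface accepts other shapes. The
posterior for B and C is insensitive to this choice.

## Inference

The reference sampler is an adaptive random-walk Metropolis on the
transformed space `z = (logit alpha, log B, log C)`, targeting the
unnormalized log posterior plus the log-Jacobian
`log[alpha (1-alpha) B C]`. Working on z removes all support boundaries.
Defaults: 4 chains, 10 000 iterations, the first 5 000 discarded as
burn-in, thinning 1 (draws are stored unthinned because the pairing
queries subsample anyway). During burn-in only, a global step-size factor
follows a Robbins–Monro recursion toward 30% acceptance (a standard
compromise for low-dimensional random-walk kernels) every 50 iterations,
and the per-coordinate proposal scales are refreshed every 200 iterations
from the sd of the recent chain history; both are frozen afterwards so
the kept segment is a valid Markov chain. Chains start from a
moment-based guess (emerged fraction clipped to [0.05, 0.95] for alpha;
the midpoint of the interval containing the median emergence for C; the
prior mean for B) with a small jitter per chain; a non-finite log
posterior at the start raises an initialization error. Every random
number comes from a `SeedSequence` spawned off the user seed, so runs are
bit-reproducible.

Convergence is summarized by split R-hat and bulk effective sample size,
computed with arviz; R-hat above 1.05 triggers a logged warning and above
1.01 a flag in the report. The test suite cross-checks arviz's split
R-hat against a directly coded between/within-variance formula.

As an independent validation route, `grid_posterior` evaluates the same
unnormalized posterior on an `n_grid`^3 lattice (default 60) and
normalizes with the trapezoid rule. The initial ranges cover the central
99.9% prior mass per axis, except that the alpha axis is widened to
essentially the whole unit interval: with a Beta(1, 9) prior the 99.9%
prior range ends near 0.57 while tray posteriors live near 0.9, and a
lattice that excluded them would be useless as an oracle. Two successive
zoom passes onto mean ± 8 sd per axis make the marginal moments
insensitive to the lattice resolution (halving the spacing moves means by
< 1e-3); the zoom window is recomputed from the previous pass, so the
procedure stays fully deterministic. The MCMC and grid routes agree on
simulated trays to within 0.02 (alpha) and 0.1 (B, C) — tested.

## Queries

Group comparisons pair draws from two independently fitted posteriors:
`n_pairs` indices are drawn with replacement from each archive
(default 1000), and the answer is the fraction of pairs satisfying the
question — strictly `<` for "emerges earlier", `>=` (ties succeed) for
"yield at least 5% higher", mirroring how such questions are phrased.
Reported probabilities carry the binomial Monte-Carlo standard error
`sqrt(p(1-p)/n_pairs)` so the estimator uncertainty is visible.
Resampling with replacement is used because the two posteriors come from
independent fits and their stored draw counts may differ; the estimate
converges to the exact posterior probability as the archives and
`n_pairs` grow.

## Synthetic data

The generator draws each seed's viability as a Bernoulli(alpha) and each
viable seed's emergence time through the quantile function
`t = C - log(-log u)/B`, `u ~ U(0,1)` — inverse-CDF sampling chosen so
the generator shares no code with the density it is used to test. Times
are binned onto the design grid; times past the horizon join the
non-viable seeds in the censored count (censoring happens only at the
horizon; there is no mid-study dropout). The default design is 110 seeds
per tray observed every 2 h for 12 days (144 intervals), and the built-in
16-group reference design uses per-group true parameters in the range
alpha 0.91–0.99, B 0.9–2.3 /day, C 3.5–5.3 days — the regime of maize
emergence under control, priming and salt-stress conditions. What the
generator does **not** emulate: spatial position effects within a tray,
seed-to-seed parameter heterogeneity beyond the viable/non-viable
mixture, imaging misclassification, and mid-study censoring. Passing
tests therefore demonstrate correctness of the inferential machinery
under the model's own assumptions, not robustness to their violation.

## Numerical choices

* Interval probabilities are computed in log space. With
  `a(t) = exp(-B(t-C))`, the mass of `[lo, hi)` is
  `exp(-a_hi) (1 - exp(-(a_lo - a_hi)))` and the difference
  `a_lo - a_hi` is formed as `a_lo (1 - exp(-B (hi - lo)))`, which stays
  finite deep in the right tail where the two CDF values are equal in
  floating point. Exact-zero interval mass maps to `-inf`, never an
  exception.
* The censored factor uses `log1p(-alpha F(t_T))`.
* Probabilities and densities at the support edges (`alpha` of 0 or 1)
  follow the conventions of `xlogy`/`xlog1py`: a zero count times a
  `-inf` log never occurs because zero-count intervals are skipped.
* Degenerate grids (posterior zero at every lattice point) raise rather
  than return garbage.

## Problem sizes in the checks

The acceptance-style tests run the sampler at reduced but adequate
lengths (2 chains × 4000 iterations for the 20-replicate coverage study;
4 × 8000 for the oracle comparison), sizes at which the Monte-Carlo error
of a posterior mean is an order of magnitude below the tolerances being
asserted. `scripts/acceptance.py` uses the full default sampler settings
for the headline fits.

## Known limitations

* A single event-time family (Gompertz/Gumbel) is built in. The
  likelihood machinery only consumes CDF values, so adding Weibull or
  log-logistic variants is a localized extension, but no such option is
  exposed yet.
* No covariate/regression structure: groups are compared through
  independent per-tray posteriors, which is exactly the intended use, but
  means information is not pooled across trays of the same treatment.
* The pairing queries report raw posterior probabilities; no
  multiple-comparison adjustment is applied across many pairwise
  contrasts, by design.
* Events files cannot represent empty observation intervals, so an
  events-dialect round trip preserves the data but not necessarily the
  full empty grid; the counts dialect is lossless.
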