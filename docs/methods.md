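# Methods

## Model

The package implements a two-stage site-occupancy model for replicated eDNA
surveys.  Site *i* is occupied with probability `psi_i`; each water sample
*j* from the site contains detectable DNA with probability `theta11` if the
site is occupied and `theta10` (a field false positive: contamination,
transported DNA) if it is not; each of the sample's `K` qPCR replicates
amplifies with probability `p11` if DNA is present and `p10` (a lab false
positive) if it is not.  The observation per sample is the count `y` of
amplifying replicates, `y | w ~ Binomial(K, p11 or p10)`.

Only occupancy is covariate-driven: `psi_i = logistic(x_i' beta)`.  Error
rates are shared across sites and laboratories.

### Identifiability

With one sample per site (M = 1) the likelihood for a site depends on the
parameters only through `q_i = psi_i * theta11 + (1 - psi_i) * theta10` and
the Stage-2 rates.  `p11` and `p10` are tightly identified (every replicate
is a Bernoulli trial); the split of `q` into occupancy and Stage-1 rates is
identified jointly by the covariate structure and the informative priors —
this is why the occupancy intercept and `theta11`/`theta10` carry wide
posteriors in intercept-only fits, and why parameter-recovery experiments
should expect the posterior mean of occupancy to be pulled along the
`q`-ridge by the priors (in constant-occupancy synthetic fits at the default
priors the site-mean occupancy posterior can sit several hundredths below a
generating value of 0.198 while matching the exact posterior computed by
quadrature).  No extra constraints are invented; the priors are the
identification device.

## Priors and their parameterization

| quantity | prior | default | why |
|---|---|---|---|
| theta11, p11 | Beta(m·c, (1−m)·c) | m = 0.9, c = 10 → Beta(9, 1) | true-positive rates near 1 |
| theta10, p10 | same | m = 0.1, c = 10 → Beta(1, 9) | false-positive rates near 0 |
| intercept | Normal(logit(0.5), 4) on the logit scale | | a priori occupancy centred at 0.5, broad |
| coefficients | Normal(0, 0.25) per design column | | slab for standardized covariates |
| inclusion | Bernoulli(h) per group, h = 2 / n_groups | | two covariates expected a priori |

The Beta concentration `c = 10` is a documented choice: the survey app this
model mirrors states only the prior means (0.9 / 0.1), so a mild strength
matching those means was fixed once and exposed as
`beta_prior_concentration` for sensitivity analysis.  Continuous covariates
are standardized before modelling so a single slab variance (0.25) is
meaningful across covariates of different scales; interactions are products
of standardized parents and are not re-standardized.

With `enforce_ordering` (default on) the prior is additionally truncated to
`theta11 > theta10` and `p11 > p10`.  Without it, small or degenerate data
sets can label-switch into the mirrored mode (true and false positive roles
exchanged); with the default informative priors and ordering the sampler
does not.  The orderings are imposed by jointly redrawing a pair from its
conjugate conditionals until ordered (a draw from the truncated joint
conditional); after 1,000 failures the pair is sorted with a logged warning.

## Sampler

One sweep, in fixed order: (1) latent occupancy `z` from its full
conditional with the sample state `w` marginalized out (Rao-Blackwellized,
log-space); (2) `w | z` per sample; (3) conjugate Beta updates of the four
error rates; (4) Pólya-Gamma auxiliaries `omega_i ~ PG(1, x_i' beta)`;
(5) one Add–Delete–Swap Metropolis–Hastings move on the group-inclusion
vector, with the move type uniform over those legal in the current state,
Hastings ratios accounting for the reverse state's legal types, and the
coefficient vector integrated out of the conditionally Gaussian augmented
likelihood; (6) coefficients of the active columns from their exact
Gaussian conditional.  Steps (5)–(6) form a block update of
(inclusion, coefficients), so integrating the coefficients in (5) is a
valid partially collapsed move.  Whole groups — all dummies of a factor —
enter and leave together.

The PG(1, z) sampler is Devroye's alternating-series rejection method
(truncated inverse-Gaussian proposal left of t = 0.64, tilted exponential
right of it), numba-jitted; it is validated against the closed-form mean
`tanh(z/2)/(2z)`, the variance 1/24 at z = 0, and a truncated
infinite-convolution construction by two-sample Kolmogorov–Smirnov tests.

Thinning keeps `n_thinned_draws` evenly spaced post-burn-in sweeps
(defaults: 5,000 burn-in, 3,000 iterations, 100 draws, one chain).  All
randomness flows from one `numpy` Generator plus one PG stream, both seeded
from `ModelConfig.seed` through `SeedSequence.spawn`; identical
configuration and seed reproduce draws bit for bit.  Binomial coefficients
are cached per data row; every likelihood product is accumulated in log
space.

Site bookkeeping: detection tables are internally ordered by sorted site
id, and `fit` permutes the design-matrix rows to that order (erroring if
the site sets differ), so covariate rows always face the right sites
regardless of input ordering.

## Variable selection behaviour

PIP is the fraction of retained draws in which a group is included; groups
with PIP > 0.5 are flagged important.  Two calibration facts worth knowing:

* With informative data (large S) the integrated-out marginal likelihood
  carries an Occam factor, so null covariates settle well *below* the prior
  inclusion probability `h`; PIP approaches `h` only as the data become
  uninformative (verified in the tests by shrinking the slab variance).
* A null covariate can still reach moderate PIP by chance association with
  the latent occupancy pattern; what the calibration tests guarantee is
  agreement with the exact inclusion posterior (enumeration and quadrature
  oracles), not that every null PIP is tiny in every data set.

## Posterior summaries

Credible intervals are equal-tailed 2.5/97.5 percentile intervals
throughout.  Pairwise categorical contrasts are per-draw differences of
level coefficients (the baseline level's coefficient is identically zero),
reported both marginally (excluded draws contribute zero differences) and
conditional on inclusion.  The conditional-absence curve evaluates, per
retained draw, the posterior probability that a site is unoccupied given
`x` of `K` replicates amplified; by default the draw's site-averaged
occupancy enters the formula (one national curve), with a fixed-psi variant
exposed.

Replicate-level false-positive magnification is reported analytically:
`1 - (1 - p10)^K` for a DNA-free sample (0.215 at p10 = 0.02, K = 12), with
an optional Stage-1 path for unoccupied sites
(`theta10 * (1 - (1 - p11)^K) + (1 - theta10) * (1 - (1 - p10)^K)`).  A
frequently quoted rounded figure of 0.24 for this quantity is not
recoverable from the point estimates: averaging `1 - (1 - p10)^K` over
posterior draws of `p10` moves the value only in the third decimal, so the
package reports the analytic value and the posterior-averaged variant and
leaves the discrepancy visible.

## Goodness of fit

Each posterior-predictive repeat maps one retained draw to one simulated
survey (repeat r uses draw r's parameters and the site-level occupancy
probabilities implied by its coefficients), simulating the full two-stage
process at the survey's S, M, K.  Box summaries use the median, quartiles
and whiskers at quartile ± 1.5·IQR; values beyond the whiskers are reported,
not clipped.  The envelope comparison flags, per replicate count, whether
the observed count falls inside the whisker range.  Two structural
diagnostics mirror the replicate-level error story: the amplification
histogram among DNA-free samples is Binomial(K, p10) — at the published
values essentially all samples amplifying in one or two replicates are
false positives — and the histogram among DNA-containing samples is
Binomial(K, p11), whose mode (ten replicates at p11 = 0.808, K = 12) is the
predicted amplification peak.  Note that the *overall* simulated count
histogram peaks at one amplifying replicate (~758 expected false-positive
singletons among ~3,940 DNA-free samples at 4,925 sites), so "peak
amplification" statements refer to the DNA-present histogram.

## Synthetic data

The generator draws exactly the process the model assumes, sharing the
design-matrix code path with the fitting side (covariate-driven occupancy
uses the same standardization and dummy coding).  Level frequencies of
synthetic categorical factors default to a single Dirichlet(0.5,...) draw
per seed, giving the heavily unbalanced factors typical of land-cover and
bedrock classifications.  Draw order is fixed (covariates, then z, then w,
then y) under one seeded generator.

What it does *not* emulate: spatial autocorrelation between ponds,
year-to-year dynamics, pond drying, laboratory random effects, or
covariate-dependent error rates.  Tests passing on this generator therefore
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to the ways real surveys violate them — the
posterior-predictive envelope is the tool for detecting such lack of fit on
real data.

## Problem sizes and numerical choices

The analysis scripts and tests run the full published MCMC schedule but at
2,000 sites (the national survey's 4,925-site design at a desk-friendly
scale; the posterior-predictive simulations do use S = 4925).  The exact
quadrature oracle used to validate the sampler integrates the five-parameter
intercept-only posterior on 32-node Gauss–Legendre grids per dimension,
exploiting the fact that the M = 1 likelihood depends on the data only
through replicate-count frequencies.  Posterior-predictive medians of
low-mean counts (expected counts below ~6) are knife-edge order statistics:
their sample medians across 100 repeats can land half a count away from the
long-run value, which is inherent to the quantity, not to the simulator.

Degenerate inputs are handled without error: all-zero detection data yield
posteriors near the prior for the unidentified parameters; empty strata in
the conjugate updates fall back to prior draws; probabilities at exactly 0
or 1 short-circuit the log-space likelihoods.

## Known limitations

* Single-chain inference; no cross-chain convergence diagnostics beyond
  determinism and the oracle tests.
* No covariates on error rates and no multi-laboratory random effects, so
  heterogeneous labs will surface as lack of fit rather than be absorbed.
* The correlation-pruning rule (drop the lower-priority member of each
  |r| ≥ 0.7 pair, priority = input order unless given) is deterministic but
  order-dependent, as any greedy rule is.
* No multiple-testing adjustment across the many categorical pair
  contrasts; wide factors produce some chance-significant pairs.
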