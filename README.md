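# edna-occupancy

Bayesian site-occupancy modelling for environmental-DNA (eDNA) surveys in
which *both* false positives and false negatives occur at two distinct
stages: field sample collection and laboratory qPCR.  The package was built
around the design of national great crested newt (*Triturus cristatus*) pond
surveys — one water sample per pond, twelve qPCR replicates per sample — but
the model applies to any single-species eDNA survey with replicated
amplification.

## The model

For site *i* with covariate vector *x_i*:

```
z_i  ~ Bernoulli(psi_i),          psi_i = logistic(x_i' beta)    site occupancy
w_ij | z_i ~ Bernoulli(theta11 if z_i = 1 else theta10)          sample holds DNA
y_ij | w_ij ~ Binomial(K, p11 if w_ij = 1 else p10)              replicates amplify
```

* `theta11` / `theta10` — Stage-1 (sample collection) true/false positive
  probabilities; `1 - theta11` is the field false-negative rate.
* `p11` / `p10` — Stage-2 (qPCR replicate) true/false positive
  probabilities.
* Error probabilities get Beta priors parameterized by mean (defaults 0.9
  for true positives, 0.1 for false positives) and concentration (default
  10, i.e. Beta(9,1) / Beta(1,9)).
* Regression coefficients get independent normal priors (intercept:
  logit(0.5) with variance 4; covariate columns: mean 0, slab variance
  0.25), and each covariate *group* (a categorical factor's dummy block
  moves as a unit) carries a Bernoulli inclusion indicator with prior
  probability `expected_num_covariates / n_groups` (default 2 / G).

Inference is a Gibbs sampler with a collapsed latent-occupancy update,
conjugate Beta updates for the error probabilities (optionally constrained
to `theta11 > theta10`, `p11 > p10`), Pólya-Gamma auxiliaries for the
logistic occupancy regression (a Devroye rejection sampler implemented
in-package), and Add–Delete–Swap Metropolis–Hastings moves on the inclusion
indicators using the conditionally Gaussian marginal likelihood with the
coefficients integrated out.

From the posterior draws the package computes posterior inclusion
probabilities (PIPs), coefficient credible intervals, all pairwise
categorical-level contrasts, the posterior conditional probability of
species absence given *x* of *K* replicates amplifying, naive threshold
occupancy, replicate-level false-positive magnification, and a
posterior-predictive goodness-of-fit simulation.

## Worked example

The `analysis/` scripts run a complete synthetic national survey end to end
(`python analysis/01_simulate.py` through `05_goodness_of_fit.py`,
artifacts under `results/analysis/`).  The survey has 2,000 ponds, one
sample each, twelve qPCR replicates, occupancy driven by three real effects
(x1 +, x3 −, x4 +), two null covariates, one covariate collinear with x1
(r = 0.85, pruned before fitting), and a 17-level unbalanced land-cover
factor.  The fit (5,000 burn-in + 3,000 iterations, 100 thinned draws,
about 16 s) prints:

```
posterior means:
  mean occupancy  0.207
  theta11 0.904   theta10 0.018
  p11     0.801   p10     0.019
```

against generating values 0.201 (realized mean occupancy), 0.948, 0.015,
0.808, 0.020 — the Stage-2 rates are tightly identified by 24,000
replicates, while occupancy and the Stage-1 rates are only jointly
identified with one sample per site, so their split leans on the priors.
The summaries then report:

```
4 of 6 covariate groups have PIP > 0.5:
  x1           PIP 1.00 *
  x3           PIP 1.00 *
  x4           PIP 1.00 *
  x5           PIP 0.02
  x6           PIP 0.26
  landcover    PIP 1.00 *
naive occupancy at threshold 1: 0.36 (725 sites)
naive occupancy at threshold 2: 0.22 (439 sites)
naive occupancy at threshold 3: 0.20 (397 sites)
model-based mean occupancy: 0.207
P(absent | x amplifying replicates): 0.97 0.97 0.97 0.96 0.36 0.07 ... (x = 0..5)
```

Every true effect and no null is flagged; the naive single-replicate
threshold (0.36) overstates occupancy relative to the model (0.207) because
with `p10 = 0.02` a DNA-free sample still has a `1 - 0.98^12 = 0.215`
chance of at least one false amplification, and samples amplifying in only
1–2 of 12 replicates are essentially all false positives — which is why the
absence probability stays near 1 up to 3 amplifying replicates and collapses
by 5.

A reusable pipeline wraps the same stages behind one YAML config:
`edna-occ run --config config.yaml` (subcommands `simulate`, `prep`, `fit`,
`summarize`, `gof`).

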