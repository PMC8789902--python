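"""Independent reference computations used by the test suite.

Everything here deliberately avoids the package's own samplers: a 5-D
Gauss-Legendre quadrature posterior for tiny intercept-only datasets, a
truncated-convolution Pólya-Gamma sampler, a random-walk Metropolis sampler
for Bayesian logistic regression, and exhaustive enumeration of
spike-and-slab inclusion posteriors given fixed Pólya-Gamma auxiliaries.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit
from scipy.stats import beta as beta_dist
from scipy.stats import binom, norm


def _gl_nodes(n: int):
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


def grid_posterior_means(y_counts, K, psi_prior_var=4.0, a_hi=9.0, b_hi=1.0,
                         a_lo=1.0, b_lo=9.0, n_nodes=32, ordered=True):
    """Posterior means of (psi, theta11, theta10, p11, p10) by 5-D quadrature.

    For an intercept-only two-stage occupancy model with M=1 the likelihood
    depends on the data only through the counts of y values:

        L = prod_y [ q * b(y; K, p11) + (1 - q) * b(y; K, p10) ]^{n_y},
        q = psi * theta11 + (1 - psi) * theta10.

    Priors: logit(psi) ~ N(0, psi_prior_var); theta11, p11 ~ Beta(a_hi, b_hi);
    theta10, p10 ~ Beta(a_lo, b_lo); optionally truncated to theta11 > theta10
    and p11 > p10.  Gauss-Legendre nodes on (0,1) in every dimension.
    """
    y_counts = np.asarray(y_counts)
    n = n_nodes
    nodes, weights = _gl_nodes(n)
    psi = t11 = t10 = p11g = p10g = nodes
    w_psi = np.exp(norm.logpdf(logit(psi), 0.0, np.sqrt(psi_prior_var))
                   - np.log(psi * (1 - psi))) * weights
    w_t11 = beta_dist.pdf(t11, a_hi, b_hi) * weights
    w_t10 = beta_dist.pdf(t10, a_lo, b_lo) * weights
    w_p11 = beta_dist.pdf(p11g, a_hi, b_hi) * weights
    w_p10 = beta_dist.pdf(p10g, a_lo, b_lo) * weights

    q = psi[:, None, None] * t11[None, :, None] \
        + (1 - psi[:, None, None]) * t10[None, None, :]
    w3 = w_psi[:, None, None] * w_t11[None, :, None] * w_t10[None, None, :]
    if ordered:
        w3 = w3 * (t11[:, None] > t10[None, :])[None, :, :]
    B11 = binom.pmf(np.arange(K + 1)[:, None], K, p11g[None, :])
    B10 = binom.pmf(np.arange(K + 1)[:, None], K, p10g[None, :])

    total = 0.0
    sums = np.zeros(5)
    gmax = None
    for a in range(n):
        for b in range(n):
            if ordered and p11g[a] <= p10g[b]:
                continue
            ll = np.zeros_like(q)
            for yy in range(K + 1):
                if y_counts[yy]:
                    ll += y_counts[yy] * np.log(q * B11[yy, a] + (1 - q) * B10[yy, b])
            m = ll.max()
            wgt = np.exp(ll - m) * w3
            s = wgt.sum() * w_p11[a] * w_p10[b]
            vec = np.array([
                (wgt * psi[:, None, None]).sum(),
                (wgt * t11[None, :, None]).sum(),
                (wgt * t10[None, None, :]).sum(),
                wgt.sum() * p11g[a],
                wgt.sum() * p10g[b],
            ]) * w_p11[a] * w_p10[b]
            if gmax is None:
                gmax, total, sums = m, s, vec
            elif m > gmax:
                f = np.exp(gmax - m)
                total = total * f + s
                sums = sums * f + vec
                gmax = m
            else:
                f = np.exp(m - gmax)
                total += s * f
                sums += vec * f
    means = sums / total
    return dict(zip(["psi", "theta11", "theta10", "p11", "p10"], means))


def pg_convolution_draws(z: float, size: int, rng, n_terms: int = 1000):
    """PG(1, z) by its infinite-convolution representation, truncated.

    PG(1, z) = (1 / 2 pi^2) * sum_k g_k / ((k - 1/2)^2 + z^2 / (4 pi^2)),
    g_k ~ Exp(1).  Truncated at `n_terms` with the tail replaced by its
    expectation (bias ~1/(2 pi^2 n_terms), negligible for KS comparisons).
    """
    k = np.arange(1, n_terms + 1)
    denom = (k - 0.5) ** 2 + z**2 / (4.0 * np.pi**2)
    g = rng.exponential(1.0, size=(size, n_terms))
    draws = (g / denom).sum(axis=1) / (2.0 * np.pi**2)
    # tail expectation: sum_{k>N} 1/denom ~ integral
    tail = 1.0 / (2.0 * np.pi**2) * (1.0 / (n_terms - 0.5))
    return draws + tail


def rw_metropolis_logistic(X, z, prior_mean, prior_var, n_iter, rng,
                           step: float = 0.15):
    """Random-walk Metropolis for Bayesian logistic regression P(z=1)=expit(Xb).

    Independent normal priors per coefficient.  Returns the post-burn-in
    chain (second half).
    """
    X = np.asarray(X, dtype=float)
    z = np.asarray(z, dtype=float)
    prior_mean = np.asarray(prior_mean, dtype=float)
    prior_var = np.asarray(prior_var, dtype=float)
    P = X.shape[1]

    def logpost(beta):
        eta = X @ beta
        ll = np.sum(z * eta - np.logaddexp(0.0, eta))
        lp = -0.5 * np.sum((beta - prior_mean) ** 2 / prior_var)
        return ll + lp

    beta = prior_mean.copy()
    lp = logpost(beta)
    chain = np.empty((n_iter, P))
    for i in range(n_iter):
        prop = beta + step * rng.standard_normal(P)
        lp_prop = logpost(prop)
        if np.log(rng.random()) < lp_prop - lp:
            beta, lp = prop, lp_prop
        chain[i] = beta
    return chain[n_iter // 2:]


def enumerate_inclusion_posterior(z, design, omega, config, log_marginal_fn):
    """Exact posterior over all 2^G inclusion states given fixed omega.

    Uses the package's marginal-likelihood function (the quantity under
    test is the ADS chain's stationary law, not the marginal itself) together
    with the independent Bernoulli(h) inclusion prior.
    """
    G = len(design.covariate_groups)
    h = config.expected_num_covariates / G
    log_w = []
    states = []
    for mask in range(2**G):
        gamma = np.array([(mask >> g) & 1 for g in range(G)], dtype=bool)
        lm = log_marginal_fn(z, design, gamma, omega, config)
        lp = np.sum(np.where(gamma, np.log(h), np.log1p(-h)))
        log_w.append(lm + lp)
        states.append(tuple(gamma))
    log_w = np.array(log_w)
    w = np.exp(log_w - log_w.max())
    return dict(zip(states, w / w.sum()))
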