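"""Two-stage occupancy model with false positives: Gibbs/Metropolis sampler.

Model
-----
For site i with occupancy probability psi_i = logistic(x_i' beta):

    z_i  ~ Bernoulli(psi_i)
    w_ij | z_i  ~ Bernoulli(theta11 if z_i = 1 else theta10)
    y_ij | w_ij ~ Binomial(K_ij, p11 if w_ij = 1 else p10)

theta11/theta10 are the Stage-1 (sample collection) true/false positive
probabilities, p11/p10 the Stage-2 (qPCR replicate) ones.  Error
probabilities get Beta priors parameterized by mean m and concentration c,
Beta(m*c, (1-m)*c).  Regression coefficients get independent normals
(intercept: mean logit(prior_occupancy_mean), variance
prior_occupancy_variance; covariate columns: mean 0, slab variance
coefficient_variance), and covariate groups carry independent Bernoulli
inclusion indicators gamma_g with prior probability
expected_num_covariates / n_groups.

Sampler
-------
One sweep updates, in this fixed order (one seeded numpy Generator plus one
seeded Pólya-Gamma stream drive all randomness):

1. z | rest, with w marginalized out (collapsed update, log-space),
2. w | z,
3. (theta11, theta10, p11, p10) by Beta conjugacy, jointly rejected until
   theta11 > theta10 and p11 > p10 when `enforce_ordering` is on,
4. omega_i ~ PG(1, x_i' beta) auxiliaries,
5. one Add–Delete–Swap Metropolis–Hastings move on gamma, using the
   marginal likelihood of the Pólya-Gamma-augmented Gaussian representation
   with beta integrated out analytically,
6. beta for the active columns from its conditional Gaussian given omega.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.special import expit, gammaln, logit

from .data_prep import DesignMatrix, validate_detection_table
from .polya_gamma import PolyaGammaSampler

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Priors and MCMC schedule; defaults mirror the survey app's settings."""

    prior_occupancy_mean: float = 0.5
    prior_occupancy_variance: float = 4.0
    coefficient_variance: float = 0.25
    expected_num_covariates: float = 2.0
    prior_mean_theta11: float = 0.9
    prior_mean_theta10: float = 0.1
    prior_mean_p11: float = 0.9
    prior_mean_p10: float = 0.1
    beta_prior_concentration: float = 10.0
    n_burn: int = 5000
    n_iter: int = 3000
    n_chains: int = 1
    n_thinned_draws: int = 100
    seed: int = 0
    enforce_ordering: bool = True
    max_ordering_retries: int = 1000

    def validate(self, n_groups: int | None = None) -> None:
        for name in ("prior_occupancy_mean", "prior_mean_theta11", "prior_mean_theta10",
                     "prior_mean_p11", "prior_mean_p10"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("prior_occupancy_variance", "coefficient_variance",
                     "beta_prior_concentration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_thinned_draws > self.n_iter:
            raise ValueError("n_thinned_draws cannot exceed n_iter")
        if n_groups is not None and n_groups > 0 and \
                self.expected_num_covariates > n_groups:
            raise ValueError("expected_num_covariates exceeds the number of "
                             "candidate covariate groups")

    def beta_prior(self, mean: float) -> tuple[float, float]:
        c = self.beta_prior_concentration
        return mean * c, (1.0 - mean) * c


@dataclass
class PosteriorDraws:
    """Thinned posterior draws; beta rows carry exact zeros outside active groups."""

    beta: np.ndarray           # (D, P) full-length coefficient draws
    gamma: np.ndarray          # (D, G) group inclusion indicators (bool)
    theta11: np.ndarray
    theta10: np.ndarray
    p11: np.ndarray
    p10: np.ndarray
    mean_psi: np.ndarray       # (D,) site-averaged occupancy per draw
    columns: list[str]
    group_names: list[str]     # candidate covariate groups (intercept excluded)
    groups: dict[str, list[int]]
    config: ModelConfig
    ads_acceptance_rate: float = float("nan")
    psi: np.ndarray | None = None   # optional (D, S) site-level occupancy
    z: np.ndarray | None = None     # optional (D, S) latent occupancy states

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for j, name in enumerate(self.columns):
            cols[f"beta_{name}"] = self.beta[:, j]
        for g, name in enumerate(self.group_names):
            cols[f"gamma_{name}"] = self.gamma[:, g].astype(int)
        cols["theta11"] = self.theta11
        cols["theta10"] = self.theta10
        cols["p11"] = self.p11
        cols["p10"] = self.p10
        cols["mean_psi"] = self.mean_psi
        return pd.DataFrame(cols)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# detection bookkeeping


@dataclass
class _Detections:
    y: np.ndarray          # (n,) amplifying replicate counts
    K: np.ndarray          # (n,) replicates per sample
    site_idx: np.ndarray   # (n,) 0..S-1
    S: int
    site_ids: list
    lchoose: np.ndarray    # (n,) log C(K, y), cached

    @classmethod
    def from_table(cls, detection: pd.DataFrame) -> "_Detections":
        df = validate_detection_table(detection)
        sites, site_idx = np.unique(df["site_id"].to_numpy(), return_inverse=True)
        y = df["y_positive"].to_numpy(dtype=np.int64)
        K = df["k_replicates"].to_numpy(dtype=np.int64)
        lchoose = gammaln(K + 1) - gammaln(y + 1) - gammaln(K - y + 1)
        return cls(y=y, K=K, site_idx=site_idx, S=len(sites),
                   site_ids=list(sites), lchoose=lchoose)

    def log_binom(self, p: float) -> np.ndarray:
        """log Binomial(y | K, p) per sample row, safe at p in {0, 1}."""
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(self.y > 0, self.y * np.log(p), 0.0)
            b = np.where(self.K - self.y > 0, (self.K - self.y) * np.log1p(-p), 0.0)
        return self.lchoose + a + b


# ---------------------------------------------------------------------------
# full conditionals


def sample_latent_z(det: _Detections, psi, theta11, theta10, p11, p10, rng,
                    return_prob: bool = False):
    """Draw z from its full conditional with w marginalized out (log space)."""
    lb11 = det.log_binom(p11)
    lb10 = det.log_binom(p10)
    per1 = np.logaddexp(np.log(theta11) + lb11, np.log1p(-theta11) + lb10) \
        if 0 < theta11 < 1 else np.where(theta11 >= 1, lb11, lb10)
    per0 = np.logaddexp(np.log(theta10) + lb11, np.log1p(-theta10) + lb10) \
        if 0 < theta10 < 1 else np.where(theta10 >= 1, lb11, lb10)
    s1 = np.bincount(det.site_idx, weights=per1, minlength=det.S)
    s0 = np.bincount(det.site_idx, weights=per0, minlength=det.S)
    psi = np.asarray(psi, dtype=float)
    with np.errstate(divide="ignore"):
        d = (np.log(psi) + s1) - (np.log1p(-psi) + s0)
    prob = expit(d)
    prob = np.where(psi >= 1.0, 1.0, np.where(psi <= 0.0, 0.0, prob))
    z = rng.random(det.S) < prob
    return (z, prob) if return_prob else z


def sample_latent_w(det: _Detections, z, theta11, theta10, p11, p10, rng,
                    return_prob: bool = False):
    """Draw w per sample given z: P(w=1) = theta*b11 / (theta*b11 + (1-theta)*b10)."""
    theta = np.where(np.asarray(z, dtype=bool)[det.site_idx], theta11, theta10)
    lb11 = det.log_binom(p11)
    lb10 = det.log_binom(p10)
    with np.errstate(divide="ignore"):
        d = logit(theta) + lb11 - lb10
    prob = expit(d)
    prob = np.where(theta >= 1.0, 1.0, np.where(theta <= 0.0, 0.0, prob))
    w = rng.random(det.y.shape[0]) < prob
    return (w, prob) if return_prob else w


def update_error_probs(det: _Detections, z, w, config: ModelConfig, rng):
    """Conjugate Beta draws of (theta11, theta10, p11, p10).

    With `enforce_ordering`, each pair is redrawn jointly until ordered
    (truncated-prior model); after `max_ordering_retries` failures the pair
    is sorted with a logged warning.
    """
    z_row = np.asarray(z, dtype=bool)[det.site_idx]
    w = np.asarray(w, dtype=bool)
    a_t11, b_t11 = config.beta_prior(config.prior_mean_theta11)
    a_t10, b_t10 = config.beta_prior(config.prior_mean_theta10)
    a_p11, b_p11 = config.beta_prior(config.prior_mean_p11)
    a_p10, b_p10 = config.beta_prior(config.prior_mean_p10)

    n1 = z_row.sum()
    s1 = (w & z_row).sum()
    n0 = (~z_row).sum()
    s0 = (w & ~z_row).sum()
    y1 = det.y[w].sum()
    f1 = (det.K[w] - det.y[w]).sum()
    y0 = det.y[~w].sum()
    f0 = (det.K[~w] - det.y[~w]).sum()

    def draw_pair(a_hi, b_hi, s_hi, f_hi, a_lo, b_lo, s_lo, f_lo, label):
        hi = rng.beta(a_hi + s_hi, b_hi + f_hi)
        lo = rng.beta(a_lo + s_lo, b_lo + f_lo)
        if not config.enforce_ordering:
            return hi, lo
        for _ in range(config.max_ordering_retries):
            if hi > lo:
                return hi, lo
            hi = rng.beta(a_hi + s_hi, b_hi + f_hi)
            lo = rng.beta(a_lo + s_lo, b_lo + f_lo)
        if hi <= lo:
            logger.warning("ordering rejection cap hit for %s; sorting the pair", label)
            hi, lo = max(hi, lo), min(hi, lo)
        return hi, lo

    theta11, theta10 = draw_pair(a_t11, b_t11, s1, n1 - s1,
                                 a_t10, b_t10, s0, n0 - s0, "theta")
    p11, p10 = draw_pair(a_p11, b_p11, y1, f1, a_p10, b_p10, y0, f0, "p")
    return theta11, theta10, p11, p10


def _prior_moments(design: DesignMatrix, config: ModelConfig):
    P = design.X.shape[1]
    m0 = np.zeros(P)
    m0[0] = logit(config.prior_occupancy_mean)
    v0 = np.full(P, config.coefficient_variance)
    v0[0] = config.prior_occupancy_variance
    return m0, v0


def update_beta_polya_gamma(z, design: DesignMatrix, gamma, config: ModelConfig,
                            rng, pg: PolyaGammaSampler, beta_current=None):
    """Draw omega ~ PG(1, X beta) then beta_active from its conditional Gaussian.

    Returns (beta_full, omega); inactive entries of beta_full are exactly zero.
    """
    active = active_columns(design, gamma)
    X = design.X
    if beta_current is None:
        beta_current = np.zeros(X.shape[1])
    eta = X @ beta_current
    omega = pg.draw(eta)
    beta = np.zeros(X.shape[1])
    beta[active] = _draw_beta_given_omega(z, X[:, active], omega,
                                          *_prior_slice(design, config, active), rng)
    return beta, omega


def _prior_slice(design, config, active):
    m0, v0 = _prior_moments(design, config)
    return m0[active], v0[active]


def _draw_beta_given_omega(z, X_a, omega, m0_a, v0_a, rng):
    kappa = np.asarray(z, dtype=float) - 0.5
    Q = X_a.T @ (X_a * omega[:, None]) + np.diag(1.0 / v0_a)
    b = X_a.T @ kappa + m0_a / v0_a
    try:
        c, low = cho_factor(Q)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular precision in the coefficient update; the active design "
            "columns are linearly dependent — deduplicate covariate columns"
        ) from exc
    mu = cho_solve((c, low), b)
    # upper Cholesky U with U'U = Q: solve U x = eps for a N(mu, Q^{-1}) draw
    U = cholesky(Q, lower=False)
    eps = rng.standard_normal(X_a.shape[1])
    return mu + solve_triangular(U, eps, lower=False)


def active_columns(design: DesignMatrix, gamma) -> np.ndarray:
    """Column indices of the intercept plus all active covariate groups."""
    cols = [0]
    for g, name in enumerate(design.covariate_groups):
        if gamma[g]:
            cols.extend(design.groups[name])
    return np.array(sorted(cols), dtype=int)


def log_marginal_given_omega(z, design: DesignMatrix, gamma, omega,
                             config: ModelConfig) -> float:
    """log marginal of the PG-augmented Gaussian model with beta integrated out.

    Up to an additive constant shared by all inclusion states (terms that
    depend only on omega, kappa and the always-included intercept prior).
    """
    active = active_columns(design, gamma)
    X_a = design.X[:, active]
    m0_a, v0_a = _prior_slice(design, config, active)
    kappa = np.asarray(z, dtype=float) - 0.5
    Q = X_a.T @ (X_a * omega[:, None]) + np.diag(1.0 / v0_a)
    b = X_a.T @ kappa + m0_a / v0_a
    L = cholesky(Q, lower=True)
    u = solve_triangular(L, b, lower=True)
    return float(-0.5 * np.sum(np.log(v0_a)) - np.sum(np.log(np.diag(L)))
                 + 0.5 * u @ u)


def update_gamma_ads(z, design: DesignMatrix, gamma, omega, config: ModelConfig,
                     rng) -> tuple[np.ndarray, bool]:
    """One Add–Delete–Swap Metropolis–Hastings move on the inclusion vector.

    Move type uniform over those legal in the current state; the Hastings
    ratio accounts for the (possibly different) number of legal types and
    eligible groups in the reverse direction.  Whole groups move together.
    """
    gamma = np.asarray(gamma, dtype=bool).copy()
    G = gamma.shape[0]
    if G == 0:
        return gamma, False
    h = min(max(config.expected_num_covariates / G, 1e-12), 1 - 1e-12)
    log_h, log_1mh = np.log(h), np.log1p(-h)

    def n_types(g):
        a = int(g.sum())
        b = G - a
        return (b > 0) + (a > 0) + (a > 0 and b > 0)

    act = np.flatnonzero(gamma)
    inact = np.flatnonzero(~gamma)
    a, b = act.size, inact.size
    types = []
    if b > 0:
        types.append("add")
    if a > 0:
        types.append("delete")
    if a > 0 and b > 0:
        types.append("swap")
    move = types[rng.integers(len(types))]

    prop = gamma.copy()
    if move == "add":
        j = inact[rng.integers(b)]
        prop[j] = True
        log_q_fwd = -np.log(len(types)) - np.log(b)
        log_q_rev = -np.log(n_types(prop)) - np.log(a + 1)
        d_prior = log_h - log_1mh
    elif move == "delete":
        j = act[rng.integers(a)]
        prop[j] = False
        log_q_fwd = -np.log(len(types)) - np.log(a)
        log_q_rev = -np.log(n_types(prop)) - np.log(b + 1)
        d_prior = log_1mh - log_h
    else:
        j = act[rng.integers(a)]
        l = inact[rng.integers(b)]
        prop[j] = False
        prop[l] = True
        log_q_fwd = -np.log(len(types)) - np.log(a) - np.log(b)
        log_q_rev = -np.log(n_types(prop)) - np.log(a) - np.log(b)
        d_prior = 0.0

    lm_cur = log_marginal_given_omega(z, design, gamma, omega, config)
    lm_prop = log_marginal_given_omega(z, design, prop, omega, config)
    log_alpha = (lm_prop - lm_cur) + d_prior + (log_q_rev - log_q_fwd)
    if np.log(rng.random()) < log_alpha:
        return prop, True
    return gamma, False


# ---------------------------------------------------------------------------
# the Gibbs cycle


def _intercept_only_design(det: _Detections) -> DesignMatrix:
    return DesignMatrix(X=np.ones((det.S, 1)), columns=["intercept"],
                        groups={"intercept": [0]}, terms=[], standardization={},
                        baseline={}, levels={}, site_ids=det.site_ids)


def fit(detection: pd.DataFrame, design: DesignMatrix | None = None,
        config: ModelConfig | None = None, store_psi: bool = False,
        store_z: bool = False, progress_every: int = 0) -> PosteriorDraws:
    """Run the Gibbs cycle and return evenly thinned post-burn-in draws.

    `detection` is a validated detection table; `design` a grouped design
    matrix over the same sites (None for an intercept-only model).  The run
    is reproducible: all draws come from one numpy Generator and one
    Pólya-Gamma stream, both seeded from ``config.seed``.
    """
    config = config or ModelConfig()
    det = _Detections.from_table(detection)
    if design is None:
        design = _intercept_only_design(det)
    else:
        if design.n_sites != det.S:
            raise ValueError(f"design has {design.n_sites} rows but the detection "
                             f"table covers {det.S} sites")
        # detection sites are held in sorted order; permute the design rows to
        # match, otherwise covariates would be regressed against the wrong sites
        if list(design.site_ids) != det.site_ids:
            pos = {sid: i for i, sid in enumerate(design.site_ids)}
            missing = [s for s in det.site_ids if s not in pos]
            if missing:
                raise ValueError(f"design is missing sites {missing[:5]}")
            perm = np.array([pos[s] for s in det.site_ids])
            design = replace(design, X=design.X[perm],
                             site_ids=list(det.site_ids))
    G = len(design.covariate_groups)
    config.validate(n_groups=G)

    ss = np.random.SeedSequence(config.seed)
    np_seed, pg_seed = ss.spawn(2)
    rng = np.random.default_rng(np_seed)
    pg = PolyaGammaSampler(pg_seed.generate_state(1, dtype=np.uint32)[0] % 2**31)

    m0, v0 = _prior_moments(design, config)
    beta = m0.copy()
    gamma = np.zeros(G, dtype=bool)
    theta11, theta10 = config.prior_mean_theta11, config.prior_mean_theta10
    p11, p10 = config.prior_mean_p11, config.prior_mean_p10

    n_total = config.n_burn + config.n_iter
    keep = set((config.n_burn
                + np.unique(np.round(np.linspace(0, config.n_iter - 1,
                                                 config.n_thinned_draws)).astype(int))
                ).tolist())

    D = config.n_thinned_draws
    out_beta = np.empty((D, design.X.shape[1]))
    out_gamma = np.empty((D, G), dtype=bool)
    out_t11 = np.empty(D)
    out_t10 = np.empty(D)
    out_p11 = np.empty(D)
    out_p10 = np.empty(D)
    out_mpsi = np.empty(D)
    out_psi = np.empty((D, det.S)) if store_psi else None
    out_z = np.empty((D, det.S), dtype=np.int8) if store_z else None

    ads_props = 0
    ads_accepts = 0
    d = 0
    for sweep in range(n_total):
        eta = design.X @ beta
        psi = expit(eta)
        z = sample_latent_z(det, psi, theta11, theta10, p11, p10, rng)
        w = sample_latent_w(det, z, theta11, theta10, p11, p10, rng)
        theta11, theta10, p11, p10 = update_error_probs(det, z, w, config, rng)
        omega = pg.draw(eta)
        if G > 0:
            gamma, accepted = update_gamma_ads(z, design, gamma, omega, config, rng)
            ads_props += 1
            ads_accepts += accepted
        active = active_columns(design, gamma)
        beta = np.zeros(design.X.shape[1])
        beta[active] = _draw_beta_given_omega(z, design.X[:, active], omega,
                                              m0[active], v0[active], rng)
        if progress_every and (sweep + 1) % progress_every == 0:
            logger.info("sweep %d/%d (ADS acceptance %.3f)", sweep + 1, n_total,
                        ads_accepts / max(ads_props, 1))
        if sweep in keep:
            psi_draw = expit(design.X @ beta)
            out_beta[d] = beta
            out_gamma[d] = gamma
            out_t11[d] = theta11
            out_t10[d] = theta10
            out_p11[d] = p11
            out_p10[d] = p10
            out_mpsi[d] = psi_draw.mean()
            if store_psi:
                out_psi[d] = psi_draw
            if store_z:
                out_z[d] = z
            d += 1

    return PosteriorDraws(
        beta=out_beta[:d], gamma=out_gamma[:d], theta11=out_t11[:d],
        theta10=out_t10[:d], p11=out_p11[:d], p10=out_p10[:d],
        mean_psi=out_mpsi[:d], columns=design.columns,
        group_names=design.covariate_groups, groups=design.groups,
        config=config,
        ads_acceptance_rate=(ads_accepts / ads_props if ads_props else float("nan")),
        psi=out_psi[:d] if store_psi else None,
        z=out_z[:d] if store_z else None,
    )


def point_draws(psi: float, theta11: float, theta10: float, p11: float,
                p10: float, n_draws: int = 100) -> PosteriorDraws:
    """Degenerate draw set with every draw at the given parameter values.

    Useful for running posterior-predictive machinery at published point
    estimates rather than a full posterior.
    """
    beta0 = float(logit(psi)) if 0 < psi < 1 else (np.inf if psi >= 1 else -np.inf)
    return PosteriorDraws(
        beta=np.full((n_draws, 1), beta0),
        gamma=np.zeros((n_draws, 0), dtype=bool),
        theta11=np.full(n_draws, theta11), theta10=np.full(n_draws, theta10),
        p11=np.full(n_draws, p11), p10=np.full(n_draws, p10),
        mean_psi=np.full(n_draws, psi), columns=["intercept"], group_names=[],
        groups={"intercept": [0]}, config=ModelConfig(n_thinned_draws=n_draws),
    )
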