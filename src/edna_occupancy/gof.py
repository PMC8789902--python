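"""Posterior-predictive goodness of fit.

Each posterior-predictive repeat r takes retained draw r's parameters,
computes site occupancy probabilities from that draw's coefficients (or its
constant occupancy when the fit had no covariates), simulates the full
two-stage process for S sites x M samples x K replicates, and tabulates

* the count of samples with exactly k amplifying replicates (k = 0..K),
* the amplifying-replicate histogram among DNA-free samples (every
  amplification there is a Stage-2 false positive),
* the histogram among DNA-containing samples (non-amplifying replicates
  there are Stage-2 false negatives),
* Stage-1 sample tallies: true/false positives and negatives.

Box summaries use the median, quartiles and whiskers at quartile +/- 1.5 IQR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .mcmc import PosteriorDraws


@dataclass
class GofSummary:
    K: int
    S: int
    M: int
    counts: np.ndarray        # (n_repeats, K+1) samples with k amplifications
    fp_counts: np.ndarray     # (n_repeats, K+1) histogram among w=0 samples
    tp_counts: np.ndarray     # (n_repeats, K+1) histogram among w=1 samples
    stage1: pd.DataFrame      # per repeat: tp, fp, tn, fn sample tallies
    observed: np.ndarray | None = None   # (K+1,) observed counts, if supplied

    @property
    def n_repeats(self) -> int:
        return self.counts.shape[0]

    def box_summary(self, which: str = "counts") -> pd.DataFrame:
        """Median, quartiles and 1.5-IQR whiskers per replicate count k."""
        arr = getattr(self, which)
        q1, med, q3 = np.percentile(arr, [25, 50, 75], axis=0)
        iqr = q3 - q1
        out = pd.DataFrame({
            "k": np.arange(self.K + 1), "median": med, "q1": q1, "q3": q3,
            "whisker_lo": q1 - 1.5 * iqr, "whisker_hi": q3 + 1.5 * iqr,
            "min": arr.min(axis=0), "max": arr.max(axis=0),
        })
        if which == "counts" and self.observed is not None:
            out["observed"] = self.observed
        return out

    def long_frame(self, which: str = "counts") -> pd.DataFrame:
        arr = getattr(self, which)
        n, kk = arr.shape
        return pd.DataFrame({
            "repeat": np.repeat(np.arange(n), kk),
            "k": np.tile(np.arange(kk), n),
            "count": arr.reshape(-1),
        })

    def write_csv(self, path_long, path_summary=None, path_stage1=None) -> None:
        self.long_frame("counts").to_csv(path_long, index=False)
        if path_summary is not None:
            self.box_summary("counts").to_csv(path_summary, index=False)
        if path_stage1 is not None:
            self.stage1.to_csv(path_stage1, index=False)


def _psi_matrix(draws: PosteriorDraws, S: int, X: np.ndarray | None) -> np.ndarray:
    """(n_draws, S) occupancy probabilities implied by each retained draw."""
    if draws.psi is not None and draws.psi.shape[1] == S:
        return draws.psi
    has_cov = len(draws.group_names) > 0 and draws.gamma.any()
    if X is not None:
        if X.shape[0] != S:
            raise ValueError("design row count does not match S")
        return expit(draws.beta @ X.T)
    if has_cov:
        raise ValueError("draws contain covariate effects; pass the design matrix")
    return expit(np.repeat(draws.beta[:, :1], S, axis=1))


def gof_simulate(draws: PosteriorDraws, S: int, M: int, K: int,
                 n_repeats: int | None = None, X: np.ndarray | None = None,
                 observed: pd.DataFrame | None = None, seed: int = 0) -> GofSummary:
    """Posterior-predictive simulation, one retained draw per repeat."""
    n_repeats = draws.n_draws if n_repeats is None else n_repeats
    if n_repeats > draws.n_draws:
        raise ValueError("n_repeats cannot exceed the number of retained draws")
    psi_mat = _psi_matrix(draws, S, X)
    rng = np.random.default_rng(seed)
    counts = np.zeros((n_repeats, K + 1), dtype=np.int64)
    fp_counts = np.zeros_like(counts)
    tp_counts = np.zeros_like(counts)
    s1 = []
    for r in range(n_repeats):
        z = rng.random(S) < psi_mat[r]
        theta = np.where(z, draws.theta11[r], draws.theta10[r])
        w = rng.random((S, M)) < theta[:, None]
        p = np.where(w, draws.p11[r], draws.p10[r])
        y = rng.binomial(K, p)
        counts[r] = np.bincount(y.reshape(-1), minlength=K + 1)
        fp_counts[r] = np.bincount(y[~w], minlength=K + 1)
        tp_counts[r] = np.bincount(y[w], minlength=K + 1)
        zz = np.repeat(z[:, None], M, axis=1)
        s1.append({"repeat": r,
                   "stage1_tp": int((zz & w).sum()), "stage1_fp": int((~zz & w).sum()),
                   "stage1_fn": int((zz & ~w).sum()), "stage1_tn": int((~zz & ~w).sum())})
    obs = None
    if observed is not None:
        if (observed["k_replicates"] != K).any():
            raise ValueError("observed table uses a different K")
        obs = np.bincount(observed["y_positive"].to_numpy(), minlength=K + 1)
    return GofSummary(K=K, S=S, M=M, counts=counts, fp_counts=fp_counts,
                      tp_counts=tp_counts, stage1=pd.DataFrame(s1), observed=obs)


def gof_compare(summary: GofSummary, observed: pd.DataFrame) -> pd.DataFrame:
    """Flag, per k, whether the observed count falls inside the whisker range."""
    if (observed["k_replicates"] != summary.K).any():
        raise ValueError("observed table uses a different K")
    obs = np.bincount(observed["y_positive"].to_numpy(), minlength=summary.K + 1)
    box = summary.box_summary("counts")
    verdict = []
    for k in range(summary.K + 1):
        lo, hi = box.loc[k, "whisker_lo"], box.loc[k, "whisker_hi"]
        if obs[k] < lo:
            verdict.append("observed < simulated envelope")
        elif obs[k] > hi:
            verdict.append("observed > simulated envelope")
        else:
            verdict.append("inside")
    box = box.copy()
    box["observed"] = obs
    box["verdict"] = verdict
    box["inside"] = box["verdict"] == "inside"
    return box


def plot_gof(summary: GofSummary, path) -> None:
    """Boxplot of simulated per-k counts with observed counts overlaid as dots."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.boxplot([summary.counts[:, k] for k in range(summary.K + 1)],
               positions=np.arange(summary.K + 1), whis=1.5, showfliers=True)
    if summary.observed is not None:
        ax.plot(np.arange(summary.K + 1), summary.observed, "ro", label="observed")
        ax.legend()
    ax.set_xlabel("amplifying qPCR replicates (k)")
    ax.set_ylabel("number of samples")
    ax.set_title("Posterior-predictive replicate-count distribution")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
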