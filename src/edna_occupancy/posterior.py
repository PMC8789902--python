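"""Summaries computed from posterior draws.

Posterior inclusion probabilities and coefficient intervals, pairwise
contrasts between categorical levels, the posterior conditional probability
of species absence given x amplifying replicates, naive threshold-based
occupancy, and the arithmetic of false-positive magnification across qPCR
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .mcmc import PosteriorDraws

PCI = (2.5, 97.5)  # equal-tailed 95% posterior credible interval


def _pci(x: np.ndarray) -> tuple[float, float]:
    lo, hi = np.percentile(x, PCI)
    return float(lo), float(hi)


def compute_pip(draws: PosteriorDraws) -> dict:
    """Posterior inclusion probabilities per group and coefficient summaries.

    Returns ``{"groups": DataFrame, "coefficients": DataFrame}``: per group
    the PIP (fraction of retained draws with gamma=1) and the importance flag
    PIP > 0.5; per design column the posterior mean and 95% PCI both
    marginally (excluded draws contribute exact zeros) and conditional on
    inclusion (all-zero draws reported when the group is never selected).
    """
    if draws.n_draws < 1:
        raise ValueError("need at least one retained draw")
    g_rows = []
    for g, name in enumerate(draws.group_names):
        pip = float(draws.gamma[:, g].mean())
        g_rows.append({"group": name, "pip": pip, "important": pip > 0.5})
    c_rows = []
    group_of_col = {}
    for name, cols in draws.groups.items():
        for c in cols:
            group_of_col[c] = name
    for j, col in enumerate(draws.columns):
        gname = group_of_col[j]
        marg = draws.beta[:, j]
        if gname == "intercept":
            cond = marg
        else:
            g = draws.group_names.index(gname)
            mask = draws.gamma[:, g]
            cond = marg[mask] if mask.any() else np.zeros(draws.n_draws)
        lo_m, hi_m = _pci(marg)
        lo_c, hi_c = _pci(cond)
        c_rows.append({
            "column": col, "group": gname,
            "mean_marginal": float(marg.mean()), "pci_lo_marginal": lo_m,
            "pci_hi_marginal": hi_m,
            "mean_conditional": float(cond.mean()), "pci_lo_conditional": lo_c,
            "pci_hi_conditional": hi_c,
        })
    return {"groups": pd.DataFrame(g_rows), "coefficients": pd.DataFrame(c_rows)}


def pairwise_contrasts(draws: PosteriorDraws, covariate: str) -> pd.DataFrame:
    """All unordered level-pair differences of a categorical covariate.

    Level coefficients are differences from the baseline (whose coefficient
    is identically zero); a pair contrast is the per-draw difference of the
    two level coefficients, summarized by its posterior mean and 95% PCI.
    Reported both marginally (draws with the group excluded contribute zero
    differences) and conditional on inclusion.
    """
    if covariate not in draws.group_names:
        raise KeyError(f"unknown categorical covariate {covariate!r}")
    prefix = f"{covariate}["
    level_cols = {}
    for j, col in enumerate(draws.columns):
        if col.startswith(prefix):
            level_cols[col[len(prefix):-1]] = j
    if not level_cols:
        raise KeyError(f"{covariate!r} has no level columns; is it categorical?")
    # recover the full level list: baseline is the level without a column
    non_base = list(level_cols)
    g = draws.group_names.index(covariate)
    mask = draws.gamma[:, g]

    def coef(level):
        if level in level_cols:
            return draws.beta[:, level_cols[level]]
        return np.zeros(draws.n_draws)

    baseline_name = "baseline"
    levels = [baseline_name] + non_base
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            diff = coef(a) - coef(b)
            cond = diff[mask] if mask.any() else np.zeros(draws.n_draws)
            lo_m, hi_m = _pci(diff)
            lo_c, hi_c = _pci(cond)
            rows.append({
                "level_a": a, "level_b": b,
                "mean_marginal": float(diff.mean()),
                "pci_lo_marginal": lo_m, "pci_hi_marginal": hi_m,
                "mean_conditional": float(cond.mean()),
                "pci_lo_conditional": lo_c, "pci_hi_conditional": hi_c,
                "excludes_zero": bool(lo_m > 0 or hi_m < 0),
            })
    return pd.DataFrame(rows)


@dataclass
class AbsenceCurve:
    x: int
    draws: np.ndarray
    mean: float
    pci_lo: float
    pci_hi: float


def conditional_absence(draws: PosteriorDraws, x: int, K: int,
                        psi_mode: str = "mean_psi",
                        psi_value: float | None = None) -> AbsenceCurve:
    """Posterior of P(site unoccupied | x of K replicates amplified).

    Per draw d, with occupancy probability psi_d (the draw's site-averaged
    occupancy by default, or a supplied value with ``psi_mode='fixed'``):

        psi_d(x) = psi * [t11 b(x;K,p11) + (1-t11) b(x;K,p10)] /
                   {same + (1-psi) * [t10 b(x;K,p11) + (1-t10) b(x;K,p10)]}

    and the reported quantity is 1 - psi_d(x).
    """
    if not 0 <= x <= K:
        raise ValueError(f"x must lie in 0..K, got {x}")
    if psi_mode == "mean_psi":
        psi = draws.mean_psi
    elif psi_mode == "fixed":
        if psi_value is None:
            raise ValueError("psi_mode='fixed' requires psi_value")
        psi = np.full(draws.n_draws, float(psi_value))
    else:
        raise ValueError(f"unknown psi_mode {psi_mode!r}")
    b11 = binom.pmf(x, K, draws.p11)
    b10 = binom.pmf(x, K, draws.p10)
    num = psi * (draws.theta11 * b11 + (1.0 - draws.theta11) * b10)
    den = num + (1.0 - psi) * (draws.theta10 * b11 + (1.0 - draws.theta10) * b10)
    with np.errstate(invalid="ignore"):
        presence = np.where(den > 0, num / den, 0.0)
    absence = 1.0 - presence
    lo, hi = _pci(absence)
    return AbsenceCurve(x=x, draws=absence, mean=float(absence.mean()),
                        pci_lo=lo, pci_hi=hi)


def absence_curve_frame(draws: PosteriorDraws, K: int, **kw) -> pd.DataFrame:
    rows = []
    for x in range(K + 1):
        c = conditional_absence(draws, x, K, **kw)
        rows.append({"x": x, "mean_absence": c.mean, "pci_lo": c.pci_lo,
                     "pci_hi": c.pci_hi})
    return pd.DataFrame(rows)


def naive_occupancy(detection: pd.DataFrame, threshold: int) -> tuple[float, int]:
    """Proportion and count of sites with >= threshold amplifying replicates.

    A site counts as occupied iff the maximum y over its samples reaches the
    threshold — the rule-of-thumb occupancy call that ignores error rates.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    per_site = detection.groupby("site_id")["y_positive"].max()
    count = int((per_site >= threshold).sum())
    return count / len(per_site), count


def fp_magnification(p_fp: float, K: int, theta_fp: float = 0.0,
                     p11: float | None = None) -> float:
    """Probability a truly negative unit yields at least one amplification.

    Stage-2 only (a DNA-free sample): ``1 - (1 - p_fp)**K``.  With a Stage-1
    false-positive path (an unoccupied site, requires ``p11``): the sample
    may still contain DNA with probability theta_fp, in which case replicates
    amplify at the true-positive rate:

        theta_fp * (1 - (1-p11)**K) + (1-theta_fp) * (1 - (1-p_fp)**K)
    """
    if not 0.0 <= p_fp <= 1.0 or not 0.0 <= theta_fp <= 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    stage2 = 1.0 - (1.0 - p_fp) ** K
    if theta_fp == 0.0:
        return stage2
    if p11 is None:
        raise ValueError("the Stage-1 path requires p11")
    return theta_fp * (1.0 - (1.0 - p11) ** K) + (1.0 - theta_fp) * stage2
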