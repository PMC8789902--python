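"""Pólya-Gamma random variates, PG(1, z).

Devroye's alternating-series rejection sampler for the Jacobi-type density
J*(1, c): a draw X ~ J*(1, z/2) is returned as X/4 ~ PG(1, z).  The proposal
mixes a truncated inverse-Gaussian (left of t = 0.64) with a tilted
exponential tail, and acceptance is decided by the partial sums of the
alternating series for the target density — no series truncation error.

The per-element loop is numba-jitted; a vector of S draws costs well under a
millisecond, which is what makes the site-level Gibbs sweeps cheap.  Numba's
nopython RNG state is process-global and per-thread, so one PolyaGammaSampler
stream is active at a time; `fit` seeds it once per run.
"""

from __future__ import annotations

import math

import numba
import numpy as np

_T = 0.64  # proposal-region boundary of the Devroye sampler


@numba.njit(cache=True)
def _norm_cdf(x):
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@numba.njit(cache=True)
def _coef(n, x):
    # n-th term of the alternating series for the J*(1, ·) density at x
    if x <= _T:
        return (
            math.pi
            * (n + 0.5)
            * (2.0 / (math.pi * x)) ** 1.5
            * math.exp(-2.0 * (n + 0.5) ** 2 / x)
        )
    return math.pi * (n + 0.5) * math.exp(-((n + 0.5) ** 2) * math.pi**2 * x / 2.0)


@numba.njit(cache=True)
def _rtigauss(zh):
    # inverse-Gaussian IG(mu=1/zh, lambda=1) truncated to (0, _T); zh >= 0
    if zh < 1.0 / _T:
        # mu > t: rejection from a one-sided stable-like proposal
        while True:
            while True:
                e1 = np.random.exponential(1.0)
                e2 = np.random.exponential(1.0)
                if e1 * e1 <= 2.0 * e2 / _T:
                    break
            x = _T / (1.0 + _T * e1) ** 2
            if np.random.random() <= math.exp(-0.5 * zh * zh * x):
                return x
    else:
        mu = 1.0 / zh
        while True:
            y = np.random.normal() ** 2
            x = mu + 0.5 * mu * mu * y - 0.5 * mu * math.sqrt(4.0 * mu * y + (mu * y) ** 2)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
            if x <= _T:
                return x


@numba.njit(cache=True)
def _pg1(z):
    zh = abs(z) * 0.5
    k = math.pi**2 / 8.0 + zh * zh / 2.0
    # proposal mass right of _T (tilted exponential)
    p = math.pi / (2.0 * k) * math.exp(-k * _T)
    # proposal mass left of _T (truncated inverse-Gaussian), via the IG cdf
    isq = 1.0 / math.sqrt(_T)
    c1 = _norm_cdf(isq * (_T * zh - 1.0))
    c2 = _norm_cdf(-isq * (_T * zh + 1.0))
    q = 2.0 * math.exp(-zh) * c1
    if c2 > 0.0:
        q += 2.0 * math.exp(zh + math.log(c2))
    ratio = p / (p + q)
    while True:
        if np.random.random() < ratio:
            x = _T + np.random.exponential(1.0) / k
        else:
            x = _rtigauss(zh)
        s = _coef(0, x)
        y = np.random.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _coef(n, x)
                if y <= s:
                    return 0.25 * x
            else:
                s += _coef(n, x)
                if y > s:
                    break


@numba.njit(cache=True)
def _pg_vector(z, out):
    for i in range(z.shape[0]):
        out[i] = _pg1(z[i])


@numba.njit(cache=True)
def _seed_numba(seed):
    np.random.seed(seed)


def pg_mean(z: float) -> float:
    """E[PG(1, z)] = tanh(z/2) / (2z), continuous at z=0 where it is 1/4."""
    if z == 0.0:
        return 0.25
    return math.tanh(z / 2.0) / (2.0 * z)


class PolyaGammaSampler:
    """Seeded stream of PG(1, z) vectors.

    Parameters
    ----------
    seed : int
        Seeds numba's global nopython RNG (reduced mod 2**31).
    """

    def __init__(self, seed: int):
        _seed_numba(int(seed) % 2**31)

    def draw(self, z) -> np.ndarray:
        z = np.ascontiguousarray(np.atleast_1d(np.asarray(z, dtype=np.float64)))
        out = np.empty(z.shape[0])
        _pg_vector(z, out)
        return out
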