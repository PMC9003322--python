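"""Polya-Gamma PG(1, z) sampling for logistic data augmentation.

A Bernoulli-logit likelihood becomes conditionally Gaussian after
augmenting each observation with a Polya-Gamma latent variable, which is
what makes the outcome node of the network exactly Gibbs-sampleable.
Draws use the alternating-series rejection sampler on the tilted
Jacobi-theta density (PG(1, z) = J*(1, z/2) / 4), which is exact and
requires no tuning.  The hot loop is JIT-compiled; seeding goes through
the compiled module's global RNG state.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["sample_pg", "seed_pg", "pg_mean"]

_TRUNC = 0.64
_PI = np.pi


@njit(cache=True)
def _a_coef(n, x):
    # series coefficients of the J*(1, 0) density, piecewise around _TRUNC
    if x <= _TRUNC:
        return _PI * (n + 0.5) * (2.0 / _PI / x) ** 1.5 \
            * np.exp(-2.0 * (n + 0.5) ** 2 / x)
    return _PI * (n + 0.5) * np.exp(-(n + 0.5) ** 2 * _PI ** 2 * x / 2.0)


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / np.sqrt(2.0)))


@njit(cache=True)
def _rtigauss(z, t):
    """Inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, t]."""
    x = t + 1.0
    mu = 1.0 / z if z > 0 else 1e18
    if mu > t:
        # rejection from the z = 0 (one-sided stable) proposal
        while True:
            while True:
                e1 = np.random.exponential(1.0)
                e2 = np.random.exponential(1.0)
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / (1.0 + t * e1) ** 2
            alpha = np.exp(-0.5 * z * z * x)
            if np.random.random() <= alpha:
                break
    else:
        while x > t:
            y = np.random.normal() ** 2
            muy = mu * y
            x = mu + 0.5 * mu * muy - 0.5 * mu * np.sqrt(4.0 * muy + muy * muy)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
    return x


@njit(cache=True)
def _sample_jstar(z):
    """J*(1, z) by the alternating-series rejection sampler."""
    z = abs(z)
    fz = _PI ** 2 / 8.0 + z * z / 2.0
    t = _TRUNC
    # probability of the exponential (right) branch of the proposal
    b = np.sqrt(1.0 / t) * (t * z - 1.0)
    a = -np.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = np.log(fz) + fz * t
    xb = x0 - z + np.log(_norm_cdf(b))
    xa = x0 + z + np.log(_norm_cdf(a))
    qdivp = 4.0 / _PI * (np.exp(xb) + np.exp(xa))
    p_right = 1.0 / (1.0 + qdivp)
    while True:
        if np.random.random() < p_right:
            x = t + np.random.exponential(1.0) / fz
        else:
            x = _rtigauss(z, t)
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        accept = False
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    accept = True
                    break
            else:
                s += _a_coef(n, x)
                if y > s:
                    break
        if accept:
            return x


@njit(cache=True)
def _sample_pg_vec(z, out):
    for i in range(z.size):
        out[i] = 0.25 * _sample_jstar(0.5 * z[i])


@njit(cache=True)
def _seed(value):
    np.random.seed(value)


def seed_pg(value: int) -> None:
    """Seed the compiled sampler's RNG state (call once per chain)."""
    _seed(int(value) % (2 ** 31))


def sample_pg(z: np.ndarray) -> np.ndarray:
    """One PG(1, z_i) draw per element of z."""
    z = np.ascontiguousarray(z, dtype=np.float64)
    out = np.empty_like(z)
    _sample_pg_vec(z, out)
    return out


def pg_mean(z: np.ndarray) -> np.ndarray:
    """E[PG(1, z)] = tanh(z/2) / (2 z), continuous at zero."""
    z = np.asarray(z, dtype=float)
    out = np.full(z.shape, 0.25)
    nz = np.abs(z) > 1e-8
    out[nz] = np.tanh(z[nz] / 2.0) / (2.0 * z[nz])
    return out
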