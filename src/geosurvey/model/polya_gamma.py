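"""Exact Polya-Gamma PG(1, z) sampling by Devroye's alternating-series
rejection method (as used for logistic data augmentation).

The hot loop is compiled with numba when available; the same code runs
as plain Python otherwise (slow but correct).  Draws are reproducible
from an integer seed passed per call.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

__all__ = ["polya_gamma", "pg_mean", "HAVE_NUMBA"]

_TRUNC = 0.64
_PI = math.pi


@njit(cache=True)
def _log_norm_cdf(x: float) -> float:
    return math.log(0.5 * math.erfc(-x / math.sqrt(2.0)))


@njit(cache=True)
def _mass_texpon(z: float) -> float:
    # probability that the proposal draws from the exponential right tail
    t = _TRUNC
    fz = _PI * _PI / 8.0 + z * z / 2.0
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    xb = x0 - z + _log_norm_cdf(b)
    xa = x0 + z + _log_norm_cdf(a)
    qdivp = 4.0 / _PI * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rtigauss(z: float) -> float:
    # inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, _TRUNC)
    t = _TRUNC
    x = t + 1.0
    if z < 1.0 / t:
        while True:
            while True:
                e1 = -math.log(np.random.random())
                e2 = -math.log(np.random.random())
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            alpha = math.exp(-0.5 * z * z * x)
            if np.random.random() <= alpha:
                break
    else:
        mu = 1.0 / z
        while x > t:
            y = np.random.standard_normal()
            y = y * y
            half_mu = 0.5 * mu
            mu_y = mu * y
            x = mu + half_mu * mu_y - half_mu * math.sqrt(4.0 * mu_y + mu_y * mu_y)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
    return x


@njit(cache=True)
def _a_coef(n: int, x: float) -> float:
    k = n + 0.5
    if x > _TRUNC:
        return _PI * k * math.exp(-k * k * _PI * _PI * x / 2.0)
    return (2.0 / (_PI * x)) ** 1.5 * _PI * k * math.exp(-2.0 * k * k / x)


@njit(cache=True)
def _sample_jstar(z: float) -> float:
    # one draw of J*(1, z); the PG(1, c) draw is J*(1, |c|/2) / 4
    z = abs(z)
    fz = _PI * _PI / 8.0 + z * z / 2.0
    while True:
        if np.random.random() < _mass_texpon(z):
            x = _TRUNC - math.log(np.random.random()) / fz
        else:
            x = _rtigauss(z)
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        accepted = False
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    accepted = True
                    break
            else:
                s += _a_coef(n, x)
                if y > s:
                    break
        if accepted:
            return x


@njit(cache=True)
def _pg_vector(z: np.ndarray, seed: int) -> np.ndarray:
    np.random.seed(seed)
    out = np.empty(z.shape[0])
    for i in range(z.shape[0]):
        out[i] = 0.25 * _sample_jstar(0.5 * z[i])
    return out


def polya_gamma(z: np.ndarray, seed: int) -> np.ndarray:
    """Draw PG(1, z_i) for each entry of ``z``, reproducibly from ``seed``."""
    z = np.ascontiguousarray(np.asarray(z, dtype=np.float64))
    return _pg_vector(z, int(seed) & 0x7FFFFFFF)


def pg_mean(z: np.ndarray) -> np.ndarray:
    """E[PG(1, z)] = tanh(z/2) / (2z), continuous at z=0 (value 1/4)."""
    z = np.asarray(z, dtype=float)
    out = np.full(z.shape, 0.25)
    nz = np.abs(z) > 1e-12
    out[nz] = np.tanh(z[nz] / 2.0) / (2.0 * z[nz])
    return out
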