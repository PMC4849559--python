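"""Accelerated-failure-time (AFT) survival families.

All families are parameterised on the log-time scale with location
``mu = x'beta``, scale ``sigma`` and (generalised gamma only) shape ``Q``:

* exponential:        S(t) = exp(-t * exp(-mu))
* Weibull:            S(t) = exp(-(t * exp(-mu))**(1/sigma))
* lognormal:          S(t) = 1 - Phi((ln t - mu) / sigma)
* generalised gamma   (Prentice form; nests Weibull at Q=1 and lognormal
  as Q -> 0): with w = (ln t - mu)/sigma and k = Q**-2,
  S(t) = GammaUpperReg(k, k*exp(Q*w)) for Q > 0 (lower tail for Q < 0).

Log-density, log-survival and hazard are vectorised over ``t`` and ``mu``.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

FAMILIES = ("exponential", "weibull", "lognormal", "generalised_gamma")

#: estimated ancillary parameter count per family
N_ANCILLARY = {"exponential": 0, "weibull": 1, "lognormal": 1, "generalised_gamma": 2}

_Q_LOGNORMAL_TOL = 1e-6  # |Q| below this treated as the lognormal limit


def _w(t, mu, sigma):
    t = np.asarray(t, dtype=float)
    return (np.log(t) - mu) / sigma


def logpdf(t, mu, sigma=1.0, q=None, family="weibull"):
    """log f(t); ``t`` must be strictly positive."""
    t = np.asarray(t, dtype=float)
    if family == "exponential":
        return -mu - t * np.exp(-mu)
    w = _w(t, mu, sigma)
    if family == "weibull":
        return -np.log(sigma) - np.log(t) + w - np.exp(w)
    if family == "lognormal":
        return -np.log(sigma) - np.log(t) + stats.norm.logpdf(w)
    if family == "generalised_gamma":
        if abs(q) < _Q_LOGNORMAL_TOL:
            return -np.log(sigma) - np.log(t) + stats.norm.logpdf(w)
        k = q**-2.0
        qw = np.clip(q * w, -700.0, 700.0)
        return (
            np.log(abs(q))
            + k * np.log(k)
            - special.gammaln(k)
            - np.log(sigma)
            - np.log(t)
            + k * (qw - np.exp(qw))
        )
    raise ValueError(f"unknown family {family!r}")


def logsf(t, mu, sigma=1.0, q=None, family="weibull"):
    """log S(t), the log of the survival function."""
    t = np.asarray(t, dtype=float)
    if family == "exponential":
        return -t * np.exp(-mu)
    w = _w(t, mu, sigma)
    if family == "weibull":
        return -np.exp(np.clip(w, -np.inf, 700.0))
    if family == "lognormal":
        return stats.norm.logsf(w)
    if family == "generalised_gamma":
        if abs(q) < _Q_LOGNORMAL_TOL:
            return stats.norm.logsf(w)
        k = q**-2.0
        u = k * np.exp(np.clip(q * w, -700.0, 700.0))
        if q > 0:
            sf = special.gammaincc(k, u)
        else:
            sf = special.gammainc(k, u)
        return np.log(np.clip(sf, 1e-320, 1.0))
    raise ValueError(f"unknown family {family!r}")


def hazard(t, mu, sigma=1.0, q=None, family="weibull"):
    """Instantaneous hazard h(t) = f(t)/S(t), per year.

    Exponential and Weibull use their closed forms (numerically stable in
    the deep tail); elsewhere an exhausted survival function yields an
    infinite, not NaN, hazard.
    """
    t = np.asarray(t, dtype=float)
    if family == "exponential":
        with np.errstate(over="ignore"):
            return np.broadcast_to(
                np.exp(-np.asarray(mu, dtype=float)),
                np.broadcast_shapes(t.shape, np.shape(mu)),
            ).copy()
    if family == "weibull":
        w = _w(t, mu, sigma)
        return np.exp(np.clip(w, -745.0, 709.0)) / (sigma * t)
    with np.errstate(over="ignore", invalid="ignore"):
        h = np.exp(logpdf(t, mu, sigma, q, family) - logsf(t, mu, sigma, q, family))
    return np.where(np.isnan(h), np.inf, h)


def sample(rng, mu, sigma=1.0, q=None, family="weibull"):
    """Draw event times; ``mu`` may be an array (one draw per element)."""
    mu = np.asarray(mu, dtype=float)
    n = mu.shape if mu.shape else (1,)
    if family == "exponential":
        return rng.exponential(1.0, size=n) * np.exp(mu)
    if family == "weibull":
        e = rng.exponential(1.0, size=n)
        return np.exp(mu + sigma * np.log(e))
    if family == "lognormal":
        return np.exp(mu + sigma * rng.standard_normal(n))
    if family == "generalised_gamma":
        if abs(q) < _Q_LOGNORMAL_TOL:
            return np.exp(mu + sigma * rng.standard_normal(n))
        k = q**-2.0
        g = rng.gamma(shape=k, scale=1.0, size=n)
        w = np.log(g / k) / q
        return np.exp(mu + sigma * w)
    raise ValueError(f"unknown family {family!r}")
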