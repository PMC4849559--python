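"""Maximum-likelihood fitting of right-censored parametric AFT models.

The estimation scale is ``theta = (beta, log sigma[, Q])``; the
variance–covariance matrix returned is the inverse observed information on
that scale, which is also the scale used by the probabilistic sensitivity
analysis.  Optimisation is multi-start: every family starts from the
closed-form-initialised exponential fit, and the generalised gamma
additionally from the fitted Weibull (Q=1) and lognormal (Q≈0) solutions.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.tools.numdiff import approx_fprime, approx_hess3

from scadmodel import families
from scadmodel.covariates import linear_predictor

GRADIENT_TOL = 1e-7  # on the mean log-likelihood, standardised-covariate scale


class ConvergenceError(RuntimeError):
    pass


def data_fingerprint(times: np.ndarray, events: np.ndarray, x: np.ndarray | None) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(times, dtype=float).tobytes())
    h.update(np.ascontiguousarray(events, dtype=np.int64).tobytes())
    if x is not None:
        h.update(np.ascontiguousarray(x, dtype=float).tobytes())
    return h.hexdigest()[:16]


@dataclass
class SurvivalFit:
    """A fitted parametric survival equation for one endpoint."""

    endpoint: str
    family: str
    coef: pd.Series  # location coefficients, index includes "intercept"
    sigma: float
    q: float | None
    vcov: np.ndarray  # on the (beta, log sigma[, Q]) scale
    loglik: float
    n_events: int
    n_obs: int
    fingerprint: str = ""
    param_names: list[str] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return len(self.coef) + families.N_ANCILLARY[self.family]

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    # -- evaluation ---------------------------------------------------
    def location(self, design: pd.Series | pd.DataFrame) -> np.ndarray | float:
        return linear_predictor(design, self.coef)

    def hazard(self, t, design) -> np.ndarray:
        """Cause-specific hazard h(t | x) per year; t strictly positive."""
        mu = self.location(design)
        return families.hazard(t, mu, self.sigma, self.q, self.family)

    def survival(self, t, design) -> np.ndarray:
        mu = self.location(design)
        return np.exp(families.logsf(t, mu, self.sigma, self.q, self.family))

    def hazard_fn(self, design):
        """Return ``h(t)`` as a callable closed over one profile."""
        mu = float(self.location(design))
        fam, sigma, q = self.family, self.sigma, self.q
        return lambda t: families.hazard(np.maximum(t, 1e-12), mu, sigma, q, fam)

    # -- (de)serialisation --------------------------------------------
    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "family": self.family,
            "coef": {k: float(v) for k, v in self.coef.items()},
            "sigma": self.sigma,
            "q": self.q,
            "vcov": np.asarray(self.vcov).tolist(),
            "loglik": self.loglik,
            "n_events": int(self.n_events),
            "n_obs": int(self.n_obs),
            "fingerprint": self.fingerprint,
            "param_names": list(self.param_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurvivalFit":
        return cls(
            endpoint=d["endpoint"],
            family=d["family"],
            coef=pd.Series(d["coef"], dtype=float),
            sigma=float(d["sigma"]),
            q=None if d["q"] is None else float(d["q"]),
            vcov=np.asarray(d["vcov"], dtype=float),
            loglik=float(d["loglik"]),
            n_events=int(d["n_events"]),
            n_obs=int(d["n_obs"]),
            fingerprint=d.get("fingerprint", ""),
            param_names=list(d.get("param_names", [])),
        )


def _unpack(theta: np.ndarray, p: int, family: str):
    beta = theta[:p]
    if family == "exponential":
        return beta, 1.0, None
    sigma = float(np.exp(theta[p]))
    q = float(theta[p + 1]) if family == "generalised_gamma" else None
    return beta, sigma, q


def _nll(theta, times, events, x, family):
    """Average negative log-likelihood (scale-free for the optimiser)."""
    p = x.shape[1]
    beta, sigma, q = _unpack(theta, p, family)
    mu = x @ beta
    with np.errstate(over="ignore", invalid="ignore"):
        ll_e = families.logpdf(times, mu, sigma, q, family)
        ll_c = families.logsf(times, mu, sigma, q, family)
    ll = np.where(events == 1, ll_e, ll_c)
    if not np.all(np.isfinite(ll)):
        return 1e12
    return -float(np.mean(ll))


def _fit_family(times, events, x, family, starts):
    best = None
    for theta0 in starts:
        res = optimize.minimize(
            _nll,
            theta0,
            args=(times, events, x, family),
            method="BFGS",
            options={"gtol": GRADIENT_TOL, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit_parametric(
    times,
    events,
    covariates: pd.DataFrame | None = None,
    family: str = "weibull",
    endpoint: str = "",
) -> SurvivalFit:
    """Fit one right-censored AFT model by maximum likelihood.

    Parameters
    ----------
    times, events
        Follow-up time in years and event indicator (1 = event of this
        cause, 0 = censored, including censoring by competing causes).
    covariates
        Design frame (no intercept column; one is added), or ``None``
        for an intercept-only model.
    family
        One of ``exponential, weibull, lognormal, generalised_gamma``.
    """
    if family not in families.FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {families.FAMILIES}")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times <= 0):
        raise ValueError("all follow-up times must be strictly positive")
    d = int(events.sum())
    if d == 0:
        raise ValueError(f"endpoint {endpoint!r}: zero events — cannot fit")
    if d < 10:
        warnings.warn(f"endpoint {endpoint!r}: only {d} events; fit may be unstable")

    names = ["intercept"] + (list(covariates.columns) if covariates is not None else [])
    if covariates is not None:
        x_raw = np.column_stack([np.ones(len(times)), covariates.to_numpy(float)])
    else:
        x_raw = np.ones((len(times), 1))
    p = x_raw.shape[1]
    fp = data_fingerprint(times, events, x_raw if covariates is not None else None)

    # standardise non-intercept columns for optimisation; estimates and
    # vcov are mapped back to the raw-covariate scale afterwards
    center = x_raw.mean(axis=0)
    center[0] = 0.0
    scale = x_raw.std(axis=0)
    scale[scale == 0] = 1.0
    scale[0] = 1.0
    x = (x_raw - center) / scale

    # exponential closed-form-style start: intercept = log(total time / events)
    beta0 = np.zeros(p)
    beta0[0] = np.log(times.sum() / d)
    res_exp = _fit_family(times, events, x, "exponential", [beta0])

    if family == "exponential":
        res = res_exp
    elif family in ("weibull", "lognormal"):
        res = _fit_family(
            times, events, x, family, [np.concatenate([res_exp.x, [0.0]])]
        )
    else:  # generalised gamma: multi-start from its two nested families
        res_w = _fit_family(times, events, x, "weibull", [np.concatenate([res_exp.x, [0.0]])])
        res_l = _fit_family(times, events, x, "lognormal", [np.concatenate([res_exp.x, [0.0]])])
        starts = [
            np.concatenate([res_w.x, [1.0]]),
            np.concatenate([res_l.x, [0.05]]),
        ]
        res = _fit_family(times, events, x, family, starts)

    grad = approx_fprime(res.x, _nll, args=(times, events, x, family), centered=True)
    gnorm = float(np.max(np.abs(grad)))
    # gradient of the per-observation mean log-likelihood on the
    # standardised scale; flat generalised-gamma ridges get a little slack
    if gnorm > (1e-4 if family != "generalised_gamma" else 1e-3):
        raise ConvergenceError(
            f"{family} fit for endpoint {endpoint!r} did not converge "
            f"(max |gradient| = {gnorm:.3e})"
        )

    n = len(times)
    hess = n * approx_hess3(res.x, _nll, args=(times, events, x, family))
    hess = 0.5 * (hess + hess.T)
    # regularised inversion: flat or numerically indefinite directions
    # (rare endpoints, saturated designs) get large-but-finite variance
    evals, evecs = np.linalg.eigh(hess)
    floor = max(1e-10 * np.max(np.abs(evals)), 1e-12)
    evals = np.clip(evals, floor, None)
    vcov_std = (evecs / evals) @ evecs.T

    # map (beta_std, ancillary) back to the raw-covariate scale
    n_anc = families.N_ANCILLARY[family]
    a = np.eye(p + n_anc)
    a[0, 1:p] = -center[1:] / scale[1:]
    for j in range(1, p):
        a[j, j] = 1.0 / scale[j]
    theta_raw = a @ res.x
    vcov = a @ vcov_std @ a.T
    vcov = 0.5 * (vcov + vcov.T)

    beta, sigma, q = _unpack(theta_raw, p, family)
    param_names = list(names)
    if family != "exponential":
        param_names.append("log_sigma")
    if family == "generalised_gamma":
        param_names.append("q")
    return SurvivalFit(
        endpoint=endpoint,
        family=family,
        coef=pd.Series(beta, index=names),
        sigma=sigma,
        q=q,
        vcov=vcov,
        loglik=-float(res.fun) * n,
        n_events=d,
        n_obs=len(times),
        fingerprint=fp,
        param_names=param_names,
    )


def select_best_family(fits: list[SurvivalFit]) -> SurvivalFit:
    """Minimum-AIC fit; ties (ΔAIC < 1e-6) go to the fewer-parameter model."""
    if not fits:
        raise ValueError("no candidate fits supplied")
    if len(fits) == 1:
        return fits[0]
    fps = {f.fingerprint for f in fits}
    if len(fps) > 1:
        raise ValueError("candidate fits were not estimated on the same data")
    best = fits[0]
    for f in fits[1:]:
        if f.aic < best.aic - 1e-6:
            best = f
        elif abs(f.aic - best.aic) <= 1e-6 and f.n_params < best.n_params:
            best = f
    return best
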