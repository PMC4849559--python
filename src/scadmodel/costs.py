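"""Per-cycle costs and health-state utilities.

Costs: a log-link mean model per 90-day cycle, estimated on the panel by
Poisson quasi-likelihood (the standard consistent estimator for
non-negative right-skewed cost data) with cluster-robust (by patient)
uncertainty.  Two components — CVD-attributable and other — are modelled
separately and sum to the total, so both total and CVD-specific lifetime
costs can be reported.

Utilities: an EQ-5D-style catalogue of age/sex base scores multiplied by
condition and event multipliers, with an extra decrement in the acute
(event) cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from scadmodel.covariates import design_matrix

log = logging.getLogger(__name__)

CYCLE_LENGTH_YEARS = 90.0 / 365.25

#: baseline covariates entering the cost model by default (current age is
#: used instead of age at entry, so baseline age is deliberately absent)
DEFAULT_COST_COVARIATES = (
    "sex_female",
    "diabetes",
    "heart_failure",
    "previous_mi",
    "copd",
    "cancer",
    "ckd",
)

LIVE_STATES = ("stable", "post_mi", "post_is", "post_hs")
EARLY_BAND_CYCLES = 4  # cycles 1..4 after an event form the "early" band

COMPONENTS = ("cvd", "other")

UTILITY_FLOOR = -0.594  # EQ-5D UK value-set minimum


@dataclass
class CostComponent:
    coef: pd.Series
    vcov: np.ndarray
    dispersion: float


@dataclass
class CostModel:
    """Two log-link component models; total cost = cvd + other."""

    components: dict[str, CostComponent]
    baseline_covariates: tuple[str, ...] = DEFAULT_COST_COVARIATES

    def to_dict(self) -> dict:
        return {
            "baseline_covariates": list(self.baseline_covariates),
            "components": {
                k: {
                    "coef": {n: float(v) for n, v in c.coef.items()},
                    "vcov": np.asarray(c.vcov).tolist(),
                    "dispersion": float(c.dispersion),
                }
                for k, c in self.components.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CostModel":
        comps = {
            k: CostComponent(
                coef=pd.Series(v["coef"], dtype=float),
                vcov=np.asarray(v["vcov"], dtype=float),
                dispersion=float(v["dispersion"]),
            )
            for k, v in d["components"].items()
        }
        return cls(components=comps, baseline_covariates=tuple(d["baseline_covariates"]))


def cost_features(
    profile_design: pd.Series,
    state: str,
    cycles_since_event: int | None,
    current_age: float,
    baseline_covariates: tuple[str, ...] = DEFAULT_COST_COVARIATES,
) -> pd.Series:
    """Feature vector for one cycle of one profile (possibly group-mean)."""
    if state not in LIVE_STATES:
        raise ValueError(f"cost is only defined for live states, got {state!r}")
    feat = {name: float(profile_design[name]) for name in baseline_covariates}
    feat["current_age"] = float(current_age)
    for s in LIVE_STATES[1:]:
        feat[f"state_{s}"] = 1.0 if state == s else 0.0
    in_post = state != "stable"
    feat["acute"] = 1.0 if (in_post and cycles_since_event == 0) else 0.0
    feat["band_early"] = (
        1.0 if (in_post and cycles_since_event is not None
                and 1 <= cycles_since_event <= EARLY_BAND_CYCLES) else 0.0
    )
    return pd.Series(feat)


def _component_mean(comp: CostComponent, feats: pd.Series | pd.DataFrame) -> np.ndarray:
    lp = comp.coef.get("intercept", 0.0)
    for name, val in comp.coef.items():
        if name == "intercept":
            continue
        lp = lp + val * (feats[name] if isinstance(feats, pd.DataFrame) else float(feats[name]))
    return np.exp(lp)


def cycle_cost(
    model: CostModel,
    profile_design: pd.Series,
    state: str,
    cycles_since_event: int | None,
    current_age: float,
) -> float:
    """Expected total cost (GBP) for one 90-day cycle."""
    comps = cycle_cost_components(model, profile_design, state, cycles_since_event, current_age)
    return float(sum(comps.values()))


def cycle_cost_components(
    model: CostModel,
    profile_design: pd.Series,
    state: str,
    cycles_since_event: int | None,
    current_age: float,
) -> dict[str, float]:
    feats = cost_features(profile_design, state, cycles_since_event, current_age,
                          model.baseline_covariates)
    return {k: float(_component_mean(c, feats)) for k, c in model.components.items()}


def fit_cost_model(
    panel: pd.DataFrame,
    cohort: pd.DataFrame,
    baseline_covariates: tuple[str, ...] = DEFAULT_COST_COVARIATES,
) -> CostModel:
    """Fit the two-component log-link cost model on a 90-day panel.

    The panel needs columns ``patient_id, cycle_index, state_at_cycle,
    cycles_since_event, observed_cost, observed_cost_cvd``.
    """
    if len(panel) == 0:
        raise ValueError("cost panel is empty")
    if (panel["observed_cost"] < 0).any():
        raise ValueError("observed costs must be non-negative")
    if (panel["observed_cost_cvd"] > panel["observed_cost"] + 1e-9).any():
        raise ValueError("CVD cost component exceeds total cost")
    merged = panel.merge(cohort, on="patient_id", how="left", validate="m:1")
    if merged["age_entry"].isna().any():
        raise ValueError("panel rows reference patients absent from the cohort")
    # contiguous patient blocks (required by the cluster-robust sandwich)
    merged = merged.sort_values(["patient_id", "cycle_index"], kind="stable").reset_index(
        drop=True
    )

    xprof = design_matrix(merged)
    age = merged["age_entry"].to_numpy(float) + merged["cycle_index"].to_numpy(float) * CYCLE_LENGTH_YEARS
    state = merged["state_at_cycle"]
    cse = merged["cycles_since_event"]
    in_post = state != "stable"
    feats = pd.DataFrame({name: xprof[name].to_numpy(float) for name in baseline_covariates})
    feats["current_age"] = age
    for s in LIVE_STATES[1:]:
        feats[f"state_{s}"] = (state == s).astype(float).to_numpy()
    feats["acute"] = (in_post & (cse == 0)).astype(float).to_numpy()
    feats["band_early"] = (in_post & cse.between(1, EARLY_BAND_CYCLES)).astype(float).to_numpy()
    x = sm.add_constant(feats, prepend=True).rename(columns={"const": "intercept"})

    groups = merged["patient_id"].to_numpy()
    comps: dict[str, CostComponent] = {}
    y_by_comp = {
        "cvd": merged["observed_cost_cvd"].to_numpy(float),
        "other": (merged["observed_cost"] - merged["observed_cost_cvd"]).to_numpy(float),
    }
    xa = x.to_numpy(float)
    for name, y in y_by_comp.items():
        if np.all(y == 0):
            raise ValueError(f"degenerate fit: all {name} costs are zero")
        coef, vcov, dispersion = _poisson_qmle(y, xa, groups)
        comps[name] = CostComponent(
            coef=pd.Series(coef, index=x.columns), vcov=vcov, dispersion=dispersion
        )
    return CostModel(components=comps, baseline_covariates=tuple(baseline_covariates))


def _poisson_qmle(y: np.ndarray, x: np.ndarray, groups: np.ndarray,
                  tol: float = 1e-10, maxiter: int = 100):
    """Log-link Poisson quasi-likelihood mean model by damped Newton.

    Equivalent to a Poisson GLM (the standard consistent estimator for a
    log-link mean regardless of the outcome distribution) with a
    cluster-robust sandwich covariance; solved directly because cost
    panels run to ~10^6 rows.  ``groups`` must be contiguous (panel rows
    are written patient by patient).
    """
    n, p = x.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-12))

    def quasi_ll(b):
        eta = np.clip(x @ b, -500, 500)
        return float(y @ eta - np.exp(eta).sum())

    ll = quasi_ll(beta)
    for _ in range(maxiter):
        eta = np.clip(x @ beta, -500, 500)
        mu = np.exp(eta)
        grad = x.T @ (y - mu)
        hess = (x * mu[:, None]).T @ x
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        lam = 1.0
        for _ in range(30):  # step-halving line search
            cand = beta + lam * step
            ll_new = quasi_ll(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            lam *= 0.5
        beta, ll_prev, ll = cand, ll, ll_new
        if np.max(np.abs(grad)) < tol * max(1.0, abs(ll)) or abs(ll - ll_prev) < 1e-12 * (
            1 + abs(ll)
        ):
            break

    eta = np.clip(x @ beta, -500, 500)
    mu = np.exp(eta)
    hess = (x * mu[:, None]).T @ x
    bread = np.linalg.pinv(hess)
    # cluster-robust meat: per-patient score sums (rows are grouped)
    score = x * (y - mu)[:, None]
    boundaries = np.flatnonzero(np.r_[True, groups[1:] != groups[:-1]])
    sg = np.add.reduceat(score, boundaries, axis=0)
    vcov = bread @ (sg.T @ sg) @ bread
    dispersion = float(np.sum((y - mu) ** 2 / np.maximum(mu, 1e-300)) / max(n - p, 1))
    return beta, 0.5 * (vcov + vcov.T), dispersion


# ---------------------------------------------------------------------------
# utilities


@dataclass
class UtilityCatalogue:
    """Age/sex base EQ-5D scores with condition and event multipliers."""

    bands: pd.DataFrame  # columns: sex, age_lo, age_hi, base_utility
    condition_multiplier: float = 1.0
    event_multipliers: dict | None = None  # post_mi / post_is / post_hs
    acute_multiplier: float = 1.0

    def __post_init__(self):
        if self.event_multipliers is None:
            self.event_multipliers = {"post_mi": 1.0, "post_is": 1.0, "post_hs": 1.0}
        b = self.bands
        if not b["base_utility"].between(UTILITY_FLOOR, 1.0).all():
            raise ValueError("base utilities must lie within the EQ-5D range")
        for m in [self.condition_multiplier, self.acute_multiplier,
                  *self.event_multipliers.values()]:
            if not 0.0 < m <= 1.0:
                raise ValueError("multipliers must lie in (0, 1]")

    def base(self, sex: str, age: float) -> float:
        sub = self.bands[self.bands["sex"] == sex]
        hit = sub[(sub["age_lo"] <= age) & (age <= sub["age_hi"])]
        if len(hit) == 0:
            log.warning("no utility band for sex=%s age=%.1f; using nearest band", sex, age)
            mid = (sub["age_lo"] + sub["age_hi"]) / 2.0
            hit = sub.iloc[[int((mid - age).abs().argmin())]]
        return float(hit["base_utility"].iloc[0])

    def to_frame(self) -> pd.DataFrame:
        out = self.bands.copy()
        out["condition_multiplier"] = self.condition_multiplier
        out["acute_multiplier"] = self.acute_multiplier
        for k, v in self.event_multipliers.items():
            out[f"mult_{k}"] = v
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "UtilityCatalogue":
        mult_cols = [c for c in df.columns if c.startswith("mult_")]
        return cls(
            bands=df[["sex", "age_lo", "age_hi", "base_utility"]].copy(),
            condition_multiplier=float(df["condition_multiplier"].iloc[0]),
            acute_multiplier=float(df["acute_multiplier"].iloc[0]),
            event_multipliers={c[len("mult_"):]: float(df[c].iloc[0]) for c in mult_cols},
        )

    def perturbed(self, rng: np.random.Generator, concentration: float = 200.0) -> "UtilityCatalogue":
        """Beta-perturbed copy for probabilistic sensitivity analysis.

        Base utilities are rescaled to (0, 1) over the EQ-5D range and drawn
        from a Beta with the catalogue value as mean; multipliers likewise.
        """
        def beta_draw(mean01):
            mean01 = np.clip(mean01, 1e-4, 1.0 - 1e-4)
            return rng.beta(mean01 * concentration, (1.0 - mean01) * concentration)

        span = 1.0 - UTILITY_FLOOR
        bands = self.bands.copy()
        bands["base_utility"] = [
            UTILITY_FLOOR + span * beta_draw((u - UTILITY_FLOOR) / span)
            for u in bands["base_utility"]
        ]
        return replace(
            self,
            bands=bands,
            condition_multiplier=float(beta_draw(self.condition_multiplier)),
            acute_multiplier=float(beta_draw(self.acute_multiplier)),
            event_multipliers={k: float(beta_draw(v)) for k, v in self.event_multipliers.items()},
        )


def cycle_utility(
    catalogue: UtilityCatalogue,
    profile_design: pd.Series,
    state: str,
    cycles_since_event: int | None,
    current_age: float,
) -> float:
    """Utility weight for one cycle: base(sex, age) x condition x event
    multipliers, acute decrement only in the event cycle.  Fractional
    ``sex_female`` (group-mean profile) blends the male/female bases."""
    if state not in LIVE_STATES:
        raise ValueError(f"utility only defined for live states, got {state!r}")
    sexf = float(profile_design["sex_female"])
    base = (1.0 - sexf) * catalogue.base("male", current_age) + sexf * catalogue.base(
        "female", current_age
    )
    u = base * catalogue.condition_multiplier
    if state != "stable":
        u *= catalogue.event_multipliers[state]
        if cycles_since_event == 0:
            u *= catalogue.acute_multiplier
    return float(u)
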