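"""Risk-decile stratification and probabilistic sensitivity analysis.

Patients are ranked by predicted 5-year composite CVD risk and split into
equally sized groups (ties broken by patient id).  The model is then
evaluated at each group's mean covariate vector — categoricals entering
as level proportions — and for a representative (median-risk) member.

PSA: survival and cost coefficients are drawn from multivariate normals
on their estimation scales (location coefficients, log scale, shape),
utilities from beta perturbations, and the cohort model is re-run per
draw; uncertainty is summarised by percentile intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from scadmodel.costs import CostModel, UtilityCatalogue
from scadmodel.covariates import design_matrix
from scadmodel.equations import (
    RiskEquationSet,
    predict_5yr_composite_risk,
    predict_5yr_composite_risk_cohort,
)
from scadmodel.markov import ModelOutputs, TreatmentEffect, run_cohort
from scadmodel.survival import SurvivalFit

log = logging.getLogger(__name__)


@dataclass
class RiskGroup:
    index: int  # 1 = lowest risk
    members: pd.DataFrame  # profile rows
    risks: np.ndarray  # predicted 5-year composite risk per member
    mean_covariates: pd.Series  # design-space mean (fractional indicators)
    mean_risk: float
    risk_at_mean: float


def assign_risk_groups(
    cohort: pd.DataFrame, equations: RiskEquationSet, k: int = 10
) -> list[RiskGroup]:
    """Rank by predicted risk and split into ``k`` near-equal groups."""
    if k > len(cohort):
        raise ValueError(f"cannot form {k} groups from {len(cohort)} patients")
    risks = predict_5yr_composite_risk_cohort(equations, cohort)
    order = np.lexsort((cohort["patient_id"].to_numpy(), risks))
    groups: list[RiskGroup] = []
    for gi, idx in enumerate(np.array_split(order, k), start=1):
        members = cohort.iloc[idx].reset_index(drop=True)
        gr = risks[idx]
        mean_cov = design_matrix(members).mean(axis=0)
        groups.append(
            RiskGroup(
                index=gi,
                members=members,
                risks=gr,
                mean_covariates=mean_cov,
                mean_risk=float(gr.mean()),
                risk_at_mean=predict_5yr_composite_risk(equations, mean_cov),
            )
        )
    return groups


def representative_patient(group: RiskGroup) -> pd.Series:
    """The member at the group's median risk (lower of two at even sizes)."""
    if len(group.members) == 0:
        raise ValueError("group is empty")
    order = np.argsort(group.risks, kind="stable")
    med = order[(len(order) - 1) // 2]
    return group.members.iloc[med]


def group_summary(groups: list[RiskGroup]) -> pd.DataFrame:
    """Tidy per-group baseline-characteristics and risk summary."""
    rows = []
    for g in groups:
        row = {"risk_group": g.index, "n": len(g.members),
               "mean_5yr_risk": g.mean_risk, "risk_at_mean_covariates": g.risk_at_mean}
        row.update({f"mean_{k}": v for k, v in g.mean_covariates.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PSA


@dataclass
class PSAResult:
    point: ModelOutputs
    draws: pd.DataFrame  # one row per iteration, columns = output fields
    ci_lower: pd.Series
    ci_upper: pd.Series


def _nearest_psd(v: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(0.5 * (v + v.T))
    if vals.min() >= 0:
        return v
    log.warning("vcov not positive semi-definite (min eig %.3e); clipping", vals.min())
    vals = np.clip(vals, 0.0, None)
    return (vecs * vals) @ vecs.T


def _mvn_draw(rng: np.random.Generator, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    return rng.multivariate_normal(mean, _nearest_psd(cov), method="eigh")


def _draw_fit(fit: SurvivalFit, rng: np.random.Generator) -> SurvivalFit:
    theta = fit.coef.to_numpy(float).tolist()
    if fit.family != "exponential":
        theta.append(np.log(fit.sigma))
    if fit.family == "generalised_gamma":
        theta.append(fit.q)
    theta = np.asarray(theta)
    vcov = np.asarray(fit.vcov, dtype=float)
    if vcov.shape != (len(theta), len(theta)):
        raise ValueError(f"vcov shape mismatch for endpoint {fit.endpoint!r}")
    if np.all(vcov == 0):
        return fit
    draw = _mvn_draw(rng, theta, vcov)
    p = len(fit.coef)
    new = replace(fit, coef=pd.Series(draw[:p], index=fit.coef.index))
    if fit.family != "exponential":
        new = replace(new, sigma=float(np.exp(draw[p])))
    if fit.family == "generalised_gamma":
        new = replace(new, q=float(draw[p + 1]))
    return new


def draw_equation_set(equations: RiskEquationSet, rng: np.random.Generator) -> RiskEquationSet:
    return replace(
        equations,
        primary={k: _draw_fit(f, rng) for k, f in equations.primary.items()},
        post={k: _draw_fit(f, rng) for k, f in equations.post.items()},
    )


def draw_cost_model(cost_model: CostModel, rng: np.random.Generator) -> CostModel:
    comps = {}
    for name, comp in cost_model.components.items():
        if np.all(comp.vcov == 0):
            comps[name] = comp
            continue
        draw = _mvn_draw(rng, comp.coef.to_numpy(float), comp.vcov)
        comps[name] = replace(comp, coef=pd.Series(draw, index=comp.coef.index))
    return replace(cost_model, components=comps)


def run_psa(
    profile: pd.Series,
    equations: RiskEquationSet,
    cost_model: CostModel,
    utilities: UtilityCatalogue,
    n_iter: int = 1000,
    seed: int = 0,
    treatment: TreatmentEffect | None = None,
    discount_rate: float = 0.035,
    horizon_years: float = 60.0,
    ci_level: float = 0.95,
) -> PSAResult:
    """Monte Carlo parameter uncertainty propagated through the model."""
    rng = np.random.default_rng(seed)
    _, point = run_cohort(
        profile, equations, cost_model, utilities,
        discount_rate=discount_rate, treatment=treatment, horizon_years=horizon_years,
    )
    rows = []
    for _ in range(n_iter):
        eq_i = draw_equation_set(equations, rng)
        cm_i = draw_cost_model(cost_model, rng)
        ut_i = utilities.perturbed(rng)
        _, out = run_cohort(
            profile, eq_i, cm_i, ut_i,
            discount_rate=discount_rate, treatment=treatment, horizon_years=horizon_years,
        )
        rows.append(out.to_dict())
    draws = pd.DataFrame(rows)
    alpha = (1.0 - ci_level) / 2.0
    return PSAResult(
        point=point,
        draws=draws,
        ci_lower=draws.quantile(alpha),
        ci_upper=draws.quantile(1.0 - alpha),
    )
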