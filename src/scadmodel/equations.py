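"""The 11-equation risk set driving disease progression.

Five primary endpoints (non-fatal MI, ischaemic stroke, haemorrhagic
stroke, CVD death, non-CVD death) are modelled on time since cohort entry
with the full baseline covariate design.  Six subsequent-mortality
endpoints (CVD and non-CVD death after each non-fatal event) reset the
clock at the event and use only sex and age at the event.  Beyond the
splice time (default 10 years of follow-up) non-CVD mortality comes from
the national life table instead of the fitted equation.

Group-mean evaluation: a profile may carry fractional indicator values
(e.g. ``sex_female = 0.44``); the life-table hazard is then the
sex-fraction-weighted blend of the male and female rates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scadmodel import families as _families
from scadmodel.covariates import design_matrix, design_row
from scadmodel.lifetable import LifeTable
from scadmodel.survival import ConvergenceError, SurvivalFit, fit_parametric, select_best_family
from scadmodel.transitions import PRIMARY_CAUSES, build_cifs

log = logging.getLogger(__name__)

NONFATAL_EVENTS = ("mi", "ischaemic_stroke", "haemorrhagic_stroke")
POST_CAUSES = ("cvd_death", "noncvd_death")
DEFAULT_SPLICE_TIME = 10.0  # years of follow-up covered by the fitted equations


@dataclass
class RiskEquationSet:
    """Five primary + six post-event fitted equations plus the life table."""

    primary: dict[str, SurvivalFit]
    post: dict[tuple[str, str], SurvivalFit]
    life_table: LifeTable
    splice_time: float = DEFAULT_SPLICE_TIME

    def __post_init__(self):
        if set(self.primary) != set(PRIMARY_CAUSES):
            raise ValueError(f"primary fits must cover {PRIMARY_CAUSES}")
        expected = {(e, c) for e in NONFATAL_EVENTS for c in POST_CAUSES}
        if set(self.post) != expected:
            raise ValueError("post-event fits must cover the six event/cause pairs")

    @property
    def n_equations(self) -> int:
        return len(self.primary) + len(self.post)

    def _blended_lifetable_hazard(self, sex_female: float, ages) -> np.ndarray:
        # 0 * inf guard: a zero sex weight must not poison the terminal row
        hm = self.life_table.hazard("male", ages)
        hf = self.life_table.hazard("female", ages)
        out = np.zeros_like(hm, dtype=float)
        if sex_female < 1.0:
            out = out + (1.0 - sex_female) * hm
        if sex_female > 0.0:
            out = out + sex_female * hf
        return out

    def primary_hazard_fns(self, profile: pd.Series) -> dict[str, callable]:
        """Cause-specific hazards h_k(t since entry) for one (possibly
        group-mean) profile, with the life-table splice on non-CVD death."""
        x = profile if "sex_female" in profile.index else design_row(profile)
        fns = {c: self.primary[c].hazard_fn(x) for c in PRIMARY_CAUSES if c != "noncvd_death"}
        param = self.primary["noncvd_death"].hazard_fn(x)
        age0 = float(x["age_entry"])
        sexf = float(x["sex_female"])
        splice = self.splice_time

        def noncvd(t, _param=param):
            t = np.asarray(t, dtype=float)
            h = np.asarray(_param(np.maximum(t, 1e-12)), dtype=float)
            beyond = t >= splice
            if np.any(beyond):
                h = np.where(
                    beyond,
                    self._blended_lifetable_hazard(sexf, np.floor(age0 + t)),
                    h,
                )
            return h

        fns["noncvd_death"] = noncvd
        return fns

    def post_event_hazard_fns(
        self, event: str, sex_female: float, age_at_event: float, t_event: float
    ) -> dict[str, callable]:
        """Two-cause hazards h(s since event); non-CVD spliced once total
        follow-up ``t_event + s`` passes the splice time."""
        x = pd.Series({"sex_female": sex_female, "age_event": age_at_event})
        fns = {"cvd_death": self.post[(event, "cvd_death")].hazard_fn(x)}
        param = self.post[(event, "noncvd_death")].hazard_fn(x)
        splice, sexf = self.splice_time, sex_female

        def noncvd(s, _param=param):
            s = np.asarray(s, dtype=float)
            h = np.asarray(_param(np.maximum(s, 1e-12)), dtype=float)
            beyond = t_event + s >= splice
            if np.any(beyond):
                h = np.where(
                    beyond,
                    self._blended_lifetable_hazard(sexf, np.floor(age_at_event + s)),
                    h,
                )
            return h

        fns["noncvd_death"] = noncvd
        return fns

    def to_dict(self) -> dict:
        return {
            "primary": {k: f.to_dict() for k, f in self.primary.items()},
            "post": {f"{e}|{c}": f.to_dict() for (e, c), f in self.post.items()},
            "life_table": self.life_table.table.to_dict(orient="list"),
            "splice_time": self.splice_time,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskEquationSet":
        post = {}
        for key, fd in d["post"].items():
            e, c = key.split("|")
            post[(e, c)] = SurvivalFit.from_dict(fd)
        return cls(
            primary={k: SurvivalFit.from_dict(v) for k, v in d["primary"].items()},
            post=post,
            life_table=LifeTable(pd.DataFrame(d["life_table"])),
            splice_time=float(d["splice_time"]),
        )


def spliced_noncvd_hazard(eq_set: RiskEquationSet, profile: pd.Series, t) -> np.ndarray:
    """Non-CVD death hazard at time ``t`` since entry, life-table spliced."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    return eq_set.primary_hazard_fns(profile)["noncvd_death"](np.maximum(t, 1e-12))


def fit_equation_set(
    cohort: pd.DataFrame,
    histories: pd.DataFrame,
    life_table: LifeTable,
    candidate_families: tuple[str, ...] = tuple(_families.FAMILIES),
    splice_time: float = DEFAULT_SPLICE_TIME,
    min_post_events: int = 5,
) -> RiskEquationSet:
    """Fit all 11 equations with per-endpoint AIC family selection.

    Post-event mortality endpoints observing fewer than ``min_post_events``
    deaths are estimated on the pool of all non-fatal events for that
    cause (sparse-data fallback, logged), mirroring how rare endpoints
    must borrow strength in small cohorts.
    """
    merged = histories.merge(cohort, on="patient_id", how="inner", validate="1:1")
    if len(merged) != len(histories):
        raise ValueError("histories contain patients absent from the cohort")
    x_full = design_matrix(merged)
    times = np.maximum(merged["time_first_event"].to_numpy(float), 1e-6)

    primary: dict[str, SurvivalFit] = {}
    for cause in PRIMARY_CAUSES:
        events = (merged["first_event"] == cause).astype(int).to_numpy()
        primary[cause] = _fit_with_selection(
            times, events, x_full, candidate_families, endpoint=cause
        )

    post_data = {}
    for event in NONFATAL_EVENTS:
        sub = merged[merged["first_event"] == event]
        x_post = pd.DataFrame(
            {
                "sex_female": (sub["sex"] == "female").astype(float).to_numpy(),
                "age_event": (sub["age_entry"] + sub["time_first_event"]).to_numpy(float),
            }
        )
        t_post = np.maximum(sub["time_post_event"].to_numpy(float), 1e-6)
        post_data[event] = (t_post, x_post, sub["post_event_outcome"].to_numpy())

    pooled_t = np.concatenate([post_data[e][0] for e in NONFATAL_EVENTS])
    pooled_x = pd.concat([post_data[e][1] for e in NONFATAL_EVENTS], ignore_index=True)
    pooled_o = np.concatenate([post_data[e][2] for e in NONFATAL_EVENTS])

    post: dict[tuple[str, str], SurvivalFit] = {}
    for event in NONFATAL_EVENTS:
        t_post, x_post, outcomes = post_data[event]
        for cause in POST_CAUSES:
            ev = (outcomes == cause).astype(int)
            if ev.sum() < min_post_events:
                log.warning(
                    "only %d %s events after %s; pooling across non-fatal events",
                    ev.sum(), cause, event,
                )
                t_use, x_use, ev_use = pooled_t, pooled_x, (pooled_o == cause).astype(int)
            else:
                t_use, x_use, ev_use = t_post, x_post, ev
            post[(event, cause)] = _fit_with_selection(
                t_use, ev_use, x_use, candidate_families, endpoint=f"{cause}_after_{event}"
            )

    return RiskEquationSet(primary=primary, post=post, life_table=life_table,
                           splice_time=splice_time)


def _fit_with_selection(times, events, covariates, candidate_families, endpoint):
    fits = []
    for fam in candidate_families:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits.append(fit_parametric(times, events, covariates, fam, endpoint=endpoint))
        except (ConvergenceError, ValueError) as exc:
            if "zero events" in str(exc):
                raise
            log.warning("family %s failed for endpoint %s: %s", fam, endpoint, exc)
    if not fits:
        raise ConvergenceError(f"no family converged for endpoint {endpoint!r}")
    return select_best_family(fits)


RISK_HORIZON_YEARS = 5.0
_RISK_N_SUB = 512  # sub-steps over the 5-year window for the risk score


def predict_5yr_composite_risk(eq_set: RiskEquationSet, profile: pd.Series) -> float:
    """P(at least one CVD event within 5 years) under competing non-CVD death.

    The composite combines the four CVD cumulative incidence functions
    (MI, ischaemic stroke, haemorrhagic stroke, CVD death) at 5 years.
    """
    fns = eq_set.primary_hazard_fns(profile)
    cifs = build_cifs(fns, n_cycles=1, cycle_length=RISK_HORIZON_YEARS, n_sub=_RISK_N_SUB)
    return float(sum(cifs.cif[c][-1] for c in PRIMARY_CAUSES if c != "noncvd_death"))


def predict_5yr_composite_risk_cohort(
    eq_set: RiskEquationSet,
    cohort: pd.DataFrame,
    n_steps: int = 128,
    chunk: int = 4096,
) -> np.ndarray:
    """Vectorised composite 5-year risk for every cohort member.

    Uses the same piecewise-constant midpoint integration as
    :func:`scadmodel.transitions.build_cifs` on an ``n_steps`` grid.
    """
    x = design_matrix(cohort)
    dt = RISK_HORIZON_YEARS / n_steps
    mid = (np.arange(n_steps) + 0.5) * dt
    out = np.empty(len(x))
    for lo in range(0, len(x), chunk):
        xc = x.iloc[lo : lo + chunk]
        n = len(xc)
        h = np.zeros((len(PRIMARY_CAUSES), n, n_steps))
        for i, cause in enumerate(PRIMARY_CAUSES):
            fit = eq_set.primary[cause]
            mu = np.asarray(fit.location(xc), dtype=float)[:, None]
            h[i] = _families.hazard(mid[None, :], mu, fit.sigma, fit.q, fit.family)
        # life-table splice irrelevant inside 5 years (splice_time >= 10 default)
        if eq_set.splice_time < RISK_HORIZON_YEARS:
            raise NotImplementedError("vectorised risk assumes splice_time >= 5 years")
        h_tot = h.sum(axis=0)
        s = np.exp(-dt * np.cumsum(h_tot, axis=1))
        s_start = np.concatenate([np.ones((n, 1)), s[:, :-1]], axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(h_tot > 0, h / np.where(h_tot > 0, h_tot, 1.0), 0.0)
        mass = frac * (s_start - s)[None, :, :]
        cvd_idx = [i for i, c in enumerate(PRIMARY_CAUSES) if c != "noncvd_death"]
        out[lo : lo + n] = mass[cvd_idx].sum(axis=(0, 2))
    return out
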