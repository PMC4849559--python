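"""Six-state Markov cohort engine and microsimulation oracle.

States: stable, post-MI, post-ischaemic-stroke, post-haemorrhagic-stroke,
CVD death, non-CVD death.  The cohort progresses in 90-day cycles until
the live mass is extinguished or an attained-age/horizon cap binds.

Because post-event mortality depends on time since the event (clock reset
at the event) the model is semi-Markov: post-event occupancy is tracked in
tunnels indexed by entry cycle.  Accrual conventions (documented, no
half-cycle correction):

* costs accrue per full cycle on start-of-cycle occupancy (matching the
  90-day cost-panel convention); life years and QALYs accrue the exact
  expected within-cycle person-time of each state;
* a transition during cycle ``j`` enters its post-event tunnel at the
  start of cycle ``j+1``, whose first cycle carries the acute cost uplift
  and acute utility decrement;
* discounting uses cycle-start time by default (mid-cycle optional);
* the final cycle is weighted so accruals stop exactly at the horizon.

The microsimulation oracle samples individual trajectories from exactly
the per-cycle transition probabilities the cohort engine integrates,
providing an independent Monte Carlo route to every output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from scadmodel import families as _families
from scadmodel.costs import CostModel, UtilityCatalogue
from scadmodel.covariates import design_row
from scadmodel.equations import RiskEquationSet
from scadmodel.transitions import (
    CYCLE_LENGTH_YEARS,
    EVENT_STATE,
    PRIMARY_CAUSES,
    STATES,
    apply_treatment,
    build_cifs,
)

log = logging.getLogger(__name__)

DEFAULT_DISCOUNT_RATE = 0.035
DEFAULT_HORIZON_YEARS = 60.0
AGE_CAP = 110.0
EXTINCTION_TOL = 1e-9

_NONFATAL = tuple(EVENT_STATE)  # mi, ischaemic_stroke, haemorrhagic_stroke


@dataclass
class TreatmentEffect:
    """A hypothetical therapy scaling CVD hazards by (1 - rho)."""

    rho: float
    treat_haemorrhagic: bool = True
    treat_post_event: bool = True

    def __post_init__(self):
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")


@dataclass
class ModelOutputs:
    """Lifetime outputs of one model run (the per-group results bundle)."""

    life_years: float
    discounted_life_years: float
    qalys: float
    discounted_qalys: float
    total_costs: float
    discounted_total_costs: float
    cvd_costs: float
    discounted_cvd_costs: float
    time_to_first_event: float
    p_first_mi: float
    p_first_ischaemic_stroke: float
    p_first_haemorrhagic_stroke: float
    p_first_cvd_death: float
    p_first_noncvd_death: float
    cvd_mortality_pct: float
    noncvd_mortality_pct: float

    def to_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in dc_fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelOutputs":
        return cls(**{f.name: float(d[f.name]) for f in dc_fields(cls)})

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in dc_fields(cls)]


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and accruals."""

    times: np.ndarray                    # cycle-start times, years
    occupancy: np.ndarray                # (n_cycles+1, 6) over STATES
    cycle_total_cost: np.ndarray
    cycle_cvd_cost: np.ndarray
    cycle_utility_time: np.ndarray       # utility-weighted years accrued per cycle
    discount_factors: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "time", self.times)
        return df


class _CompiledModel:
    """Per-profile transition probabilities, costs and utilities.

    Shared verbatim by the deterministic cohort run and the
    microsimulation oracle so both integrate the same model.
    """

    def __init__(
        self,
        profile: pd.Series,
        equations: RiskEquationSet,
        cost_model: CostModel,
        utilities: UtilityCatalogue,
        discount_rate: float = DEFAULT_DISCOUNT_RATE,
        treatment: TreatmentEffect | None = None,
        horizon_years: float = DEFAULT_HORIZON_YEARS,
        n_sub: int = 16,
        post_n_sub: int = 8,
        mid_cycle_discount: bool = False,
    ):
        x = profile if "sex_female" in getattr(profile, "index", []) else design_row(profile)
        self.x = x
        self.dt = CYCLE_LENGTH_YEARS
        self.age0 = float(x["age_entry"])
        self.sexf = float(x["sex_female"])
        self.horizon = float(min(horizon_years, AGE_CAP - self.age0))
        if self.horizon <= 0:
            raise ValueError("profile age is at or beyond the attained-age cap")
        self.n_cycles = int(np.ceil(self.horizon / self.dt - 1e-9))
        c = self.n_cycles
        t_start = np.arange(c) * self.dt
        #: fraction of each cycle lying inside the horizon
        self.cycle_weight = np.minimum(self.dt, self.horizon - t_start) / self.dt

        hazards = equations.primary_hazard_fns(x)
        if treatment is not None:
            hazards = apply_treatment(hazards, treatment.rho, treatment.treat_haemorrhagic)
        self.cifs = build_cifs(hazards, c, self.dt, n_sub)
        s = self.cifs.survival
        with np.errstate(invalid="ignore", divide="ignore"):
            self.p_stay_stable = np.where(s[:-1] > 0, s[1:] / np.where(s[:-1] > 0, s[:-1], 1.0), 1.0)
            self.p_stable_to = {
                cause: np.where(
                    s[:-1] > 0, np.diff(f) / np.where(s[:-1] > 0, s[:-1], 1.0), 0.0
                )
                for cause, f in self.cifs.cif.items()
            }
            # expected person-time in the cycle given event-free at its start
            self.pt_stable = np.where(
                s[:-1] > 0, self.cifs.person_time / np.where(s[:-1] > 0, s[:-1], 1.0), 0.0
            )

        # post-event tunnels: entry cycle je = 1..c; stage index m = j - je.
        # Vectorised over entry cycles: hazards depend on (sex, age at
        # event, time since event), with the non-CVD splice keyed to total
        # follow-up t_event + s.
        post_rho = treatment.rho if (treatment is not None and treatment.treat_post_event) else 0.0
        je_idx = np.arange(c + 1)
        age_event = self.age0 + je_idx * self.dt
        t_event = je_idx * self.dt
        dtf = self.dt / post_n_sub
        s_mid = (np.arange(c * post_n_sub) + 0.5) * dtf
        total_t = t_event[:, None] + s_mid[None, :]
        beyond = total_t >= equations.splice_time
        lt_h = equations._blended_lifetable_hazard(self.sexf, np.floor(self.age0 + total_t))
        self.p_die_post = {}  # event -> (cause -> (c+1, c) matrix over [je, m])
        self.pt_post = {}  # event -> (c+1, c) expected person-time per cycle
        for event in _NONFATAL:
            h = {}
            for cause in ("cvd_death", "noncvd_death"):
                fit = equations.post[(event, cause)]
                mu = (
                    float(fit.coef.get("intercept", 0.0))
                    + float(fit.coef.get("sex_female", 0.0)) * self.sexf
                    + float(fit.coef.get("age_event", 0.0)) * age_event
                )
                h[cause] = _families.hazard(s_mid[None, :], mu[:, None], fit.sigma,
                                            fit.q, fit.family)
            h["noncvd_death"] = np.where(beyond, lt_h, h["noncvd_death"])
            if post_rho > 0:
                h["cvd_death"] = (1.0 - post_rho) * h["cvd_death"]
            self.p_die_post[event], self.pt_post[event] = _cycle_death_probs(
                h, dtf, post_n_sub, c
            )

        # accrual arrays ------------------------------------------------
        ages_start = self.age0 + t_start
        self.stable_cost = _cost_series(cost_model, x, "stable", None, ages_start)
        self.stable_util = _utility_series(utilities, self.sexf, "stable", None, ages_start)

        # post-event: matrix over [je, m]; age = age0 + (je + m) dt
        self.post_cost = {}
        self.post_util = {}
        m_idx = np.arange(c)
        for event in _NONFATAL:
            state = EVENT_STATE[event]
            je_idx = np.arange(c + 1)
            ages = self.age0 + (je_idx[:, None] + m_idx[None, :]) * self.dt
            self.post_cost[event] = _cost_matrix(cost_model, x, state, m_idx, ages)
            self.post_util[event] = _utility_matrix(utilities, self.sexf, state, m_idx, ages)

        t_disc = t_start + (self.dt / 2.0 if mid_cycle_discount else 0.0)
        self.disc = (1.0 + discount_rate) ** (-t_disc)


def _cycle_death_probs(h: dict, dtf: float, n_sub: int, c: int) -> tuple[dict, np.ndarray]:
    """Conditional per-cycle death probabilities from fine-grid hazards.

    ``h`` maps cause -> (R, c*n_sub) hazard matrix; returns (cause ->
    (R, c) probability of dying of that cause during cycle m given alive
    at its start, conditional expected person-time in that cycle (R, c)).
    Same piecewise-constant composition as ``build_cifs``.
    """
    causes = tuple(h)
    hs = np.minimum(np.stack([h[k] for k in causes]), 1e12)  # (K, R, M)
    h_tot = hs.sum(axis=0)
    inf_mask = ~np.isfinite(h_tot)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        frac = np.where(h_tot > 0, hs / np.where(h_tot > 0, h_tot, 1.0), 0.0)
    if inf_mask.any():
        n_inf = (~np.isfinite(hs)).sum(axis=0)
        sel = np.broadcast_to(inf_mask, hs.shape)
        frac[sel] = (~np.isfinite(hs))[sel] / np.broadcast_to(n_inf, hs.shape)[sel]
    step = np.exp(-np.where(inf_mask, np.inf, h_tot) * dtf)
    s_fine = np.cumprod(step, axis=-1)
    s_prev = np.concatenate([np.ones((*s_fine.shape[:-1], 1)), s_fine[..., :-1]], axis=-1)
    mass = frac * (s_prev - s_fine)  # (K, R, M)
    per_cycle = mass.reshape(*mass.shape[:-1], c, n_sub).sum(axis=-1)
    s_start = s_prev[..., ::n_sub]  # (R, c) survival at cycle starts
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(s_start > 0, per_cycle / np.where(s_start > 0, s_start, 1.0), 0.0)
        pt_fine = np.where(
            h_tot > 0,
            s_prev * (-np.expm1(-np.where(inf_mask, 1.0, h_tot) * dtf))
            / np.where(h_tot > 0, h_tot, 1.0),
            s_prev * dtf,
        )
    pt_fine[inf_mask] = 0.0
    pt_cycle = pt_fine.reshape(*pt_fine.shape[:-1], c, n_sub).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pt_cond = np.where(s_start > 0, pt_cycle / np.where(s_start > 0, s_start, 1.0), 0.0)
    return {k: p[i] for i, k in enumerate(causes)}, pt_cond


def _cost_series(cost_model, x, state, cse, ages):
    """(2, n) expected (total, cvd) per-cycle costs for a live state."""
    ages = np.asarray(ages, dtype=float)
    total = np.zeros((2, len(ages)))
    for ci, (name, comp) in enumerate(cost_model.components.items()):
        lp = np.full(len(ages), comp.coef.get("intercept", 0.0))
        for fname, b in comp.coef.items():
            if fname == "intercept":
                continue
            if fname == "current_age":
                lp = lp + b * ages
            elif fname == f"state_{state}":
                lp = lp + b
            elif fname.startswith("state_") or fname in ("acute", "band_early"):
                continue  # stable state: no event indicators
            else:
                lp = lp + b * float(x[fname])
        val = np.exp(lp)
        total[0] += val
        if name == "cvd":
            total[1] = val
    return total


def _cost_matrix(cost_model, x, state, m_idx, ages):
    """(2, n_je, n_m) expected costs for a post-event tunnel, vectorised."""
    out = np.zeros((2, *ages.shape))
    acute = (m_idx == 0).astype(float)
    band = ((m_idx >= 1) & (m_idx <= 4)).astype(float)
    for ci, (name, comp) in enumerate(cost_model.components.items()):
        lp = np.full(ages.shape, comp.coef.get("intercept", 0.0))
        for fname, b in comp.coef.items():
            if fname == "intercept":
                continue
            if fname == "current_age":
                lp = lp + b * ages
            elif fname == f"state_{state}":
                lp = lp + b
            elif fname.startswith("state_"):
                continue
            elif fname == "acute":
                lp = lp + b * acute[None, :]
            elif fname == "band_early":
                lp = lp + b * band[None, :]
            else:
                lp = lp + b * float(x[fname])
        val = np.exp(lp)
        out[0] += val
        if name == "cvd":
            out[1] = val
    return out


def _base_utility_vec(catalogue: UtilityCatalogue, sexf: float, ages: np.ndarray) -> np.ndarray:
    out = np.zeros_like(ages, dtype=float)
    for sex, weight in (("male", 1.0 - sexf), ("female", sexf)):
        if weight == 0.0:
            continue
        sub = catalogue.bands[catalogue.bands["sex"] == sex]
        lo = sub["age_lo"].to_numpy(float)
        hi = sub["age_hi"].to_numpy(float)
        u = sub["base_utility"].to_numpy(float)
        a = np.clip(ages, lo.min(), hi.max())  # nearest-band fallback at the edges
        vals = np.zeros_like(a)
        for l, h, uu in zip(lo, hi, u):
            vals = np.where((a >= l) & (a <= h), uu, vals)
        out = out + weight * vals
    return out


def _utility_series(catalogue, sexf, state, cse, ages):
    u = _base_utility_vec(catalogue, sexf, np.asarray(ages, float)) * catalogue.condition_multiplier
    if state != "stable":
        u = u * catalogue.event_multipliers[state]
    return u


def _utility_matrix(catalogue, sexf, state, m_idx, ages):
    u = _utility_series(catalogue, sexf, state, None, ages)
    acute = np.where(m_idx == 0, catalogue.acute_multiplier, 1.0)
    return u * acute[None, :]


def run_cohort(
    profile: pd.Series,
    equations: RiskEquationSet,
    cost_model: CostModel,
    utilities: UtilityCatalogue,
    discount_rate: float = DEFAULT_DISCOUNT_RATE,
    treatment: TreatmentEffect | None = None,
    horizon_years: float = DEFAULT_HORIZON_YEARS,
    n_sub: int = 16,
    mid_cycle_discount: bool = False,
    _compiled: "_CompiledModel | None" = None,
) -> tuple[CohortTrace, ModelOutputs]:
    """Deterministic cohort run for one (possibly group-mean) profile."""
    cm = _compiled or _CompiledModel(
        profile, equations, cost_model, utilities, discount_rate, treatment,
        horizon_years, n_sub=n_sub, mid_cycle_discount=mid_cycle_discount,
    )
    c, dt = cm.n_cycles, cm.dt
    occ = np.zeros((c + 1, len(STATES)))
    occ[0, 0] = 1.0
    tun = {e: np.zeros(c + 2) for e in _NONFATAL}  # mass by entry cycle je
    dead = {"cvd_death": 0.0, "noncvd_death": 0.0}

    cyc_cost = np.zeros(c)
    cyc_cvd = np.zeros(c)
    cyc_util = np.zeros(c)   # utility-weighted person-time, years
    cyc_pt = np.zeros(c)     # person-time, years

    state_idx = {s: i for i, s in enumerate(STATES)}
    for j in range(c):
        w = cm.cycle_weight[j]
        stable = occ[j, 0]
        # costs on start-of-cycle occupancy (panel convention); life years
        # and QALYs on expected within-cycle person-time
        cost_j = stable * cm.stable_cost[0, j]
        cvd_j = stable * cm.stable_cost[1, j]
        pt_j = stable * cm.pt_stable[j]
        util_j = stable * cm.stable_util[j] * cm.pt_stable[j]
        for e in _NONFATAL:
            jes = np.arange(1, j + 1)
            if len(jes) == 0:
                continue
            mass = tun[e][jes]
            ms = j - jes
            cost_j += float(mass @ cm.post_cost[e][0, jes, ms])
            cvd_j += float(mass @ cm.post_cost[e][1, jes, ms])
            pt_post = cm.pt_post[e][jes, ms]
            pt_j += float(mass @ pt_post)
            util_j += float(mass @ (cm.post_util[e][jes, ms] * pt_post))
        cyc_cost[j] = cost_j * w
        cyc_cvd[j] = cvd_j * w
        cyc_util[j] = util_j * w
        cyc_pt[j] = pt_j * w

        # transitions
        new_tun_mass = {}
        for cause in PRIMARY_CAUSES:
            moved = stable * cm.p_stable_to[cause][j]
            if cause in EVENT_STATE:
                new_tun_mass[cause] = moved
            else:
                dead[cause] += moved
        for e in _NONFATAL:
            jes = np.arange(1, j + 1)
            if len(jes) > 0:
                mass = tun[e][jes]
                ms = j - jes
                d_cvd = mass * cm.p_die_post[e]["cvd_death"][jes, ms]
                d_ncvd = mass * cm.p_die_post[e]["noncvd_death"][jes, ms]
                dead["cvd_death"] += float(d_cvd.sum())
                dead["noncvd_death"] += float(d_ncvd.sum())
                tun[e][jes] = mass - d_cvd - d_ncvd
            tun[e][j + 1] = new_tun_mass[e]
        occ[j + 1, 0] = stable * cm.p_stay_stable[j]
        for e in _NONFATAL:
            occ[j + 1, state_idx[EVENT_STATE[e]]] = tun[e][1 : j + 2].sum()
        occ[j + 1, state_idx["cvd_death"]] = dead["cvd_death"]
        occ[j + 1, state_idx["noncvd_death"]] = dead["noncvd_death"]

    residual = 1.0 - dead["cvd_death"] - dead["noncvd_death"]
    if residual > EXTINCTION_TOL:
        log.warning(
            "horizon cap at %.1f years reached with live mass %.3e still in the model",
            cm.horizon, residual,
        )

    disc = cm.disc
    outputs = ModelOutputs(
        life_years=float(cyc_pt.sum()),
        discounted_life_years=float(cyc_pt @ disc),
        qalys=float(cyc_util.sum()),
        discounted_qalys=float(cyc_util @ disc),
        total_costs=float(cyc_cost.sum()),
        discounted_total_costs=float(cyc_cost @ disc),
        cvd_costs=float(cyc_cvd.sum()),
        discounted_cvd_costs=float(cyc_cvd @ disc),
        time_to_first_event=float(cm.cifs.person_time @ cm.cycle_weight),
        p_first_mi=float(cm.cifs.cif["mi"][-1]),
        p_first_ischaemic_stroke=float(cm.cifs.cif["ischaemic_stroke"][-1]),
        p_first_haemorrhagic_stroke=float(cm.cifs.cif["haemorrhagic_stroke"][-1]),
        p_first_cvd_death=float(cm.cifs.cif["cvd_death"][-1]),
        p_first_noncvd_death=float(cm.cifs.cif["noncvd_death"][-1]),
        cvd_mortality_pct=100.0 * dead["cvd_death"],
        noncvd_mortality_pct=100.0 * dead["noncvd_death"],
    )
    trace = CohortTrace(
        times=np.arange(c + 1) * dt,
        occupancy=occ,
        cycle_total_cost=cyc_cost,
        cycle_cvd_cost=cyc_cvd,
        cycle_utility_time=cyc_util,
        discount_factors=disc,
    )
    return trace, outputs


def microsim_oracle(
    profile: pd.Series,
    equations: RiskEquationSet,
    cost_model: CostModel,
    utilities: UtilityCatalogue,
    n: int = 10_000,
    seed: int = 0,
    discount_rate: float = DEFAULT_DISCOUNT_RATE,
    treatment: TreatmentEffect | None = None,
    horizon_years: float = DEFAULT_HORIZON_YEARS,
    n_sub: int = 16,
    mid_cycle_discount: bool = False,
) -> tuple[ModelOutputs, ModelOutputs]:
    """Individual-level Monte Carlo oracle.

    Samples ``n`` trajectories cycle by cycle from the compiled per-cycle
    transition probabilities and returns ``(means, standard_errors)`` as
    two :class:`ModelOutputs`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cm = _CompiledModel(
        profile, equations, cost_model, utilities, discount_rate, treatment,
        horizon_years, n_sub=n_sub, mid_cycle_discount=mid_cycle_discount,
    )
    c = cm.n_cycles
    disc = cm.disc

    state = np.zeros(n, dtype=np.int8)  # indices into STATES
    entry_cycle = np.zeros(n, dtype=np.int32)
    acc = {k: np.zeros(n) for k in (
        "ly", "dly", "qaly", "dqaly", "cost", "dcost", "cvd", "dcvd", "tfe")}
    first_cause = np.full(n, -1, dtype=np.int8)  # index into PRIMARY_CAUSES

    cause_state = np.array([STATES.index(EVENT_STATE.get(cs, cs)) for cs in PRIMARY_CAUSES])
    stable_cum = np.cumsum(
        np.column_stack([cm.p_stable_to[cs] for cs in PRIMARY_CAUSES]), axis=1
    )
    for j in range(c):
        alive = state < 4
        if not alive.any():
            break
        w = cm.cycle_weight[j]
        # accruals: costs full-cycle at start-of-cycle state; life years
        # and QALYs as expected within-cycle person-time (matches cohort)
        st = state == 0
        if st.any():
            pt = cm.pt_stable[j] * w
            acc["ly"][st] += pt
            acc["dly"][st] += pt * disc[j]
            acc["qaly"][st] += cm.stable_util[j] * pt
            acc["dqaly"][st] += cm.stable_util[j] * pt * disc[j]
            acc["cost"][st] += cm.stable_cost[0, j] * w
            acc["dcost"][st] += cm.stable_cost[0, j] * w * disc[j]
            acc["cvd"][st] += cm.stable_cost[1, j] * w
            acc["dcvd"][st] += cm.stable_cost[1, j] * w * disc[j]
            acc["tfe"][st] += pt
        for si, e in zip((1, 2, 3), _NONFATAL):
            sel = state == si
            if not sel.any():
                continue
            je = entry_cycle[sel]
            m = j - je
            pt = cm.pt_post[e][je, m] * w
            acc["ly"][sel] += pt
            acc["dly"][sel] += pt * disc[j]
            u = cm.post_util[e][je, m]
            acc["qaly"][sel] += u * pt
            acc["dqaly"][sel] += u * pt * disc[j]
            ct = cm.post_cost[e][0, je, m] * w
            cv = cm.post_cost[e][1, je, m] * w
            acc["cost"][sel] += ct
            acc["dcost"][sel] += ct * disc[j]
            acc["cvd"][sel] += cv
            acc["dcvd"][sel] += cv * disc[j]

        # transitions
        u = rng.random(n)
        if st.any():
            us = u[st]
            dest = np.searchsorted(stable_cum[j], us)  # 5 = stay
            moved = dest < len(PRIMARY_CAUSES)
            idx = np.flatnonzero(st)
            fc = first_cause[idx]
            fc[moved] = dest[moved]
            first_cause[idx] = fc
            new_state = np.where(moved, cause_state[np.minimum(dest, 4)], 0).astype(np.int8)
            state[idx] = new_state
            went_post = moved & (new_state >= 1) & (new_state <= 3)
            entry_cycle[idx[went_post]] = j + 1
        for si, e in zip((1, 2, 3), _NONFATAL):
            sel = np.flatnonzero(state == si)
            sel = sel[entry_cycle[sel] <= j]  # exclude this cycle's entrants
            if len(sel) == 0:
                continue
            je = entry_cycle[sel]
            m = j - je
            p_cvd = cm.p_die_post[e]["cvd_death"][je, m]
            p_ncvd = cm.p_die_post[e]["noncvd_death"][je, m]
            uu = u[sel]
            die_cvd = uu < p_cvd
            die_ncvd = (~die_cvd) & (uu < p_cvd + p_ncvd)
            state[sel[die_cvd]] = STATES.index("cvd_death")
            state[sel[die_ncvd]] = STATES.index("noncvd_death")

    per_ind = {
        "life_years": acc["ly"],
        "discounted_life_years": acc["dly"],
        "qalys": acc["qaly"],
        "discounted_qalys": acc["dqaly"],
        "total_costs": acc["cost"],
        "discounted_total_costs": acc["dcost"],
        "cvd_costs": acc["cvd"],
        "discounted_cvd_costs": acc["dcvd"],
        "time_to_first_event": acc["tfe"],
        "p_first_mi": (first_cause == 0).astype(float),
        "p_first_ischaemic_stroke": (first_cause == 1).astype(float),
        "p_first_haemorrhagic_stroke": (first_cause == 2).astype(float),
        "p_first_cvd_death": (first_cause == 3).astype(float),
        "p_first_noncvd_death": (first_cause == 4).astype(float),
        "cvd_mortality_pct": 100.0 * (state == STATES.index("cvd_death")).astype(float),
        "noncvd_mortality_pct": 100.0 * (state == STATES.index("noncvd_death")).astype(float),
    }
    means = ModelOutputs(**{k: float(np.mean(v)) for k, v in per_ind.items()})
    ses = ModelOutputs(
        **{k: float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
           for k, v in per_ind.items()}
    )
    return means, ses
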