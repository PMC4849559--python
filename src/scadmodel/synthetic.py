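"""Synthetic EHR-like cohorts with known ground truth.

Because the source EHR data are access-restricted, every downstream stage
is exercised on synthetic cohorts whose *marginal* structure mirrors a
large English stable-CAD population: covariate means/proportions follow
the published overall patient-characteristics table, event histories are
drawn from known parametric cause-specific hazards, and 90-day cost
panels follow a known log-link mean model.  The ground truth
(:class:`TrueParameters`) is what parameter-recovery tests check
estimates against, and can be wrapped into a
:class:`~scadmodel.equations.RiskEquationSet` to drive the Markov engine
directly.

Dependence structure: continuous covariates are drawn through a Gaussian
copula (default correlations zero — the published table reports only
marginals); binary and categorical covariates are independent draws from
their marginal proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from scadmodel import families
from scadmodel.covariates import (
    BINARY_FIELDS,
    BIOMARKER_FIELDS,
    COVARIATE_COLUMNS,
    SMOKING_LEVELS,
    SUBTYPE_LEVELS,
    design_matrix,
)
from scadmodel.costs import CYCLE_LENGTH_YEARS, UtilityCatalogue
from scadmodel.lifetable import LifeTable
from scadmodel.survival import SurvivalFit
from scadmodel.transitions import EVENT_STATE, PRIMARY_CAUSES

NONFATAL = tuple(EVENT_STATE)
MEDIAN_FOLLOWUP_YEARS = 4.2
DEFAULT_CENSOR_RATE = float(np.log(2.0) / MEDIAN_FOLLOWUP_YEARS)

_CONTINUOUS = ("age_entry", *BIOMARKER_FIELDS)


@dataclass
class GeneratorConfig:
    """Marginal targets and dependence knobs for cohort generation.

    Defaults reproduce the overall-column means/proportions of the
    published baseline-characteristics table for an English stable-CAD
    cohort.
    """

    prop_female: float = 0.44
    age_mean_male: float = 67.0
    age_mean_female: float = 72.0
    age_sd: float = 12.0
    deprivation_probs: tuple = (0.20, 0.20, 0.20, 0.20, 0.20)
    subtype_probs: dict = field(
        default_factory=lambda: {
            "stable_angina": 0.46,
            "unstable_angina": 0.14,
            "stemi": 0.07,
            "nstemi": 0.10,
            "other_chd": 0.23,
        }
    )
    binary_props: dict = field(
        default_factory=lambda: {
            "pci_6m": 0.09,
            "cabg_6m": 0.04,
            "previous_mi": 0.18,
            "nitrates": 0.28,
            "hypertension": 0.76,
            "diabetes": 0.16,
            "heart_failure": 0.26,
            "pad": 0.08,
            "af": 0.15,
            "prior_stroke": 0.09,
            "ckd": 0.07,
            "copd": 0.23,
            "cancer": 0.09,
            "liver_disease": 0.01,
            "depression": 0.17,
            "anxiety": 0.08,
        }
    )
    smoking_probs: dict = field(
        default_factory=lambda: {"never": 0.33, "ex": 0.32, "current": 0.35}
    )
    biomarker_means: dict = field(
        default_factory=lambda: {
            "total_chol": 4.79,
            "hdl": 1.37,
            "heart_rate": 72.0,
            "creatinine": 100.0,
            "wcc": 7.46,
            "haemoglobin": 1.36,
        }
    )
    biomarker_sds: dict = field(
        default_factory=lambda: {
            "total_chol": 1.10,
            "hdl": 0.40,
            "heart_rate": 12.0,
            "creatinine": 25.0,
            "wcc": 2.0,
            "haemoglobin": 0.18,
        }
    )
    #: pairwise Gaussian-copula correlations between continuous fields,
    #: e.g. {("age_entry", "creatinine"): 0.2}; unlisted pairs are 0.
    correlations: dict = field(default_factory=dict)
    censor_rate: float = DEFAULT_CENSOR_RATE

    def validate(self) -> None:
        probs = [self.prop_female, *self.deprivation_probs,
                 *self.subtype_probs.values(), *self.binary_props.values(),
                 *self.smoking_probs.values()]
        bad = [p for p in probs if not 0.0 <= p <= 1.0]
        if bad:
            raise ValueError(f"proportions must lie in [0, 1]; offending values: {bad}")
        for group, tot in [("deprivation", sum(self.deprivation_probs)),
                           ("subtype", sum(self.subtype_probs.values())),
                           ("smoking", sum(self.smoking_probs.values()))]:
            if abs(tot - 1.0) > 1e-6:
                raise ValueError(f"{group} probabilities must sum to 1 (got {tot})")
        if any(sd <= 0 for sd in self.biomarker_sds.values()) or self.age_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor rate must be non-negative")

    def mean_design(self) -> pd.Series:
        """Expected design vector implied by the marginal targets."""
        x = dict.fromkeys(COVARIATE_COLUMNS, 0.0)
        x["sex_female"] = self.prop_female
        x["age_entry"] = (
            (1 - self.prop_female) * self.age_mean_male + self.prop_female * self.age_mean_female
        )
        for q in range(2, 6):
            x[f"deprived_q{q}"] = self.deprivation_probs[q - 1]
        for lv in SUBTYPE_LEVELS[1:]:
            x[f"subtype_{lv}"] = self.subtype_probs[lv]
        for f, p in self.binary_props.items():
            x[f] = p
        for lv in SMOKING_LEVELS[1:]:
            x[f"smoking_{lv}"] = self.smoking_probs[lv]
        for f, m in self.biomarker_means.items():
            x[f] = m
        return pd.Series(x)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["deprivation_probs"] = list(self.deprivation_probs)
        d["correlations"] = {f"{a}|{b}": v for (a, b), v in self.correlations.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "deprivation_probs" in d:
            d["deprivation_probs"] = tuple(d["deprivation_probs"])
        if "correlations" in d:
            d["correlations"] = {
                tuple(k.split("|")): float(v) for k, v in d["correlations"].items()
            }
        return cls(**d)


def generate_cohort(n: int, seed: int, config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Draw ``n`` synthetic baseline patient profiles."""
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    sex = np.where(rng.random(n) < config.prop_female, "female", "male")

    # Gaussian copula over the continuous block
    k = len(_CONTINUOUS)
    corr = np.eye(k)
    idx = {name: i for i, name in enumerate(_CONTINUOUS)}
    for (a, b), r in config.correlations.items():
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, k)) @ chol.T

    age_mean = np.where(sex == "female", config.age_mean_female, config.age_mean_male)
    age = np.clip(age_mean + config.age_sd * z[:, idx["age_entry"]], 18.0, 110.0)

    cohort = pd.DataFrame({"patient_id": np.arange(n), "sex": sex, "age_entry": age})
    cohort["deprived_quintile"] = (
        rng.choice(5, size=n, p=np.asarray(config.deprivation_probs)
                   / sum(config.deprivation_probs)) + 1
    )
    levels = list(config.subtype_probs)
    cohort["cad_subtype"] = rng.choice(
        levels, size=n, p=np.asarray([config.subtype_probs[lv] for lv in levels])
    )
    for f in BINARY_FIELDS:
        cohort[f] = (rng.random(n) < config.binary_props[f]).astype(int)
    smk = list(config.smoking_probs)
    cohort["smoking"] = rng.choice(smk, size=n, p=[config.smoking_probs[s] for s in smk])
    for f in BIOMARKER_FIELDS:
        m, s = config.biomarker_means[f], config.biomarker_sds[f]
        lsig2 = np.log1p((s / m) ** 2)  # lognormal moment matching keeps the mean exact
        cohort[f] = np.exp(np.log(m) - lsig2 / 2.0 + np.sqrt(lsig2) * z[:, idx[f]])
    return cohort


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class EndpointTruth:
    family: str
    coef: dict  # design-column name -> AFT location coefficient (+ intercept)
    sigma: float = 1.0
    q: float | None = None


@dataclass
class TrueParameters:
    """The data-generating parameters behind a synthetic cohort."""

    primary: dict  # cause -> EndpointTruth (covariates: full design)
    post: dict  # (event, cause) -> EndpointTruth (covariates: sex_female, age_event)
    cost: dict  # component -> {feature: coefficient}
    cost_noise_shape: float | None = 1.5  # gamma shape; None = deterministic costs
    censor_rate: float = DEFAULT_CENSOR_RATE
    utility: UtilityCatalogue | None = None

    def location(self, truth: EndpointTruth, design: pd.DataFrame | pd.Series):
        lp = truth.coef.get("intercept", 0.0)
        for name, b in truth.coef.items():
            if name == "intercept":
                continue
            col = design[name]
            lp = lp + b * (col.to_numpy(float) if hasattr(col, "to_numpy") else float(col))
        return lp

    def to_cost_model(self):
        """Wrap the cost truth into a CostModel (zero parameter uncertainty)."""
        from scadmodel.costs import CostComponent, CostModel

        comps = {
            name: CostComponent(
                coef=pd.Series(coef, dtype=float),
                vcov=np.zeros((len(coef), len(coef))),
                dispersion=0.0,
            )
            for name, coef in self.cost.items()
        }
        return CostModel(components=comps)

    def to_equation_set(self, life_table: LifeTable, splice_time: float = 10.0):
        """Wrap the truth into a RiskEquationSet (zero parameter uncertainty)."""
        from scadmodel.equations import RiskEquationSet

        def as_fit(endpoint, truth: EndpointTruth) -> SurvivalFit:
            coef = pd.Series({"intercept": 0.0, **truth.coef}, dtype=float)
            npar = len(coef) + families.N_ANCILLARY[truth.family]
            return SurvivalFit(
                endpoint=endpoint,
                family=truth.family,
                coef=coef,
                sigma=truth.sigma,
                q=truth.q,
                vcov=np.zeros((npar, npar)),
                loglik=np.nan,
                n_events=0,
                n_obs=0,
                fingerprint="truth",
                param_names=list(coef.index),
            )

        return RiskEquationSet(
            primary={c: as_fit(c, t) for c, t in self.primary.items()},
            post={k: as_fit(f"{k[1]}_after_{k[0]}", t) for k, t in self.post.items()},
            life_table=life_table,
            splice_time=splice_time,
        )


#: 5-year cause-specific cumulative hazards at the mean covariate vector
#: that the default truth is calibrated to (plausible for stable-CAD).
DEFAULT_PRIMARY_TARGETS = {
    "mi": 0.065,
    "ischaemic_stroke": 0.048,
    "haemorrhagic_stroke": 0.006,
    "cvd_death": 0.055,
    "noncvd_death": 0.16,
}

#: 1-year post-event cause-specific cumulative hazards at reference
#: (44% female, age 72 at event).
DEFAULT_POST_TARGETS = {
    ("mi", "cvd_death"): 0.08,
    ("mi", "noncvd_death"): 0.06,
    ("ischaemic_stroke", "cvd_death"): 0.10,
    ("ischaemic_stroke", "noncvd_death"): 0.07,
    ("haemorrhagic_stroke", "cvd_death"): 0.15,
    ("haemorrhagic_stroke", "noncvd_death"): 0.08,
}

_PRIMARY_COEFS = {
    "mi": {"age_entry": -0.030, "sex_female": 0.15, "previous_mi": -0.35,
           "diabetes": -0.30, "smoking_current": -0.30, "heart_failure": -0.25,
           "hypertension": -0.15, "creatinine": -0.002},
    "ischaemic_stroke": {"age_entry": -0.040, "sex_female": 0.05, "af": -0.40,
                         "prior_stroke": -0.60, "hypertension": -0.25,
                         "smoking_current": -0.20, "diabetes": -0.20},
    "haemorrhagic_stroke": {"age_entry": -0.040, "hypertension": -0.40,
                            "prior_stroke": -0.30, "smoking_current": -0.10},
    "cvd_death": {"age_entry": -0.050, "sex_female": 0.15, "heart_failure": -0.60,
                  "previous_mi": -0.25, "diabetes": -0.25, "smoking_current": -0.25,
                  "pad": -0.30, "creatinine": -0.003},
    "noncvd_death": {"age_entry": -0.055, "sex_female": 0.10, "cancer": -0.70,
                     "copd": -0.40, "ckd": -0.30, "smoking_current": -0.35,
                     "heart_failure": -0.30, "liver_disease": -0.50},
}

_PRIMARY_SIGMAS = {"mi": 0.9, "ischaemic_stroke": 0.9, "haemorrhagic_stroke": 0.9,
                   "cvd_death": 0.8, "noncvd_death": 0.7}

_POST_COEFS = {"sex_female": 0.10, "age_event": -0.030}
_POST_SIGMA = 0.8
_POST_REF = pd.Series({"sex_female": 0.44, "age_event": 72.0})

DEFAULT_COST_COEFS = {
    "cvd": {"intercept": float(np.log(350.0) - 0.015 * 69.0), "current_age": 0.015,
            "heart_failure": 0.40, "previous_mi": 0.25, "diabetes": 0.15,
            "state_post_mi": 0.45, "state_post_is": 0.80, "state_post_hs": 0.90,
            "acute": 1.60, "band_early": 0.30},
    "other": {"intercept": float(np.log(450.0) - 0.020 * 69.0), "current_age": 0.020,
              "copd": 0.30, "cancer": 0.50, "diabetes": 0.20, "sex_female": -0.05},
}


def _calibrated_intercept(family: str, sigma: float, horizon: float, cumhaz: float,
                          coef: dict, mean_design: pd.Series) -> float:
    """Location intercept so the cumulative hazard at ``horizon`` equals
    ``cumhaz`` at the mean covariate vector (Weibull/exponential form)."""
    if family not in ("weibull", "exponential"):
        raise NotImplementedError("calibration implemented for Weibull-type truths")
    mu_bar = np.log(horizon) - sigma * np.log(cumhaz)
    offset = sum(b * float(mean_design[name]) for name, b in coef.items() if name != "intercept")
    return float(mu_bar - offset)


def default_true_parameters(config: GeneratorConfig | None = None) -> TrueParameters:
    """The package's reference ground truth, calibrated to the generator
    config's mean covariate vector."""
    config = config or GeneratorConfig()
    xbar = config.mean_design()
    primary = {}
    for cause in PRIMARY_CAUSES:
        coef = dict(_PRIMARY_COEFS[cause])
        sigma = _PRIMARY_SIGMAS[cause]
        coef["intercept"] = _calibrated_intercept(
            "weibull", sigma, 5.0, DEFAULT_PRIMARY_TARGETS[cause], coef, xbar
        )
        primary[cause] = EndpointTruth("weibull", coef, sigma)
    post = {}
    for key, target in DEFAULT_POST_TARGETS.items():
        coef = dict(_POST_COEFS)
        coef["intercept"] = _calibrated_intercept(
            "weibull", _POST_SIGMA, 1.0, target, coef, _POST_REF
        )
        post[key] = EndpointTruth("weibull", coef, _POST_SIGMA)
    return TrueParameters(
        primary=primary,
        post=post,
        cost={k: dict(v) for k, v in DEFAULT_COST_COEFS.items()},
        censor_rate=config.censor_rate,
        utility=synthetic_utility_catalogue(),
    )


def simulate_event_histories(
    cohort: pd.DataFrame, truth: TrueParameters, seed: int
) -> pd.DataFrame:
    """Draw competing-risk first events and post-event outcomes.

    Latent cause-specific event times are simulated per cause from the
    AFT truth; the first event is their minimum (exact under
    cause-specific-hazard composition), with independent exponential
    censoring.  After a non-fatal event the clock resets and two latent
    mortality times are drawn from the post-event truth using sex and age
    at the event.
    """
    n = len(cohort)
    rng = np.random.default_rng(seed)
    x = design_matrix(cohort)

    latent = np.empty((len(PRIMARY_CAUSES), n))
    for i, cause in enumerate(PRIMARY_CAUSES):
        t = truth.primary[cause]
        mu = np.broadcast_to(np.asarray(truth.location(t, x), dtype=float), (n,))
        if not np.all(np.isfinite(mu)):
            bad = np.flatnonzero(~np.isfinite(mu))[:5]
            raise ValueError(
                f"non-finite hazard for cause {cause!r} at patient rows {bad.tolist()}"
            )
        latent[i] = np.maximum(families.sample(rng, mu, t.sigma, t.q, t.family), 1e-6)

    censor = (
        rng.exponential(1.0 / truth.censor_rate, size=n)
        if truth.censor_rate > 0
        else np.full(n, np.inf)
    )
    winner = latent.argmin(axis=0)
    t_first = latent.min(axis=0)
    censored = censor < t_first
    t_first = np.where(censored, censor, t_first)
    first_event = np.where(censored, "censored", np.asarray(PRIMARY_CAUSES)[winner])

    out = pd.DataFrame(
        {
            "patient_id": cohort["patient_id"].to_numpy(),
            "first_event": first_event,
            "time_first_event": t_first,
            "post_event_outcome": "none",
            "time_post_event": np.nan,
        }
    )

    sexf = x["sex_female"].to_numpy(float)
    age0 = x["age_entry"].to_numpy(float)
    for event in NONFATAL:
        mask = (out["first_event"] == event).to_numpy()
        if not mask.any():
            continue
        m = int(mask.sum())
        post_design = pd.DataFrame(
            {"sex_female": sexf[mask], "age_event": age0[mask] + t_first[mask]}
        )
        post_latent = np.empty((2, m))
        for i, cause in enumerate(("cvd_death", "noncvd_death")):
            pt = truth.post[(event, cause)]
            mu = np.broadcast_to(np.asarray(truth.location(pt, post_design), dtype=float), (m,))
            post_latent[i] = np.maximum(families.sample(rng, mu, pt.sigma, pt.q, pt.family), 1e-6)
        post_censor = np.maximum(censor[mask] - t_first[mask], 1e-6)
        pwin = post_latent.argmin(axis=0)
        pt_time = post_latent.min(axis=0)
        pcens = post_censor < pt_time
        out.loc[mask, "time_post_event"] = np.where(pcens, post_censor, pt_time)
        out.loc[mask, "post_event_outcome"] = np.where(
            pcens, "censored", np.asarray(["cvd_death", "noncvd_death"])[pwin]
        )
    return out


def simulate_cost_panel(
    cohort: pd.DataFrame, histories: pd.DataFrame, truth: TrueParameters, seed: int
) -> pd.DataFrame:
    """90-day cost panel rows while each patient is alive and uncensored."""
    merged = histories.merge(cohort, on="patient_id", how="inner", validate="1:1")
    if len(merged) != len(histories):
        raise ValueError("histories cover patients absent from the cohort")
    rng = np.random.default_rng(seed)
    x = design_matrix(merged)
    dt = CYCLE_LENGTH_YEARS

    t_first = merged["time_first_event"].to_numpy(float)
    nonfatal = merged["first_event"].isin(NONFATAL).to_numpy()
    t_end = np.where(
        nonfatal, t_first + merged["time_post_event"].to_numpy(float), t_first
    )
    n_rows = np.floor(t_end / dt).astype(int) + 1
    pid = np.repeat(merged["patient_id"].to_numpy(), n_rows)
    row_of = np.repeat(np.arange(len(merged)), n_rows)
    cyc = np.concatenate([np.arange(k) for k in n_rows])

    event_cycle = np.floor(t_first / dt).astype(int)
    ev_cyc = event_cycle[row_of]
    in_post = nonfatal[row_of] & (cyc >= ev_cyc)
    state_name = np.asarray(
        ["stable"] + [EVENT_STATE[e] for e in NONFATAL], dtype=object
    )
    ev_state = np.asarray(
        [EVENT_STATE.get(e, "stable") for e in merged["first_event"]], dtype=object
    )[row_of]
    state = np.where(in_post, ev_state, "stable")
    cse = np.where(in_post, cyc - ev_cyc, -1)  # -1 encodes "no event yet"

    age = x["age_entry"].to_numpy(float)[row_of] + cyc * dt
    mean = {}
    for comp, coef in truth.cost.items():
        lp = np.full(len(cyc), coef.get("intercept", 0.0))
        for name, b in coef.items():
            if name == "intercept":
                continue
            if name == "current_age":
                lp += b * age
            elif name.startswith("state_"):
                lp += b * (state == name[len("state_"):]).astype(float)
            elif name == "acute":
                lp += b * (cse == 0).astype(float)
            elif name == "band_early":
                lp += b * ((cse >= 1) & (cse <= 4)).astype(float)
            else:
                lp += b * x[name].to_numpy(float)[row_of]
        mean[comp] = np.exp(lp)

    shape = truth.cost_noise_shape
    obs = {}
    for comp, mu in mean.items():
        if shape is None or shape == 0:
            obs[comp] = mu
        else:
            obs[comp] = rng.gamma(shape=shape, scale=mu / shape)
    return pd.DataFrame(
        {
            "patient_id": pid,
            "cycle_index": cyc,
            "state_at_cycle": state,
            "cycles_since_event": np.where(cse < 0, np.nan, cse),
            "observed_cost": obs["cvd"] + obs["other"],
            "observed_cost_cvd": obs["cvd"],
        }
    )


# ---------------------------------------------------------------------------
# packaged reference inputs (synthetic stand-ins for national sources)


def synthetic_life_table(terminal_age: int = 100) -> LifeTable:
    """Synthetic national-style life table of annual non-CVD death
    probabilities, Gompertz by sex, terminal row q=1."""
    rows = []
    for sex, a, b in [("male", 2.6e-5, 0.102), ("female", 1.4e-5, 0.105)]:
        ages = np.arange(18, terminal_age + 1)
        h = a * np.exp(b * ages)
        q = 1.0 - np.exp(-h)
        q[-1] = 1.0
        rows.append(pd.DataFrame({"sex": sex, "age": ages, "qx": q}))
    return LifeTable(pd.concat(rows, ignore_index=True))


def synthetic_utility_catalogue() -> UtilityCatalogue:
    """Synthetic EQ-5D-style utility catalogue (UK-population-norm shaped)."""
    bands = [(18, 24), (25, 34), (35, 44), (45, 54), (55, 64), (65, 74), (75, 110)]
    male = [0.94, 0.93, 0.91, 0.85, 0.80, 0.78, 0.73]
    rows = []
    for sex, offset in [("male", 0.0), ("female", -0.02)]:
        for (lo, hi), u in zip(bands, male):
            rows.append({"sex": sex, "age_lo": lo, "age_hi": hi, "base_utility": u + offset})
    return UtilityCatalogue(
        bands=pd.DataFrame(rows),
        condition_multiplier=0.92,
        event_multipliers={"post_mi": 0.88, "post_is": 0.80, "post_hs": 0.75},
        acute_multiplier=0.85,
    )
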