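"""Baseline covariate schema and design-matrix encoding.

A cohort is a :class:`pandas.DataFrame` with one row per patient and the
columns listed in :data:`PROFILE_SCHEMA`.  The survival and cost equations
consume a fixed one-hot design with reference levels sex=male,
CAD subtype=stable_angina, smoking=never, deprivation quintile=1 (least
deprived); continuous biomarkers enter linearly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SEX_LEVELS = ("male", "female")
SUBTYPE_LEVELS = ("stable_angina", "unstable_angina", "stemi", "nstemi", "other_chd")
SMOKING_LEVELS = ("never", "ex", "current")

BINARY_FIELDS = (
    "pci_6m",
    "cabg_6m",
    "previous_mi",
    "nitrates",
    "hypertension",
    "diabetes",
    "heart_failure",
    "pad",
    "af",
    "prior_stroke",
    "ckd",
    "copd",
    "cancer",
    "liver_disease",
    "depression",
    "anxiety",
)

BIOMARKER_FIELDS = (
    "total_chol",
    "hdl",
    "heart_rate",
    "creatinine",
    "wcc",
    "haemoglobin",
)

PROFILE_SCHEMA = (
    ("patient_id", "int"),
    ("sex", "category"),
    ("age_entry", "float"),
    ("deprived_quintile", "int"),
    ("cad_subtype", "category"),
    *((f, "int") for f in BINARY_FIELDS),
    ("smoking", "category"),
    *((f, "float") for f in BIOMARKER_FIELDS),
)

#: Design-matrix column order (without intercept).
COVARIATE_COLUMNS = (
    "sex_female",
    "age_entry",
    "deprived_q2",
    "deprived_q3",
    "deprived_q4",
    "deprived_q5",
    "subtype_unstable_angina",
    "subtype_stemi",
    "subtype_nstemi",
    "subtype_other_chd",
    *BINARY_FIELDS,
    "smoking_ex",
    "smoking_current",
    *BIOMARKER_FIELDS,
)


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Raise ``ValueError`` on schema or invariant violations."""
    missing = [c for c, _ in PROFILE_SCHEMA if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing columns: {missing}")
    if not cohort["age_entry"].between(18, 110).all():
        raise ValueError("age_entry must lie in [18, 110]")
    for f in BIOMARKER_FIELDS:
        if not (cohort[f] > 0).all():
            raise ValueError(f"biomarker {f!r} must be strictly positive")
    for f in BINARY_FIELDS:
        if not cohort[f].isin([0, 1]).all():
            raise ValueError(f"indicator {f!r} must be 0/1")
    if not cohort["sex"].isin(SEX_LEVELS).all():
        raise ValueError(f"sex must be one of {SEX_LEVELS}")
    if not cohort["cad_subtype"].isin(SUBTYPE_LEVELS).all():
        raise ValueError(f"cad_subtype must be one of {SUBTYPE_LEVELS}")
    if not cohort["smoking"].isin(SMOKING_LEVELS).all():
        raise ValueError(f"smoking must be one of {SMOKING_LEVELS}")
    if not cohort["deprived_quintile"].isin(range(1, 6)).all():
        raise ValueError("deprived_quintile must be in 1..5")


def design_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Encode profiles into the fixed one-hot design (no intercept column).

    Categorical columns may also arrive pre-encoded as fractional
    indicators (a group-mean covariate vector); those are passed through.
    """
    out = pd.DataFrame(index=cohort.index, dtype=float)
    if "sex_female" in cohort.columns:
        # already-encoded input (e.g. a group-mean profile)
        for col in COVARIATE_COLUMNS:
            out[col] = pd.to_numeric(cohort[col], errors="raise")
        return out
    out["sex_female"] = (cohort["sex"] == "female").astype(float)
    out["age_entry"] = cohort["age_entry"].astype(float)
    for q in range(2, 6):
        out[f"deprived_q{q}"] = (cohort["deprived_quintile"] == q).astype(float)
    for lv in SUBTYPE_LEVELS[1:]:
        out[f"subtype_{lv}"] = (cohort["cad_subtype"] == lv).astype(float)
    for f in BINARY_FIELDS:
        out[f] = cohort[f].astype(float)
    for lv in SMOKING_LEVELS[1:]:
        out[f"smoking_{lv}"] = (cohort["smoking"] == lv).astype(float)
    for f in BIOMARKER_FIELDS:
        out[f] = cohort[f].astype(float)
    return out[list(COVARIATE_COLUMNS)]


def design_row(profile: pd.Series) -> pd.Series:
    """Encode a single profile (raw or pre-encoded) into a design vector."""
    frame = profile.to_frame().T
    if "sex_female" not in frame.columns:
        frame = frame.astype(
            {c: t for c, t in PROFILE_SCHEMA if t != "category" and c in frame.columns}
        )
    return design_matrix(frame).iloc[0]


def mean_profile(cohort: pd.DataFrame) -> pd.Series:
    """Group-mean covariate vector: categoricals as level proportions."""
    x = design_matrix(cohort)
    return x.mean(axis=0)


def linear_predictor(
    design: pd.DataFrame | pd.Series, coef: pd.Series | dict[str, float]
) -> np.ndarray | float:
    """``intercept + x'beta`` using coefficient names; absent names mean 0."""
    coef = pd.Series(coef, dtype=float)
    lp = float(coef.get("intercept", 0.0))
    if isinstance(design, pd.Series):
        extra = sum(v * float(design[k]) for k, v in coef.items() if k != "intercept")
        return lp + extra
    vals = np.full(len(design), lp)
    for k, v in coef.items():
        if k != "intercept":
            vals = vals + v * design[k].to_numpy(float)
    return vals
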