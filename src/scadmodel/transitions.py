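"""Competing-risks composition: hazards → CIFs → per-cycle transitions.

Cause-specific hazards are combined into an event-free survival curve
``S(t) = exp(-sum_k H_k(t))`` and cumulative incidence functions
``F_k(t) = ∫ h_k(u) S(u) du``.  Integration treats hazards as piecewise
constant on a sub-cycle grid (midpoint evaluation), which makes the
accounting identity ``S + Σ F_k = 1`` hold to machine precision at every
grid point and is exact for constant hazards.

Per-cycle transition probabilities condition on being event-free at the
cycle start:

    P(move to cause k during cycle j) = (F_k(t_{j+1}) - F_k(t_j)) / S(t_j)
    P(stay event-free)                =  S(t_{j+1}) / S(t_j)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

log = logging.getLogger(__name__)

CYCLE_LENGTH_YEARS = 90.0 / 365.25

PRIMARY_CAUSES = ("mi", "ischaemic_stroke", "haemorrhagic_stroke", "cvd_death", "noncvd_death")
STATES = ("stable", "post_mi", "post_is", "post_hs", "cvd_death", "noncvd_death")
EVENT_STATE = {"mi": "post_mi", "ischaemic_stroke": "post_is", "haemorrhagic_stroke": "post_hs"}
CVD_CAUSES = ("mi", "ischaemic_stroke", "haemorrhagic_stroke", "cvd_death")

DEFAULT_N_SUB = 16  # sub-steps per 90-day cycle for hazard integration


@dataclass
class CIFBundle:
    """Event-free survival and per-cause CIFs on cycle boundaries."""

    times: np.ndarray                 # cycle boundaries, years; length C+1
    survival: np.ndarray              # S(t) at boundaries
    cif: dict[str, np.ndarray]        # cause -> F_k(t) at boundaries
    person_time: np.ndarray | None = None  # ∫ S du over each cycle, years (length C)

    @property
    def causes(self) -> tuple[str, ...]:
        return tuple(self.cif)

    def conservation_error(self) -> float:
        total = self.survival + sum(self.cif.values())
        return float(np.max(np.abs(total - 1.0)))


@dataclass
class CycleTransition:
    cycle: int
    from_state: str
    probs: np.ndarray  # over STATES, sums to 1

    def __post_init__(self):
        if self.probs.shape != (len(STATES),):
            raise ValueError("probability vector must cover the six model states")


def build_cifs(
    hazards: Mapping[str, Callable],
    n_cycles: int,
    cycle_length: float = CYCLE_LENGTH_YEARS,
    n_sub: int = DEFAULT_N_SUB,
) -> CIFBundle:
    """Integrate cause-specific hazards into a :class:`CIFBundle`.

    ``hazards`` maps cause names to callables ``h(t) -> per-year rate``,
    evaluated at sub-cycle midpoints.  Infinite rates (life-table terminal
    row) send all remaining mass to the infinite-rate cause(s).
    """
    causes = tuple(hazards)
    m = n_cycles * n_sub
    dt = cycle_length / n_sub
    mid = (np.arange(m) + 0.5) * dt
    h = np.empty((len(causes), m))
    for i, c in enumerate(causes):
        h[i] = np.broadcast_to(np.asarray(hazards[c](mid), dtype=float), (m,))
    if np.any(np.isnan(h)) or np.any(h < 0):
        bad = [c for i, c in enumerate(causes) if np.any(~(h[i] >= 0))]
        raise ValueError(f"negative or non-finite hazard for cause(s) {bad}")
    # clamp "certain death" rates (life-table terminal row) to a huge finite
    # value: exp(-1e12 dt) is exactly 0 in floats, with no inf arithmetic
    h = np.minimum(h, 1e12)

    h_tot = h.sum(axis=0)
    inf_mask = ~np.isfinite(h_tot)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(h_tot > 0, h / np.where(h_tot > 0, h_tot, 1.0), 0.0)
    if inf_mask.any():
        n_inf = (~np.isfinite(h)).sum(axis=0)
        frac[:, inf_mask] = (~np.isfinite(h[:, inf_mask])) / n_inf[inf_mask]

    step_surv = np.exp(-np.where(inf_mask, np.inf, h_tot) * dt)
    s_fine = np.concatenate([[1.0], np.cumprod(step_surv)])
    df = frac * (s_fine[:-1] - s_fine[1:])  # per-cause mass in each sub-step
    f_fine = np.concatenate([np.zeros((len(causes), 1)), np.cumsum(df, axis=1)], axis=1)

    # exact ∫ S du per sub-step under the piecewise-constant hazard,
    # via expm1 (stable as h -> 0)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        pt_fine = np.where(
            h_tot > 0,
            s_fine[:-1] * (-np.expm1(-np.where(inf_mask, 1.0, h_tot) * dt))
            / np.where(h_tot > 0, h_tot, 1.0),
            s_fine[:-1] * dt,
        )
    pt_fine[inf_mask] = 0.0

    idx = np.arange(0, m + 1, n_sub)
    return CIFBundle(
        times=np.arange(n_cycles + 1) * cycle_length,
        survival=s_fine[idx],
        cif={c: f_fine[i, idx] for i, c in enumerate(causes)},
        person_time=pt_fine.reshape(n_cycles, n_sub).sum(axis=1),
    )


def _conditional_row(cifs: CIFBundle, j: int, state_of: Mapping[str, str], stay_state: str,
                     from_state: str) -> CycleTransition:
    s_j = cifs.survival[j]
    probs = np.zeros(len(STATES))
    if s_j <= 1e-300:
        log.warning("state %s unreachable at cycle %d (S=0); absorbing self-loop", from_state, j)
        probs[STATES.index(from_state)] = 1.0
        return CycleTransition(j, from_state, probs)
    for cause, f in cifs.cif.items():
        probs[STATES.index(state_of[cause])] = (f[j + 1] - f[j]) / s_j
    probs[STATES.index(stay_state)] = cifs.survival[j + 1] / s_j
    return CycleTransition(j, from_state, probs)


def stable_state_transitions(cifs: CIFBundle, j: int) -> CycleTransition:
    """Transition row out of the stable state for cycle ``j``."""
    if j + 1 >= len(cifs.times):
        raise IndexError(f"CIF grid does not cover cycle {j}")
    state_of = dict(EVENT_STATE, cvd_death="cvd_death", noncvd_death="noncvd_death")
    return _conditional_row(cifs, j, state_of, "stable", "stable")


def post_event_transitions(
    post_fits: Mapping[str, "object"],
    sex: str,
    age_at_event: float,
    cycles_since_event: int,
    event_state: str = "post_mi",
    cycle_length: float = CYCLE_LENGTH_YEARS,
    n_sub: int = DEFAULT_N_SUB,
) -> CycleTransition:
    """Two-cause competing-risk transition row for a post-event state.

    ``post_fits`` maps ``cvd_death`` / ``noncvd_death`` to fitted
    equations whose covariates are sex and age at the non-fatal event;
    the clock is time since that event.
    """
    import pandas as pd

    design = pd.Series({"sex_female": 1.0 if sex == "female" else 0.0, "age_event": age_at_event})
    hazards = {k: f.hazard_fn(design) for k, f in post_fits.items()}
    cifs = build_cifs(hazards, cycles_since_event + 1, cycle_length, n_sub)
    state_of = {"cvd_death": "cvd_death", "noncvd_death": "noncvd_death"}
    return _conditional_row(cifs, cycles_since_event, state_of, event_state, event_state)


def apply_treatment(
    hazards: Mapping[str, Callable],
    rho: float,
    treat_haemorrhagic: bool = True,
) -> dict[str, Callable]:
    """Scale CVD cause-specific hazards by (1 - rho); non-CVD untouched."""
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"hazard reduction rho must lie in [0, 1); got {rho}")
    treated = set(CVD_CAUSES)
    if not treat_haemorrhagic:
        treated.discard("haemorrhagic_stroke")

    def scaled(h):
        return lambda t, _h=h: (1.0 - rho) * np.asarray(_h(t), dtype=float)

    return {c: (scaled(h) if c in treated else h) for c, h in hazards.items()}
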