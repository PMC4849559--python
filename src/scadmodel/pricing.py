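"""Incremental cost-effectiveness and value-based maximum prices.

For a treatment that scales CVD hazards by (1 - rho), the maximum annual
price at threshold ``lambda`` (GBP/QALY) is the price at which
incremental net monetary benefit is exactly zero:

    p* = max(0, (lambda * dQALY - dCost_disease) / exposure)

where dQALY and dCost_disease are discounted increments (disease costs
exclude the treatment's own price) and exposure is the treated arm's
discounted life years — the treatment is taken, and paid for, while
alive, discounted like every other cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from scadmodel.markov import ModelOutputs


@dataclass
class IncrementalDeltas:
    d_qalys: float           # discounted QALY gain
    d_disease_costs: float   # discounted total-cost change, excluding treatment price
    exposure_years: float    # treated discounted life years (price paid while alive)


@dataclass
class PricingResult:
    rho: float
    threshold: float
    deltas: IncrementalDeltas
    max_annual_price: float


def incremental(base: ModelOutputs, treated: ModelOutputs) -> IncrementalDeltas:
    """Treated-minus-base discounted increments for pricing."""
    vals = [getattr(o, f) for o in (base, treated) for f in ModelOutputs.field_names()]
    if any(math.isnan(v) for v in vals):
        raise ValueError("model outputs contain NaN; runs are not comparable")
    return IncrementalDeltas(
        d_qalys=treated.discounted_qalys - base.discounted_qalys,
        d_disease_costs=treated.discounted_total_costs - base.discounted_total_costs,
        exposure_years=treated.discounted_life_years,
    )


def max_price(deltas: IncrementalDeltas, threshold: float) -> float:
    """Maximum cost-effective annual price (GBP/year), floored at zero."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if deltas.exposure_years <= 0:
        raise ValueError("treatment exposure is zero; maximum price undefined")
    headroom = threshold * deltas.d_qalys - deltas.d_disease_costs
    return max(0.0, headroom / deltas.exposure_years)


def pricing_grid(
    base: ModelOutputs,
    treated_by_rho: dict[float, ModelOutputs],
    thresholds: tuple[float, ...] = (10_000.0, 20_000.0, 30_000.0, 40_000.0),
    group_index: int | None = None,
) -> pd.DataFrame:
    """Tidy (group, rho, threshold, max price) table for one profile."""
    rows = []
    for rho, treated in sorted(treated_by_rho.items()):
        deltas = incremental(base, treated)
        for lam in thresholds:
            rows.append(
                {
                    "risk_group": group_index,
                    "rho": rho,
                    "threshold": lam,
                    "d_qalys": deltas.d_qalys,
                    "d_disease_costs": deltas.d_disease_costs,
                    "exposure_years": deltas.exposure_years,
                    "max_annual_price": max_price(deltas, lam),
                }
            )
    return pd.DataFrame(rows)


def price_result(base: ModelOutputs, treated: ModelOutputs, rho: float,
                 threshold: float) -> PricingResult:
    deltas = incremental(base, treated)
    return PricingResult(
        rho=rho, threshold=threshold, deltas=deltas,
        max_annual_price=max_price(deltas, threshold),
    )
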