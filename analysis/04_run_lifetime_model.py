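"""Run the six-state lifetime Markov model for every risk decile.

Evaluates the cohort model at each decile's mean covariate vector, for
standard care and for hypothetical treatments reducing CVD hazards by
10-40%, accruing (discounted) life years, QALYs and total/CVD costs in
90-day cycles until cohort extinction.  Prints the per-decile summary.
"""

import sys

import pandas as pd

from scadmodel.pipeline import stage_run
from analysis_config import CONFIG


def main() -> None:
    stage_run(CONFIG)
    res = pd.read_csv(f"{CONFIG.output_dir}/results.csv")
    base = res[res["rho"] == 0.0]
    cols = ["risk_group", "life_years", "discounted_life_years", "qalys",
            "discounted_qalys", "discounted_total_costs", "discounted_cvd_costs",
            "time_to_first_event", "cvd_mortality_pct", "noncvd_mortality_pct"]
    print("standard care, by risk decile:")
    print(base[cols].round(2).to_string(index=False))
    print("\nnote the gradient: lower-risk deciles live longer, accrue more "
          "QALYs and more lifetime cost; even the highest-risk decile dies "
          "more often of non-CVD than CVD causes.")


if __name__ == "__main__":
    sys.exit(main())
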