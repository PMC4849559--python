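"""Propagate parameter uncertainty through the model (PSA).

Per decile, repeatedly draws survival and cost coefficients from their
estimated multivariate normals (utilities from beta perturbations) and
re-runs the cohort model, summarising each output with percentile 95%
intervals.
"""

import sys

import pandas as pd

from scadmodel.pipeline import stage_psa
from analysis_config import CONFIG


def main() -> None:
    stage_psa(CONFIG)
    psa = pd.read_csv(f"{CONFIG.output_dir}/psa.csv")
    show = psa[psa["output"].isin(["discounted_qalys", "discounted_total_costs"])]
    print(f"PSA ({CONFIG.psa_iterations} iterations per decile), 95% intervals:")
    print(show.round(2).to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
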