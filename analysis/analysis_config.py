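"""Shared run configuration for the numbered analysis scripts.

Smoke scale (2,000 patients, 50 PSA iterations) so the full sequence
runs in minutes on one CPU; raise ``cohort_size``/``psa_iterations`` for
production-scale runs.
"""

from scadmodel.config import RunConfig

CONFIG = RunConfig(seed=1, cohort_size=2000, psa_iterations=50,
                   output_dir="results/run")
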