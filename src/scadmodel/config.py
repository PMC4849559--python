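"""Run configuration with validation and lossless YAML round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from scadmodel.synthetic import GeneratorConfig


@dataclass
class RunConfig:
    seed: int = 1
    cohort_size: int = 2000
    psa_iterations: int = 50
    discount_rate: float = 0.035
    horizon_years: float = 60.0
    splice_time: float = 10.0
    cycle_length_days: float = 90.0
    n_groups: int = 10
    families: tuple = ("exponential", "weibull", "lognormal", "generalised_gamma")
    rho_list: tuple = (0.10, 0.20, 0.30, 0.40)
    threshold_list: tuple = (10_000.0, 20_000.0, 30_000.0, 40_000.0)
    treat_haemorrhagic: bool = True
    treat_post_event: bool = True
    output_dir: str = "results/run"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def validate(self) -> None:
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        if self.psa_iterations < 0:
            raise ValueError("psa_iterations must be >= 0")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError("discount_rate must lie in [0, 1)")
        if self.cycle_length_days <= 0:
            raise ValueError("cycle_length_days must be positive")
        if self.cycle_length_days != 90.0:
            raise ValueError("only the 90-day cycle length is supported")
        if self.horizon_years <= 0 or self.splice_time <= 0:
            raise ValueError("horizon_years and splice_time must be positive")
        if self.n_groups < 1 or self.n_groups > self.cohort_size:
            raise ValueError("n_groups must lie in [1, cohort_size]")
        if any(not 0.0 <= r < 1.0 for r in self.rho_list):
            raise ValueError("every rho must lie in [0, 1)")
        if any(lam <= 0 for lam in self.threshold_list):
            raise ValueError("thresholds must be positive")
        self.generator.validate()

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["generator"] = self.generator.to_dict()
        for key in ("families", "rho_list", "threshold_list"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "generator" in d:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        for key in ("families", "rho_list", "threshold_list"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg
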