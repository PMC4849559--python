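"""National-life-table representation for long-term non-CVD mortality.

The table holds annual probabilities of non-CVD death ``q_x`` by sex and
integer age, ending in a terminal age with ``q = 1``.  Beyond the fitted
equations' support the model uses the constant-within-year hazard
``-ln(1 - q_x)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class LifeTable:
    table: pd.DataFrame  # columns: sex, age, qx

    def __post_init__(self) -> None:
        t = self.table
        required = {"sex", "age", "qx"}
        if not required.issubset(t.columns):
            raise ValueError(f"life table needs columns {sorted(required)}")
        if not t["qx"].between(0.0, 1.0).all():
            raise ValueError("life table qx values must lie in [0, 1]")
        self._by_sex: dict[str, np.ndarray] = {}
        self._age0: dict[str, int] = {}
        for sex, grp in t.groupby("sex", observed=True):
            grp = grp.sort_values("age")
            ages = grp["age"].to_numpy(int)
            if not np.all(np.diff(ages) == 1):
                raise ValueError(f"life table ages for sex={sex!r} are not contiguous")
            if grp["qx"].iloc[-1] != 1.0:
                raise ValueError(f"life table for sex={sex!r} must end with qx = 1")
            self._by_sex[str(sex)] = grp["qx"].to_numpy(float)
            self._age0[str(sex)] = int(ages[0])

    @property
    def terminal_age(self) -> int:
        sex = next(iter(self._by_sex))
        return self._age0[sex] + len(self._by_sex[sex]) - 1

    def qx(self, sex: str, age) -> np.ndarray:
        """Annual death probability at integer age; terminal row beyond range."""
        q = self._by_sex[sex]
        idx = np.clip(np.asarray(age, dtype=int) - self._age0[sex], 0, len(q) - 1)
        return q[idx]

    def hazard(self, sex: str, age) -> np.ndarray:
        """Continuous-time rate -ln(1 - q_x) per year; +inf at the terminal row.

        The transition engine converts hazards to per-cycle probabilities
        through ``1 - exp(-h dt)``, so an infinite rate realises "certain
        death within the year" without special-casing.
        """
        with np.errstate(divide="ignore"):
            return -np.log1p(-self.qx(sex, age))
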