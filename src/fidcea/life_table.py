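"""Age-indexed annual mortality for the background cohort.

A life table here is the minimal object the cohort model needs: one row per
integer age carrying ``qx``, the probability of dying within the year for a
person alive at that age.  Tables are exchanged as two-column CSV
(``age,qx``) so that any externally sourced national table can be dropped in
place of the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LifeTable"]


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities ``qx`` on a contiguous integer age grid.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``age`` (contiguous integers) and ``qx`` (each in [0, 1]).

    Notes
    -----
    A terminal ``qx`` of 1 is required only when the table is used to run a
    lifetime-horizon cohort (checked by the engine); finite-horizon test
    tables may leave the last row open.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        if not {"age", "qx"}.issubset(df.columns):
            raise ValueError("life table needs 'age' and 'qx' columns")
        ages = df["age"].to_numpy()
        qx = df["qx"].to_numpy(dtype=float)
        if len(ages) == 0:
            raise ValueError("life table is empty")
        if not np.array_equal(ages, np.arange(ages[0], ages[0] + len(ages))):
            raise ValueError("ages must be contiguous integers")
        if not np.all(np.isfinite(qx)) or np.any(qx < 0) or np.any(qx > 1):
            raise ValueError("qx values must be finite and within [0, 1]")
        object.__setattr__(
            self,
            "table",
            pd.DataFrame({"age": ages.astype(int), "qx": qx}).reset_index(drop=True),
        )

    @property
    def min_age(self) -> int:
        return int(self.table["age"].iloc[0])

    @property
    def max_age(self) -> int:
        return int(self.table["age"].iloc[-1])

    @property
    def terminal_qx(self) -> float:
        return float(self.table["qx"].iloc[-1])

    def qx(self, age: int) -> float:
        """Annual death probability at ``age``; ages past the table are fatal."""
        if age < self.min_age:
            raise ValueError(f"age {age} below life-table range ({self.min_age})")
        if age > self.max_age:
            return 1.0
        return float(self.table["qx"].iloc[age - self.min_age])

    def survival_curve(self, start_age: int | None = None) -> pd.Series:
        """Cohort survival S(a) from ``start_age``, S(start_age) = 1."""
        a0 = self.min_age if start_age is None else start_age
        sub = self.table[self.table["age"] >= a0]
        surv = np.concatenate([[1.0], np.cumprod(1.0 - sub["qx"].to_numpy())])
        return pd.Series(surv, index=np.arange(a0, a0 + len(surv)), name="survival")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path))
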