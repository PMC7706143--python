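"""Incremental cost-effectiveness comparison with dominance classification.

The comparison reports increments (intervention minus comparator) in cost,
QALYs and life years, and either an ICER or a dominance verdict: a strategy
that is cheaper and more effective dominates; one that is costlier and less
effective is dominated.  Ratios are always formed from the unrounded
increments — recomputing an ICER from the rounded increments a report
prints can be off by tens of percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["StrategyResult", "CEAComparison", "compare", "DOMINANT", "DOMINATED"]

DOMINANT = "dominant"
DOMINATED = "dominated"


@dataclass(frozen=True)
class StrategyResult:
    """One strategy's discounted totals under a common model setting."""

    name: str
    total_cost: float
    total_qaly: float
    total_ly: float
    settings_id: str | None = None  # guards against cross-setting comparisons

    def __post_init__(self) -> None:
        for attr in ("total_cost", "total_qaly", "total_ly"):
            if not math.isfinite(getattr(self, attr)):
                raise ValueError(f"{self.name}.{attr} must be finite")


def _verdict(delta_cost: float, delta_effect: float) -> float | str:
    if delta_cost < 0 and delta_effect > 0:
        return DOMINANT
    if delta_cost > 0 and delta_effect < 0:
        return DOMINATED
    if delta_effect == 0:
        if delta_cost == 0:
            return 0.0
        sign = "higher" if delta_cost > 0 else "lower"
        return f"undefined (no effect difference, {sign} cost)"
    return delta_cost / delta_effect


@dataclass(frozen=True)
class CEAComparison:
    """Increments and verdicts for intervention vs comparator."""

    intervention: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer_per_qaly: float | str
    icer_per_ly: float | str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "intervention": self.intervention,
                    "comparator": self.comparator,
                    "delta_cost_usd": self.delta_cost,
                    "delta_qaly": self.delta_qaly,
                    "delta_ly": self.delta_ly,
                    "icer_per_qaly": format_icer(self.icer_per_qaly),
                    "icer_per_ly": format_icer(self.icer_per_ly),
                }
            ]
        )


def format_icer(value: float | str) -> str:
    """Render an ICER as e.g. '27 012' (space-grouped, 0 decimals)."""
    if isinstance(value, str):
        return value.capitalize() if value in (DOMINANT, DOMINATED) else value
    return f"{value:,.0f}".replace(",", " ")


def compare(intervention: StrategyResult, comparator: StrategyResult) -> CEAComparison:
    """Incremental comparison of two strategies run under the same settings."""
    if (
        intervention.settings_id is not None
        and comparator.settings_id is not None
        and intervention.settings_id != comparator.settings_id
    ):
        raise ValueError(
            "strategies were run under different settings: "
            f"{intervention.settings_id!r} vs {comparator.settings_id!r}"
        )
    d_cost = intervention.total_cost - comparator.total_cost
    d_qaly = intervention.total_qaly - comparator.total_qaly
    d_ly = intervention.total_ly - comparator.total_ly
    return CEAComparison(
        intervention=intervention.name,
        comparator=comparator.name,
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        delta_ly=d_ly,
        icer_per_qaly=_verdict(d_cost, d_qaly),
        icer_per_ly=_verdict(d_cost, d_ly),
    )
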