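"""One-way deterministic sensitivity scenarios.

Each scenario is a named set of parameter overrides (dotted paths into the
configuration) applied to the calibrated base case; the model is rerun and
the incremental comparison recorded.  Calibration is NOT redone per
scenario: the excess cancer mortality and the 80+ utility anchored in the
base case are held fixed, so a scenario isolates the effect of the one
assumption it changes.

The default list mirrors the published sensitivity analysis: discount rates
0% and 5%, start ages 60 and 70, equal sepsis risk, equal infection and
sepsis risk, no same-day implantation/imaging for the intervention, and a
one-year horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import pandas as pd

from .cea import format_icer
from .config import copy_config, set_by_path

__all__ = ["Scenario", "apply_scenario", "default_scenarios", "run_all"]


@dataclass(frozen=True)
class Scenario:
    """A named one-way deviation from the base configuration."""

    name: str
    overrides: Mapping[str, Any] = field(default_factory=dict)


def apply_scenario(base: dict, scenario: Scenario) -> dict:
    """Deep-copied configuration with the overrides applied; base untouched."""
    cfg = copy_config(base)
    for path, value in scenario.overrides.items():
        set_by_path(cfg, path, value)
    return cfg


def default_scenarios(base: dict) -> list[Scenario]:
    """The eight published one-way scenarios, anchored to the base config.

    Risk-equalizing scenarios copy the comparator's current values rather
    than hard-coding them, so they stay consistent if the comparator's
    pooled risks are overridden.
    """
    interv = base["intervention"]
    comp_block = base["strategies"][base["comparator"]]
    p = f"strategies.{interv}"
    return [
        Scenario("Discount rate 0%", {"settings.discount_rate": 0.0}),
        Scenario("Discount rate 5%", {"settings.discount_rate": 0.05}),
        Scenario("Starting age 60 years", {"settings.start_age": 60}),
        Scenario("Starting age 70 years", {"settings.start_age": 70}),
        Scenario(
            "No sepsis difference",
            {f"{p}.p_sepsis_given_infection": comp_block["p_sepsis_given_infection"]},
        ),
        Scenario(
            "No infection and sepsis difference",
            {
                f"{p}.p_infection": comp_block["p_infection"],
                f"{p}.p_sepsis_given_infection": comp_block["p_sepsis_given_infection"],
            },
        ),
        Scenario(
            "Implantation and treatment planning on different days",
            {f"{p}.same_day_imaging": False, f"{p}.waiting_days": 6},
        ),
        Scenario("One-year time horizon", {"settings.horizon": 1}),
    ]


def run_all(
    base: dict,
    life=None,
    scenarios: list[Scenario] | None = None,
) -> pd.DataFrame:
    """Run the base case and every scenario; return a Table-3-shaped frame.

    ``base`` must already be calibrated (the pipeline does this); the same
    life table is reused throughout unless a scenario overrides the
    mortality model itself.
    """
    from .pipeline import evaluate_strategies  # deferred: pipeline imports us

    from .config import build_life_table

    if life is None:
        life = build_life_table(base)
    if scenarios is None:
        scenarios = default_scenarios(base)

    rows = []

    def add_row(label: str, cfg: dict) -> None:
        bundle = evaluate_strategies(cfg, life)
        cmp_ = bundle.comparison
        rows.append(
            {
                "scenario": label,
                "delta_cost_usd": cmp_.delta_cost,
                "delta_qaly": cmp_.delta_qaly,
                "delta_ly": cmp_.delta_ly,
                "icer_per_qaly": format_icer(cmp_.icer_per_qaly),
            }
        )

    add_row("Base case", base)
    for sc in scenarios:
        add_row(sc.name, apply_scenario(base, sc))
    return pd.DataFrame(rows)
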