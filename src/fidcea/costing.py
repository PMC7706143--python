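"""Expected first-cycle cost of a marker strategy, societal perspective.

All costs in the model are incurred at implantation time (cycle 0) and are
therefore undiscounted: the markers themselves, the implantation procedure,
antibiotic prophylaxis, expected analgesics, expected infection work-up and
treatment, expected sepsis care, and — for a strategy that cannot image on
the implantation day — the logistics of the extra treatment-planning visit
(travel, expected rebooking administration, optionally a sick-leave day).

Unit costs are in USD (the source converts SEK at a fixed 8.65 SEK/USD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .markov_engine import FirstCycleOutcomes, StrategyRisks

__all__ = [
    "CostSchedule",
    "CostBreakdown",
    "MissingPriceError",
    "visit_logistics_cost",
    "first_cycle_expected_cost",
]


class MissingPriceError(ValueError):
    """A required unit price (e.g. the censored 22G marker price) is absent."""


@dataclass(frozen=True)
class CostSchedule:
    """Unit costs (USD) and resource usage for both strategies."""

    marker_unit_cost_22g: float | None = None  # censored at source
    marker_unit_cost_17g: float = 28.0
    implantation: float = 493.0
    prophylaxis: float = 2.0
    analgesics: float = 22.0
    antibiotic_treatment: float = 15.0
    sepsis_treatment: float = 6276.0
    admin_per_hour: float = 25.0
    sick_leave_per_day: float = 250.0
    travel_per_10km: float = 2.0
    round_trip_km: float = 130.0
    rebook_probability: float = 0.015
    rebook_hours: float = 0.71
    infection_doctor_visits: float = 1.5
    infection_visit_cost: float = 200.0
    sepsis_hospital_days: float = 12.0
    sick_leave_days_imaging: float = 1.0
    include_sick_leave_in_extra_visit: bool = False

    def __post_init__(self) -> None:
        for name in ("marker_unit_cost_17g", "implantation", "prophylaxis",
                     "analgesics", "antibiotic_treatment", "sepsis_treatment",
                     "admin_per_hour", "sick_leave_per_day", "travel_per_10km",
                     "round_trip_km", "rebook_hours", "infection_doctor_visits",
                     "infection_visit_cost", "sepsis_hospital_days",
                     "sick_leave_days_imaging"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.marker_unit_cost_22g is not None and self.marker_unit_cost_22g < 0:
            raise ValueError("marker_unit_cost_22g must be >= 0")
        if not 0.0 <= self.rebook_probability <= 1.0:
            raise ValueError("rebook_probability must be in [0, 1]")


@dataclass(frozen=True)
class CostBreakdown:
    """Itemized expected costs (USD); the total is the exact item sum."""

    items: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return sum(self.items.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"item": k, "expected_cost_usd": v} for k, v in self.items.items()]
        rows.append({"item": "total", "expected_cost_usd": self.total})
        return pd.DataFrame(rows)


def visit_logistics_cost(same_day: bool, schedule: CostSchedule) -> float:
    """Cost of the extra treatment-planning imaging visit, if one is needed.

    With same-day implantation and imaging there is no extra visit and the
    cost is 0.  Otherwise the visit costs one extra round trip plus the
    expected rebooking administration; a sick-leave day is included only
    when the schedule says so (off by default — the visit is short and the
    base analysis attributes no full absence day to it).
    """
    if same_day:
        return 0.0
    travel = schedule.round_trip_km / 10.0 * schedule.travel_per_10km
    rebooking = (schedule.rebook_probability * schedule.rebook_hours
                 * schedule.admin_per_hour)
    sick_leave = 0.0
    if schedule.include_sick_leave_in_extra_visit:
        sick_leave = schedule.sick_leave_days_imaging * schedule.sick_leave_per_day
    return travel + rebooking + sick_leave


def first_cycle_expected_cost(
    risks: StrategyRisks,
    outcomes: FirstCycleOutcomes,
    schedule: CostSchedule,
    visit_cost_infection: float | None = None,
    marker_unit_cost: float | None = None,
) -> CostBreakdown:
    """Expected cost of one strategy's first cycle; later cycles cost nothing.

    Parameters
    ----------
    visit_cost_infection : float, optional
        Unit cost of one doctor visit for a suspected infection; defaults to
        ``schedule.infection_visit_cost``.
    marker_unit_cost : float, optional
        Per-marker price for this strategy; defaults to
        ``risks.marker_unit_cost``.  Required — the 22G price is censored in
        the source and must be supplied explicitly.
    """
    unit_cost = marker_unit_cost if marker_unit_cost is not None else risks.marker_unit_cost
    if unit_cost is None:
        raise MissingPriceError(
            f"strategy {risks.name!r}: marker unit price not supplied "
            "(the Gold Anchor 22G price is censored and must be user-provided)"
        )
    visit_cost = (visit_cost_infection if visit_cost_infection is not None
                  else schedule.infection_visit_cost)
    p_sepsis = outcomes.p_sepsis_survive + outcomes.p_sepsis_death
    items = {
        "markers": risks.markers_used * unit_cost,
        "implantation": schedule.implantation,
        "prophylaxis": schedule.prophylaxis,
        "analgesics": risks.p_analgesics * schedule.analgesics,
        "infection_care": risks.p_infection
        * (schedule.infection_doctor_visits * visit_cost
           + schedule.antibiotic_treatment),
        "sepsis_care": p_sepsis * schedule.sepsis_treatment,
        "imaging_visit_logistics": visit_logistics_cost(risks.same_day_imaging, schedule),
    }
    return CostBreakdown(items=items)
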