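"""Synthetic inputs: life tables, simulated study sets, parameter fixture.

The published analysis rests on three inputs that cannot be redistributed
here: a national male life table, the per-study complication counts behind
the meta-analysis, and a parameter table of risks, utilities and unit costs.
This module generates faithful stand-ins for all three so that every
downstream stage runs and is testable offline.

* :func:`make_life_table` builds a Gompertz–Makeham life table — a constant
  background hazard plus an exponentially age-increasing component, the
  standard 3-parameter description of adult mortality.
* :func:`simulate_study_set` draws single-arm binomial studies around a
  common log-odds with Normal between-study heterogeneity, the generative
  model the DerSimonian–Laird pooling stage assumes.
* :func:`reference_fixture` returns the published parameter set (risks,
  resource usage, unit costs, utility weights) as one nested mapping.  The
  Gold Anchor 22G per-marker price is censored in the source and is stored
  as ``None`` unless supplied by the caller; costing the 22G arm without it
  fails loudly downstream.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .life_table import LifeTable
from .risk_pooling import StudyCounts

__all__ = [
    "MortalityModel",
    "StudySetSpec",
    "make_life_table",
    "simulate_study_set",
    "reference_fixture",
]


@dataclass(frozen=True)
class MortalityModel:
    """Gompertz–Makeham hazard: h(a) = makeham + scale * exp(shape * a).

    The annual death probability is q(a) = 1 - exp(-h(a)), which is always
    in [0, 1] and non-decreasing in age for non-negative parameters.
    Defaults emulate the mortality of men in a contemporary high-income
    country (remaining life expectancy at 65 close to 19 years).
    """

    makeham_constant: float = 5.0e-4
    gompertz_scale: float = 1.2e-5
    gompertz_shape: float = 0.104
    max_age: int = 105

    def __post_init__(self) -> None:
        for name in ("makeham_constant", "gompertz_scale", "gompertz_shape"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.makeham_constant < 0:
            raise ValueError("makeham_constant must be >= 0")
        if self.gompertz_scale < 0:
            raise ValueError("gompertz_scale must be >= 0")
        if self.gompertz_shape < 0:
            raise ValueError("gompertz_shape must be >= 0")
        if self.max_age < 1:
            raise ValueError("max_age must be >= 1")

    def hazard(self, age: np.ndarray | float) -> np.ndarray | float:
        return self.makeham_constant + self.gompertz_scale * np.exp(
            self.gompertz_shape * np.asarray(age, dtype=float)
        )

    def annual_death_probability(self, age: np.ndarray | float) -> np.ndarray | float:
        return 1.0 - np.exp(-self.hazard(age))


def make_life_table(model: MortalityModel) -> LifeTable:
    """Tabulate q(a) for ages 0..max_age; the terminal q is forced to 1.

    Forcing q(max_age) = 1 guarantees cohort extinction in a lifetime-horizon
    run regardless of how heavy the tail of the hazard is.
    """
    ages = np.arange(model.max_age + 1)
    qx = np.clip(np.asarray(model.annual_death_probability(ages)), 0.0, 1.0)
    qx[-1] = 1.0
    return LifeTable(pd.DataFrame({"age": ages, "qx": qx}))


@dataclass(frozen=True)
class StudySetSpec:
    """Generative settings for one simulated set of single-arm studies.

    Each study's true log-odds is Normal(true_logit_mean, between_study_sd);
    between_study_sd**2 is the tau-squared the pooling stage estimates.
    """

    n_studies: int
    true_logit_mean: float
    between_study_sd: float
    denominators: tuple[int, ...] | int
    seed: int

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if self.between_study_sd < 0:
            raise ValueError("between_study_sd must be >= 0")
        dens = self.denominators
        if isinstance(dens, int):
            dens = (dens,) * self.n_studies
        else:
            dens = tuple(int(d) for d in dens)
        if len(dens) != self.n_studies:
            raise ValueError("need one denominator per study")
        if any(d < 1 for d in dens):
            raise ValueError("denominators must be positive")
        object.__setattr__(self, "denominators", dens)


def simulate_study_set(spec: StudySetSpec) -> list[StudyCounts]:
    """Draw one study set; reproducible for a fixed spec (seed included)."""
    rng = np.random.default_rng(spec.seed)
    logits = rng.normal(spec.true_logit_mean, spec.between_study_sd, spec.n_studies)
    probs = 1.0 / (1.0 + np.exp(-logits))
    ns = np.asarray(spec.denominators)
    events = rng.binomial(ns, probs)
    return [
        StudyCounts(study_id=f"sim{i + 1:02d}", events=int(e), denominator=int(n))
        for i, (e, n) in enumerate(zip(events, ns))
    ]


# Published parameter set: first-cycle risks and logistics per strategy,
# the societal cost schedule, and the utility block.  The 22G marker price
# is censored at source; the infection-visit unit cost is cited from a
# regional price list without a printed figure and defaults to a typical
# specialist outpatient tariff (documented assumption, configurable).
_REFERENCE_PARAMETERS: dict = {
    "strategies": {
        "gold_anchor_22g": {
            "p_infection": 0.003,
            "p_sepsis_given_infection": 0.0,
            "p_death_given_sepsis": 0.186,
            "p_analgesics": 0.4,
            "same_day_imaging": True,
            "waiting_days": 6,
            "markers_used": 3.0,
            "marker_unit_cost": None,  # censored; must be user-supplied
        },
        "comparator_17_18g": {
            "p_infection": 0.024,
            "p_sepsis_given_infection": 0.285,
            "p_death_given_sepsis": 0.186,
            "p_analgesics": 0.73,
            "same_day_imaging": False,
            "waiting_days": 6,
            "markers_used": 3.3,
            "marker_unit_cost": 28.0,
        },
    },
    "costs": {
        "implantation": 493.0,
        "prophylaxis": 2.0,
        "analgesics": 22.0,
        "antibiotic_treatment": 15.0,
        "sepsis_treatment": 6276.0,
        "admin_per_hour": 25.0,
        "sick_leave_per_day": 250.0,
        "travel_per_10km": 2.0,
        "round_trip_km": 130.0,
        "rebook_probability": 0.015,
        "rebook_hours": 0.71,
        "infection_doctor_visits": 1.5,
        "infection_visit_cost": 200.0,  # assumption: regional tariff unprinted
        "sick_leave_days_imaging": 1.0,
        "include_sick_leave_in_extra_visit": False,
    },
    "utilities": {
        "age_band_utilities": {50: 0.845, 60: 0.829, 70: 0.797},
        "old_age_utility": 0.797,  # 80+ band unpublished; calibrated in the pipeline
        "cancer_decrement": 0.1,
        "waiting_decrement": 0.1,
        "u_sepsis_hospital": 0.53,
        "u_sepsis_first_year": 0.62,
        "sepsis_hospital_days": 12,
    },
    "settings": {
        "start_age": 65,
        "discount_rate": 0.03,
        "horizon": "lifetime",
        "excess_cancer_mortality": 0.0,  # unpublished; calibrated in the pipeline
    },
    "calibration": {
        "comparator_life_years": 13.459,
        "comparator_qalys": 9.273,
    },
}


def reference_fixture(marker_unit_cost_22g: float | None = None) -> dict:
    """Return the published parameter set as a nested mapping.

    Parameters
    ----------
    marker_unit_cost_22g : float, optional
        Per-marker price of the Gold Anchor 22G marker.  Censored in the
        source; when omitted the fixture stores ``None`` and costing that
        arm raises an explicit error.
    """
    params = copy.deepcopy(_REFERENCE_PARAMETERS)
    if marker_unit_cost_22g is not None:
        if marker_unit_cost_22g < 0:
            raise ValueError("marker_unit_cost_22g must be >= 0")
        params["strategies"]["gold_anchor_22g"]["marker_unit_cost"] = float(
            marker_unit_cost_22g
        )
    _validate_fixture(params)
    return params


def _validate_fixture(params: dict) -> None:
    for name, strat in params["strategies"].items():
        for key in ("p_infection", "p_sepsis_given_infection", "p_death_given_sepsis", "p_analgesics"):
            p = strat[key]
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}.{key}={p} outside [0, 1]")
        if strat["markers_used"] < 0 or strat["waiting_days"] < 0:
            raise ValueError(f"{name}: counts must be >= 0")
        if strat["marker_unit_cost"] is not None and strat["marker_unit_cost"] < 0:
            raise ValueError(f"{name}: marker_unit_cost must be >= 0")
    for key, v in params["costs"].items():
        if isinstance(v, bool):
            continue
        if v < 0:
            raise ValueError(f"costs.{key}={v} must be >= 0")
    util = params["utilities"]
    for u in list(util["age_band_utilities"].values()) + [
        util["old_age_utility"], util["u_sepsis_hospital"], util["u_sepsis_first_year"]
    ]:
        if not 0.0 <= u <= 1.0:
            raise ValueError(f"utility {u} outside [0, 1]")
    if util["cancer_decrement"] < 0 or util["waiting_decrement"] < 0:
        raise ValueError("utility decrements must be >= 0")
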