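"""Configuration handling: YAML round-trip, validation, typed builders.

One YAML document drives the whole pipeline.  It contains the parameter
fixture blocks (``strategies``, ``costs``, ``utilities``, ``settings``,
``calibration``) plus run plumbing: a ``mortality_model`` block (or a
``life_table_csv`` path overriding it), the intervention/comparator
strategy names, and a ``seed``.  Every run writes the fully resolved
configuration next to its outputs so reruns are audit-reproducible.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

from .costing import CostSchedule
from .life_table import LifeTable
from .markov_engine import ModelSettings, StrategyRisks, UtilityProfile
from .synthetic_data import MortalityModel, make_life_table, reference_fixture

__all__ = [
    "default_config",
    "load_config",
    "save_config",
    "validate_config",
    "get_by_path",
    "set_by_path",
    "build_strategy",
    "build_utilities",
    "build_settings",
    "build_cost_schedule",
    "build_life_table",
]

_REQUIRED_BLOCKS = ("strategies", "costs", "utilities", "settings", "calibration")


def default_config(marker_unit_cost_22g: float | None = None) -> dict:
    """Demo configuration: the published parameter set plus run plumbing."""
    cfg = reference_fixture(marker_unit_cost_22g)
    cfg["mortality_model"] = {
        "makeham_constant": 5.0e-4,
        "gompertz_scale": 1.2e-5,
        "gompertz_shape": 0.104,
        "max_age": 105,
    }
    cfg["life_table_csv"] = None
    cfg["intervention"] = "gold_anchor_22g"
    cfg["comparator"] = "comparator_17_18g"
    cfg["seed"] = 1
    return cfg


def validate_config(cfg: dict) -> dict:
    """Check the schema before any computation; returns the config unchanged."""
    missing = [b for b in _REQUIRED_BLOCKS if b not in cfg]
    if missing:
        raise ValueError(f"configuration missing blocks: {missing}")
    for role in ("intervention", "comparator"):
        name = cfg.get(role)
        if name not in cfg["strategies"]:
            raise ValueError(f"{role} strategy {name!r} not found under 'strategies'")
    if cfg.get("life_table_csv") is None and "mortality_model" not in cfg:
        raise ValueError("configuration needs 'mortality_model' or 'life_table_csv'")
    # typed builders perform the value-level validation
    for name in cfg["strategies"]:
        build_strategy(cfg, name)
    build_utilities(cfg)
    build_settings(cfg)
    build_cost_schedule(cfg)
    return cfg


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a YAML mapping at top level")
    return validate_config(cfg)


def save_config(cfg: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def get_by_path(cfg: dict, path: str) -> Any:
    node: Any = cfg
    for part in path.split("."):
        key: Any = part
        if isinstance(node, dict) and key not in node and part.isdigit():
            key = int(part)
        if not isinstance(node, dict) or key not in node:
            raise KeyError(f"unknown parameter path {path!r} (failed at {part!r})")
        node = node[key]
    return node


def set_by_path(cfg: dict, path: str, value: Any) -> None:
    """Set an existing leaf by dotted path; unknown paths are rejected."""
    parts = path.split(".")
    node: Any = cfg
    for part in parts[:-1]:
        key: Any = part
        if isinstance(node, dict) and key not in node and part.isdigit():
            key = int(part)
        if not isinstance(node, dict) or key not in node:
            raise KeyError(f"unknown parameter path {path!r} (failed at {part!r})")
        node = node[key]
    leaf: Any = parts[-1]
    if isinstance(node, dict) and leaf not in node and parts[-1].isdigit():
        leaf = int(parts[-1])
    if not isinstance(node, dict) or leaf not in node:
        raise KeyError(f"unknown parameter path {path!r} (failed at {parts[-1]!r})")
    node[leaf] = value


def build_strategy(cfg: dict, name: str) -> StrategyRisks:
    block = cfg["strategies"][name]
    return StrategyRisks(
        name=name,
        p_infection=block["p_infection"],
        p_sepsis_given_infection=block["p_sepsis_given_infection"],
        p_death_given_sepsis=block["p_death_given_sepsis"],
        p_analgesics=block.get("p_analgesics", 0.0),
        same_day_imaging=block.get("same_day_imaging", True),
        waiting_days=block.get("waiting_days", 0.0),
        markers_used=block.get("markers_used", 0.0),
        marker_unit_cost=block.get("marker_unit_cost"),
    )


def build_utilities(cfg: dict) -> UtilityProfile:
    u = cfg["utilities"]
    return UtilityProfile(
        age_band_utilities={int(k): float(v) for k, v in u["age_band_utilities"].items()},
        old_age_utility=u["old_age_utility"],
        cancer_decrement=u["cancer_decrement"],
        waiting_decrement=u["waiting_decrement"],
        u_sepsis_hospital=u["u_sepsis_hospital"],
        u_sepsis_first_year=u["u_sepsis_first_year"],
        sepsis_hospital_days=u["sepsis_hospital_days"],
    )


def build_settings(cfg: dict) -> ModelSettings:
    s = cfg["settings"]
    return ModelSettings(
        start_age=s["start_age"],
        discount_rate=s["discount_rate"],
        horizon=s["horizon"],
        excess_cancer_mortality=s.get("excess_cancer_mortality", 0.0),
        half_cycle_credit=s.get("half_cycle_credit", True),
    )


def build_cost_schedule(cfg: dict) -> CostSchedule:
    c = cfg["costs"]
    strategies = cfg["strategies"]
    return CostSchedule(
        marker_unit_cost_22g=strategies.get("gold_anchor_22g", {}).get("marker_unit_cost"),
        marker_unit_cost_17g=strategies.get("comparator_17_18g", {}).get(
            "marker_unit_cost", 28.0
        )
        or 28.0,
        implantation=c["implantation"],
        prophylaxis=c["prophylaxis"],
        analgesics=c["analgesics"],
        antibiotic_treatment=c["antibiotic_treatment"],
        sepsis_treatment=c["sepsis_treatment"],
        admin_per_hour=c["admin_per_hour"],
        sick_leave_per_day=c["sick_leave_per_day"],
        travel_per_10km=c["travel_per_10km"],
        round_trip_km=c["round_trip_km"],
        rebook_probability=c["rebook_probability"],
        rebook_hours=c["rebook_hours"],
        infection_doctor_visits=c["infection_doctor_visits"],
        infection_visit_cost=c["infection_visit_cost"],
        sepsis_hospital_days=cfg["utilities"].get("sepsis_hospital_days", 12.0),
        sick_leave_days_imaging=c.get("sick_leave_days_imaging", 1.0),
        include_sick_leave_in_extra_visit=c.get("include_sick_leave_in_extra_visit", False),
    )


def build_life_table(cfg: dict) -> LifeTable:
    if cfg.get("life_table_csv"):
        return LifeTable.from_csv(cfg["life_table_csv"])
    m = cfg["mortality_model"]
    return make_life_table(
        MortalityModel(
            makeham_constant=m["makeham_constant"],
            gompertz_scale=m["gompertz_scale"],
            gompertz_shape=m["gompertz_shape"],
            max_age=m["max_age"],
        )
    )


def copy_config(cfg: dict) -> dict:
    return copy.deepcopy(cfg)
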