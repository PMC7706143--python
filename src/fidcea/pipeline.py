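"""End-to-end pipeline: pool → calibrate → run both arms → compare → scenarios.

The pipeline is deterministic given a configuration: it builds (or loads)
the life table, calibrates the unpublished excess cancer mortality and 80+
utility so the comparator arm reproduces the external anchor totals, runs
both strategies through the cohort model and costing, and emits the
base-case and sensitivity tables as CSV, together with the fully resolved
configuration and a parameter-echo log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import costing
from .cea import CEAComparison, StrategyResult, compare, format_icer
from .config import (
    build_cost_schedule,
    build_life_table,
    build_settings,
    build_strategy,
    build_utilities,
    copy_config,
    save_config,
    validate_config,
)
from .costing import CostBreakdown, MissingPriceError
from .life_table import LifeTable
from .markov_engine import (
    MarkovTrace,
    calibrate_excess_mortality,
    calibrate_old_age_utility,
    first_cycle_outcomes,
    run_model,
)
from .risk_pooling import forest_table, pool_random_effects, read_studies_csv

__all__ = ["ResultBundle", "evaluate_strategies", "calibrate_base", "run_pipeline"]

logger = logging.getLogger("fidcea")


@dataclass
class ResultBundle:
    """Everything one evaluation of a configuration produces."""

    results: dict[str, StrategyResult]
    traces: dict[str, MarkovTrace]
    breakdowns: dict[str, CostBreakdown | None]
    comparison: CEAComparison
    config: dict = field(repr=False)

    def table2(self) -> pd.DataFrame:
        """Per-strategy totals plus increments, base-case-results layout."""
        interv = self.config["intervention"]
        comp = self.config["comparator"]
        rows = []
        for name in (interv, comp):
            r = self.results[name]
            is_interv = name == interv
            rows.append(
                {
                    "strategy": name,
                    "cost_usd": r.total_cost,
                    "delta_cost_usd": self.comparison.delta_cost if is_interv else None,
                    "qaly": r.total_qaly,
                    "delta_qaly": self.comparison.delta_qaly if is_interv else None,
                    "life_years": r.total_ly,
                    "delta_life_years": self.comparison.delta_ly if is_interv else None,
                    "icer_per_ly": format_icer(self.comparison.icer_per_ly)
                    if is_interv
                    else None,
                    "icer_per_qaly": format_icer(self.comparison.icer_per_qaly)
                    if is_interv
                    else None,
                }
            )
        return pd.DataFrame(rows)


def evaluate_strategies(
    cfg: dict, life: LifeTable, with_costs: bool | str = "auto"
) -> ResultBundle:
    """Run both configured strategies through the model and costing.

    ``with_costs="auto"`` skips costing (totals 0, no breakdown) only when a
    required marker price is missing; ``with_costs=False`` skips it always;
    ``with_costs=True`` makes a missing price a hard error.
    """
    util = build_utilities(cfg)
    settings = build_settings(cfg)
    schedule = build_cost_schedule(cfg)
    settings_id = repr(settings)

    results: dict[str, StrategyResult] = {}
    traces: dict[str, MarkovTrace] = {}
    breakdowns: dict[str, CostBreakdown | None] = {}
    for role in ("intervention", "comparator"):
        name = cfg[role]
        risks = build_strategy(cfg, name)
        trace = run_model(risks, life, util, settings)
        breakdown: CostBreakdown | None = None
        total_cost = 0.0
        if with_costs is True or with_costs == "auto":
            try:
                breakdown = costing.first_cycle_expected_cost(
                    risks, first_cycle_outcomes(risks), schedule
                )
                total_cost = breakdown.total
            except MissingPriceError:
                if with_costs is True:
                    raise
                logger.warning(
                    "strategy %s: marker price missing, reporting effects only", name
                )
        results[name] = StrategyResult(
            name=name,
            total_cost=total_cost,
            total_qaly=trace.total_qaly,
            total_ly=trace.total_ly,
            settings_id=settings_id,
        )
        traces[name] = trace
        breakdowns[name] = breakdown

    comparison = compare(results[cfg["intervention"]], results[cfg["comparator"]])
    return ResultBundle(results, traces, breakdowns, comparison, cfg)


def calibrate_base(cfg: dict, life: LifeTable | None = None) -> dict:
    """Anchor the unpublished knobs on the comparator arm's target totals.

    Returns a deep-copied configuration whose ``settings.excess_cancer_
    mortality`` and ``utilities.old_age_utility`` make the comparator arm's
    discounted life years and QALYs hit the configured calibration targets.
    """
    cfg = copy_config(cfg)
    if life is None:
        life = build_life_table(cfg)
    risks = build_strategy(cfg, cfg["comparator"])
    util = build_utilities(cfg)
    settings = build_settings(cfg)
    targets = cfg["calibration"]

    excess = calibrate_excess_mortality(
        life, util, settings, risks, targets["comparator_life_years"]
    )
    cfg["settings"]["excess_cancer_mortality"] = excess
    settings = replace(settings, excess_cancer_mortality=excess)
    logger.info("calibrated excess cancer mortality: %.6f", excess)

    u80 = calibrate_old_age_utility(
        life, util, settings, risks, targets["comparator_qalys"]
    )
    cfg["utilities"]["old_age_utility"] = u80
    logger.info("calibrated 80+ utility: %.6f", u80)
    return cfg


def run_pipeline(cfg: dict, outdir, studies_csv=None) -> ResultBundle:
    """Validate, calibrate, run, and write the full result bundle to disk."""
    from .scenarios import run_all  # deferred: scenarios imports us

    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        life = build_life_table(cfg)
        life.to_csv(outdir / "life_table.csv")
        logger.info(
            "life table: ages %d-%d, terminal qx %.3f",
            life.min_age, life.max_age, life.terminal_qx,
        )

        if studies_csv is not None:
            studies = read_studies_csv(studies_csv)
            pooled = pool_random_effects(studies)
            forest_table(studies, pooled).to_csv(outdir / "pooled_risk.csv", index=False)
            logger.info(
                "pooled %d studies: probability %.4f (tau2 %.4f)",
                pooled.n_studies, pooled.pooled_probability, pooled.tau_squared,
            )

        cfg = calibrate_base(cfg, life)
        bundle = evaluate_strategies(cfg, life)
        for name, trace in bundle.traces.items():
            trace.to_csv(outdir / f"trace_{name}.csv")
        for name, bd in bundle.breakdowns.items():
            if bd is not None:
                bd.to_frame().to_csv(outdir / f"costs_{name}.csv", index=False)
        bundle.table2().to_csv(outdir / "base_case_results.csv", index=False)
        logger.info(
            "base case: delta cost %.2f USD, delta QALY %.4f, delta LY %.4f",
            bundle.comparison.delta_cost,
            bundle.comparison.delta_qaly,
            bundle.comparison.delta_ly,
        )

        run_all(cfg, life).to_csv(outdir / "sensitivity_results.csv", index=False)
        save_config(cfg, outdir / "resolved_config.yaml")
        return bundle
    finally:
        logger.removeHandler(handler)
        handler.close()
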