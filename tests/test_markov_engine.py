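"""First-cycle decision tree, cohort cycles, discounting, calibration."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fidcea import (
    LifeTable,
    ModelSettings,
    MortalityModel,
    StrategyRisks,
    UtilityProfile,
    calibrate_excess_mortality,
    calibrate_old_age_utility,
    discount_factor,
    first_cycle_outcomes,
    make_life_table,
    run_model,
)
from fidcea.markov_engine import CalibrationError

COMPARATOR = StrategyRisks(
    "comp", p_infection=0.024, p_sepsis_given_infection=0.285,
    p_death_given_sepsis=0.186, p_analgesics=0.73,
    same_day_imaging=False, waiting_days=6, markers_used=3.3,
)
GOLD_ANCHOR = StrategyRisks(
    "ga", p_infection=0.003, p_sepsis_given_infection=0.0,
    p_death_given_sepsis=0.186, p_analgesics=0.4,
    same_day_imaging=True, waiting_days=6, markers_used=3.0,
)


def flat_life_table(qx=0.0, lo=0, hi=200):
    ages = np.arange(lo, hi + 1)
    q = np.full(len(ages), float(qx))
    q[-1] = 1.0
    return LifeTable(pd.DataFrame({"age": ages, "qx": q}))


class TestFirstCycleOutcomes:
    def test_comparator_pathway_probabilities(self):
        fc = first_cycle_outcomes(COMPARATOR)
        assert fc.p_sepsis_death == pytest.approx(0.024 * 0.285 * 0.186, abs=1e-15)
        assert fc.p_sepsis_survive == pytest.approx(0.024 * 0.285 * 0.814, abs=1e-15)
        assert fc.p_infection_only == pytest.approx(0.024 * 0.715, abs=1e-15)
        assert fc.p_no_event == pytest.approx(0.976, abs=1e-15)

    def test_zero_sepsis_risk_means_no_sepsis_deaths(self):
        fc = first_cycle_outcomes(GOLD_ANCHOR)
        assert fc.p_sepsis_death == 0.0
        assert fc.p_sepsis_survive == 0.0

    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)
    )
    def test_outcomes_partition_unity(self, p_inf, p_sep, p_die):
        fc = first_cycle_outcomes(
            StrategyRisks("x", p_inf, p_sep, p_die)
        )
        total = fc.p_no_event + fc.p_infection_only + fc.p_sepsis_survive + fc.p_sepsis_death
        assert total == pytest.approx(1.0, abs=1e-12)


class TestDiscounting:
    @pytest.mark.parametrize(
        "t,rate,expected",
        [(0, 0.03, 1.0), (1, 0.03, 1 / 1.03), (5, 0.0, 1.0), (2, 0.05, 1.05**-2)],
    )
    def test_factor(self, t, rate, expected):
        assert discount_factor(t, rate) == pytest.approx(expected, rel=1e-15)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.03)
        with pytest.raises(ValueError):
            discount_factor(1, -1.0)


class TestRunModel:
    def _neutral(self):
        util = UtilityProfile(
            age_band_utilities={0: 1.0}, old_age_utility=1.0,
            cancer_decrement=0.0, waiting_decrement=0.0,
        )
        risks = StrategyRisks("none", 0.0, 0.0, 0.0)
        return risks, util

    def test_identity_cohort_accrues_one_year_per_cycle(self):
        risks, util = self._neutral()
        settings = ModelSettings(start_age=65, discount_rate=0.0, horizon=10)
        trace = run_model(risks, flat_life_table(), util, settings)
        assert trace.total_ly == pytest.approx(10.0, abs=1e-12)
        assert trace.total_qaly == pytest.approx(10.0, abs=1e-12)

    def test_full_survival_matches_geometric_annuity(self):
        risks, util = self._neutral()
        T, r = 25, 0.03
        settings = ModelSettings(start_age=60, discount_rate=r, horizon=T)
        trace = run_model(risks, flat_life_table(), util, settings)
        annuity = sum((1 + r) ** (-t) for t in range(T))
        assert trace.total_ly == pytest.approx(annuity, abs=1e-12)

    def test_lifetime_run_extinguishes_cohort(self, life_table):
        util = UtilityProfile()
        settings = ModelSettings()
        trace = run_model(COMPARATOR, life_table, util, settings)
        alive = trace.trace["alive"].to_numpy()
        assert (np.diff(alive) <= 1e-15).all()
        assert alive[-1] == pytest.approx(0.0, abs=1e-12)

    def test_qaly_never_exceeds_life_years(self, life_table):
        trace = run_model(COMPARATOR, life_table, UtilityProfile(), ModelSettings())
        assert trace.total_qaly <= trace.total_ly
        assert trace.total_ly == pytest.approx(trace.trace["disc_ly"].sum())

    def test_more_infection_never_more_qalys(self, life_table):
        util, settings = UtilityProfile(), ModelSettings()
        q = [
            run_model(replace(COMPARATOR, p_infection=p), life_table, util, settings).total_qaly
            for p in (0.0, 0.1, 0.5, 1.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(q, q[1:]))

    def test_higher_discount_rate_never_raises_totals(self, life_table):
        util = UtilityProfile()
        totals = [
            run_model(COMPARATOR, life_table, util, ModelSettings(discount_rate=r))
            for r in (0.0, 0.03, 0.05)
        ]
        assert totals[0].total_ly >= totals[1].total_ly >= totals[2].total_ly
        assert totals[0].total_qaly >= totals[1].total_qaly >= totals[2].total_qaly

    def test_equal_risk_strategies_trace_identically(self, life_table):
        twin = replace(GOLD_ANCHOR, name="twin", p_infection=COMPARATOR.p_infection,
                       p_sepsis_given_infection=COMPARATOR.p_sepsis_given_infection,
                       same_day_imaging=False, waiting_days=6)
        ref = replace(COMPARATOR, name="ref")
        a = run_model(twin, life_table, UtilityProfile(), ModelSettings())
        b = run_model(ref, life_table, UtilityProfile(), ModelSettings())
        pd.testing.assert_frame_equal(a.trace, b.trace)

    def test_waiting_disutility_only_without_same_day_imaging(self, life_table):
        util, settings = UtilityProfile(), ModelSettings()
        waits = replace(GOLD_ANCHOR, same_day_imaging=False)
        q_wait = run_model(waits, life_table, util, settings).total_qaly
        q_same = run_model(GOLD_ANCHOR, life_table, util, settings).total_qaly
        assert q_same - q_wait == pytest.approx(6 / 365 * 0.1, abs=1e-12)

    def test_invalid_horizon_or_start_age_rejected(self, life_table):
        with pytest.raises(ValueError):
            ModelSettings(horizon=0)
        with pytest.raises(ValueError):
            run_model(COMPARATOR, life_table, UtilityProfile(),
                      ModelSettings(start_age=500))

    def test_lifetime_needs_terminal_qx_one(self):
        ages = np.arange(60, 80)
        open_table = LifeTable(pd.DataFrame({"age": ages, "qx": np.full(20, 0.01)}))
        with pytest.raises(ValueError, match="terminal"):
            run_model(COMPARATOR, open_table, UtilityProfile(), ModelSettings())


class TestCalibration:
    def test_excess_zero_is_fixed_point(self, life_table):
        util, settings = UtilityProfile(), ModelSettings()
        base_ly = run_model(COMPARATOR, life_table, util, settings).total_ly
        excess = calibrate_excess_mortality(life_table, util, settings, COMPARATOR, base_ly)
        assert excess == pytest.approx(0.0, abs=1e-5)

    def test_excess_round_trip_recovery(self, life_table):
        util = UtilityProfile()
        target = run_model(
            COMPARATOR, life_table, util, ModelSettings(excess_cancer_mortality=0.01)
        ).total_ly
        recovered = calibrate_excess_mortality(
            life_table, util, ModelSettings(), COMPARATOR, target
        )
        assert recovered == pytest.approx(0.01, abs=1e-4)

    def test_unreachable_ly_target_diagnosed(self, life_table):
        util, settings = UtilityProfile(), ModelSettings()
        too_high = run_model(COMPARATOR, life_table, util, settings).total_ly + 5.0
        with pytest.raises(CalibrationError):
            calibrate_excess_mortality(life_table, util, settings, COMPARATOR, too_high)

    def test_old_age_utility_fixed_point(self, life_table):
        util, settings = UtilityProfile(old_age_utility=0.797), ModelSettings()
        target = run_model(COMPARATOR, life_table, util, settings).total_qaly
        u80 = calibrate_old_age_utility(life_table, util, settings, COMPARATOR, target)
        assert u80 == pytest.approx(0.797, abs=1e-4)

    def test_old_age_utility_round_trip(self, life_table):
        settings = ModelSettings()
        target = run_model(
            COMPARATOR, life_table, UtilityProfile(old_age_utility=0.64), settings
        ).total_qaly
        u80 = calibrate_old_age_utility(
            life_table, UtilityProfile(), settings, COMPARATOR, target
        )
        assert u80 == pytest.approx(0.64, abs=1e-4)

    def test_unreachable_qaly_target_diagnosed(self, life_table):
        settings = ModelSettings()
        hi = run_model(
            COMPARATOR, life_table, UtilityProfile(old_age_utility=1.0), settings
        ).total_qaly
        with pytest.raises(CalibrationError):
            calibrate_old_age_utility(
                life_table, UtilityProfile(), settings, COMPARATOR, hi + 1.0
            )
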