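"""Decision-tree first cycle plus lifetime alive/dead Markov cohort model.

The model follows a cohort of prostate-cancer patients from fiducial-marker
implantation to death.  All implantation complications (infection, sepsis,
sepsis death) resolve within the first annual cycle, branching the cohort
through a small decision tree; every later cycle is a plain alive/dead
Markov step driven by the background life table plus a constant additive
excess annual death probability for prostate cancer.

Quality weights are age-band EQ-5D population norms minus a lifelong cancer
decrement; sepsis survivors spend the hospital days at the in-hospital
weight and the remainder of the first year at the first-year-after-sepsis
weight.  A strategy without same-day implantation and imaging carries a
waiting-time anxiety decrement for the waiting days of cycle 0.

Life years and QALYs are discounted per cycle at a fixed annual rate; a
member dying within a cycle receives half that cycle's credit (half-cycle
convention, switchable via ``ModelSettings.half_cycle_credit``).

Two calibration routines pin the unpublished quantities — the excess cancer
mortality and the 80+ utility band — to externally given totals by
bisection, exploiting monotonicity of the totals in each knob.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .life_table import LifeTable

__all__ = [
    "StrategyRisks",
    "UtilityProfile",
    "ModelSettings",
    "FirstCycleOutcomes",
    "MarkovTrace",
    "CalibrationError",
    "first_cycle_outcomes",
    "discount_factor",
    "run_model",
    "calibrate_excess_mortality",
    "calibrate_old_age_utility",
]

DAYS_PER_YEAR = 365.0


def _check_probability(name: str, p: float) -> None:
    if not (math.isfinite(p) and 0.0 <= p <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {p!r}")


@dataclass(frozen=True)
class StrategyRisks:
    """First-cycle event probabilities and logistics of one marker strategy."""

    name: str
    p_infection: float
    p_sepsis_given_infection: float
    p_death_given_sepsis: float
    p_analgesics: float = 0.0
    same_day_imaging: bool = True
    waiting_days: float = 0.0
    markers_used: float = 0.0
    marker_unit_cost: float | None = None

    def __post_init__(self) -> None:
        for attr in ("p_infection", "p_sepsis_given_infection",
                     "p_death_given_sepsis", "p_analgesics"):
            _check_probability(f"{self.name}.{attr}", getattr(self, attr))
        if self.waiting_days < 0:
            raise ValueError(f"{self.name}: waiting_days must be >= 0")
        if self.markers_used < 0:
            raise ValueError(f"{self.name}: markers_used must be >= 0")

    @property
    def p_sepsis(self) -> float:
        """Marginal first-cycle sepsis probability."""
        return self.p_infection * self.p_sepsis_given_infection


@dataclass(frozen=True)
class UtilityProfile:
    """EQ-5D age-band weights, decrements and sepsis state utilities."""

    age_band_utilities: dict[int, float] = field(
        default_factory=lambda: {50: 0.845, 60: 0.829, 70: 0.797}
    )
    old_age_utility: float = 0.797  # 80+ band; calibrated when unpublished
    cancer_decrement: float = 0.1
    waiting_decrement: float = 0.1
    u_sepsis_hospital: float = 0.53
    u_sepsis_first_year: float = 0.62
    sepsis_hospital_days: float = 12.0

    def __post_init__(self) -> None:
        for band, u in sorted(self.age_band_utilities.items()):
            _check_probability(f"utility band {band}", u)
        _check_probability("old_age_utility", self.old_age_utility)
        _check_probability("u_sepsis_hospital", self.u_sepsis_hospital)
        _check_probability("u_sepsis_first_year", self.u_sepsis_first_year)
        if self.cancer_decrement < 0 or self.waiting_decrement < 0:
            raise ValueError("decrements must be >= 0")
        if not 0 <= self.sepsis_hospital_days <= DAYS_PER_YEAR:
            raise ValueError("sepsis_hospital_days must be within one year")

    def band_utility(self, age: float) -> float:
        """Age-band norm: bands are closed-open, ages 80+ use old_age_utility."""
        if age >= 80:
            return self.old_age_utility
        bands = sorted(self.age_band_utilities.items())
        value = bands[0][1]  # ages below the first band inherit its weight
        for lower, u in bands:
            if age >= lower:
                value = u
        return value

    def applied_utility(self, age: float) -> float:
        """Band utility minus the lifelong cancer decrement, floored at 0."""
        return max(0.0, self.band_utility(age) - self.cancer_decrement)


@dataclass(frozen=True)
class ModelSettings:
    """Cohort settings: start age, discounting, horizon, excess mortality."""

    start_age: int = 65
    discount_rate: float = 0.03
    horizon: int | str = "lifetime"
    excess_cancer_mortality: float = 0.0
    half_cycle_credit: bool = True

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if self.excess_cancer_mortality < 0:
            raise ValueError("excess_cancer_mortality must be >= 0")
        if isinstance(self.horizon, str):
            if self.horizon != "lifetime":
                raise ValueError("horizon must be a positive integer or 'lifetime'")
        elif self.horizon <= 0:
            raise ValueError("horizon must be a positive integer or 'lifetime'")


@dataclass(frozen=True)
class FirstCycleOutcomes:
    """Probabilities of the four mutually exclusive first-cycle pathways."""

    p_no_event: float
    p_infection_only: float
    p_sepsis_survive: float
    p_sepsis_death: float

    def __post_init__(self) -> None:
        total = (self.p_no_event + self.p_infection_only
                 + self.p_sepsis_survive + self.p_sepsis_death)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"first-cycle outcomes must sum to 1, got {total}")


def first_cycle_outcomes(risks: StrategyRisks) -> FirstCycleOutcomes:
    """Collapse the implantation decision tree into its four terminal paths."""
    p_inf = risks.p_infection
    p_sep = risks.p_sepsis_given_infection
    p_die = risks.p_death_given_sepsis
    return FirstCycleOutcomes(
        p_no_event=1.0 - p_inf,
        p_infection_only=p_inf * (1.0 - p_sep),
        p_sepsis_survive=p_inf * p_sep * (1.0 - p_die),
        p_sepsis_death=p_inf * p_sep * p_die,
    )


def discount_factor(t: int, rate: float) -> float:
    """Discount factor 1/(1+rate)^t; cycle 0 is undiscounted."""
    if t < 0:
        raise ValueError("cycle index must be >= 0")
    if rate <= -1:
        raise ValueError("rate must be > -1")
    return (1.0 + rate) ** (-t)


@dataclass(frozen=True)
class MarkovTrace:
    """Per-cycle occupancy and discounted accumulators, with totals."""

    trace: pd.DataFrame = field(repr=False)
    total_ly: float = 0.0
    total_qaly: float = 0.0

    def to_csv(self, path) -> None:
        self.trace.to_csv(path, index=False)


def run_model(
    risks: StrategyRisks,
    life: LifeTable,
    util: UtilityProfile,
    settings: ModelSettings,
) -> MarkovTrace:
    """Run the first-cycle tree plus annual alive/dead cycles for one strategy.

    Cycle 0 applies the decision tree: sepsis deaths leave the cohort with a
    half-cycle credit taken at the in-hospital sepsis weight; sepsis
    survivors split the year between the in-hospital and first-year sepsis
    weights; everyone else accrues the age-band utility minus the cancer
    decrement.  Without same-day imaging, the waiting-day anxiety decrement
    is charged to the whole cohort in cycle 0.  From cycle 1 on, the death
    probability is qx(age) + excess cancer mortality (capped at 1) and
    utility is the decremented age-band weight.
    """
    if not (life.min_age <= settings.start_age <= life.max_age):
        raise ValueError(
            f"start_age {settings.start_age} outside life-table range "
            f"[{life.min_age}, {life.max_age}]"
        )
    lifetime = settings.horizon == "lifetime"
    if lifetime and life.terminal_qx < 1.0:
        raise ValueError("a lifetime horizon requires a life table with terminal qx = 1")
    n_cycles = (life.max_age - settings.start_age + 1) if lifetime else int(settings.horizon)

    fc = first_cycle_outcomes(risks)
    death_credit = 0.5 if settings.half_cycle_credit else 0.0

    # --- cycle 0: decision tree ---
    deaths = fc.p_sepsis_death
    alive = 1.0 - deaths
    ly0 = alive + death_credit * deaths

    u_base = util.applied_utility(settings.start_age)
    frac_hosp = util.sepsis_hospital_days / DAYS_PER_YEAR
    u_sepsis_year = (frac_hosp * util.u_sepsis_hospital
                     + (1.0 - frac_hosp) * util.u_sepsis_first_year)
    qaly0 = ((fc.p_no_event + fc.p_infection_only) * u_base
             + fc.p_sepsis_survive * u_sepsis_year
             + death_credit * deaths * util.u_sepsis_hospital)
    if not risks.same_day_imaging:
        qaly0 -= (risks.waiting_days / DAYS_PER_YEAR) * util.waiting_decrement
    qaly0 = max(0.0, qaly0)

    rows = [(0, settings.start_age, alive, ly0, qaly0)]

    # --- cycles 1..: alive/dead Markov steps ---
    for t in range(1, n_cycles):
        age = settings.start_age + t
        q = min(1.0, life.qx(age) + settings.excess_cancer_mortality)
        deaths = alive * q
        alive -= deaths
        d = discount_factor(t, settings.discount_rate)
        credit = alive + death_credit * deaths
        rows.append((t, age, alive, d * credit, d * credit * util.applied_utility(age)))
        if alive <= 0.0:
            break

    trace = pd.DataFrame(rows, columns=["cycle", "age", "alive", "disc_ly", "disc_qaly"])
    return MarkovTrace(
        trace=trace,
        total_ly=float(trace["disc_ly"].sum()),
        total_qaly=float(trace["disc_qaly"].sum()),
    )


class CalibrationError(ValueError):
    """Raised when a calibration target is unreachable on the knob's range."""


def _bisect(f, lo: float, hi: float, target: float, increasing: bool,
            tol: float, max_iter: int = 100) -> float:
    """Bisection for a monotone f on [lo, hi] until |f(x) - target| <= tol."""
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        val = f(mid)
        if abs(val - target) <= tol or (hi - lo) < 1e-15:
            return mid
        if (val < target) == increasing:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_excess_mortality(
    life: LifeTable,
    util: UtilityProfile,
    settings: ModelSettings,
    risks: StrategyRisks,
    target_discounted_ly: float,
    tol: float = 1e-6,
) -> float:
    """Find the constant excess annual death probability matching a LY total.

    Total discounted life years decrease monotonically in the excess, so the
    solution on [0, 1] is unique whenever the target does not exceed the
    zero-excess total.
    """
    def ly_at(excess: float) -> float:
        s = replace(settings, excess_cancer_mortality=excess)
        return run_model(risks, life, util, s).total_ly

    ly_zero = ly_at(0.0)
    if target_discounted_ly > ly_zero + tol:
        raise CalibrationError(
            f"target life years {target_discounted_ly:.4f} exceed the "
            f"zero-excess total {ly_zero:.4f}; lighten the life table"
        )
    if target_discounted_ly < ly_at(1.0) - tol:
        raise CalibrationError("target life years below the excess=1 total")
    return _bisect(ly_at, 0.0, 1.0, target_discounted_ly, increasing=False, tol=tol)


def calibrate_old_age_utility(
    life: LifeTable,
    util: UtilityProfile,
    settings: ModelSettings,
    risks: StrategyRisks,
    target_discounted_qaly: float,
    tol: float = 1e-6,
) -> float:
    """Find the 80+ band utility matching a discounted QALY total.

    All published utilities are held fixed; total QALYs increase
    monotonically in the 80+ weight on [0, 1].
    """
    def qaly_at(u80: float) -> float:
        u = replace(util, old_age_utility=u80)
        return run_model(risks, life, u, settings).total_qaly

    lo, hi = qaly_at(0.0), qaly_at(1.0)
    if not (lo - tol <= target_discounted_qaly <= hi + tol):
        raise CalibrationError(
            f"target QALYs {target_discounted_qaly:.4f} outside the reachable "
            f"range [{lo:.4f}, {hi:.4f}] for the 80+ utility"
        )
    return _bisect(qaly_at, 0.0, 1.0, target_discounted_qaly, increasing=True, tol=tol)
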