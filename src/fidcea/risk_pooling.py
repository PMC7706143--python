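"""Random-effects pooling of single-arm complication risks.

Published complication rates for a device come from separate single-arm
series, so the quantity pooled here is each study's odds of the event
(events vs non-events), combined on the log-odds scale with the
DerSimonian–Laird moment estimator of between-study variance.  The pooled
log-odds is back-transformed to a probability via odds/(1+odds), which is
the transition probability the cohort model consumes.

Zero-event (or all-event) studies get the conventional 0.5 continuity
correction added to both cells of that study only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "StudyCounts",
    "PooledRisk",
    "study_log_odds",
    "odds_to_probability",
    "pool_random_effects",
    "read_studies_csv",
    "forest_table",
]

_Z95 = 1.959963984540054  # standard normal 0.975 quantile


@dataclass(frozen=True)
class StudyCounts:
    """Event count and denominator for one published single-arm study."""

    study_id: str
    events: int
    denominator: int

    def __post_init__(self) -> None:
        if self.denominator < 1:
            raise ValueError(f"{self.study_id}: denominator must be >= 1")
        if not 0 <= self.events <= self.denominator:
            raise ValueError(
                f"{self.study_id}: events must satisfy 0 <= events <= denominator"
            )

    @property
    def corrected_proportion(self) -> float:
        """Event proportion after the continuity correction, if one applies."""
        e, n = _corrected_cells(self)
        return e / n


def _corrected_cells(study: StudyCounts) -> tuple[float, float]:
    e, n = float(study.events), float(study.denominator)
    if study.events == 0 or study.events == study.denominator:
        # 0.5 added to both cells; the denominator grows by 1
        return e + 0.5, n + 1.0
    return e, n


def study_log_odds(study: StudyCounts) -> tuple[float, float]:
    """Per-study log-odds ln(e/(n-e)) and its variance 1/e + 1/(n-e)."""
    e, n = _corrected_cells(study)
    log_odds = math.log(e / (n - e))
    variance = 1.0 / e + 1.0 / (n - e)
    return log_odds, variance


def odds_to_probability(odds: float) -> float:
    """Convert odds to a probability, odds/(1+odds)."""
    if not math.isfinite(odds) or odds < 0:
        raise ValueError(f"odds must be finite and >= 0, got {odds!r}")
    return odds / (1.0 + odds)


@dataclass(frozen=True)
class PooledRisk:
    """Random-effects pooled event risk on odds and probability scales."""

    pooled_log_odds: float
    pooled_odds: float
    pooled_probability: float
    tau_squared: float
    ci_low: float
    ci_high: float
    q_statistic: float
    n_studies: int
    se_log_odds: float


def pool_random_effects(
    studies: list[StudyCounts], *, tau_squared: float | None = None
) -> PooledRisk:
    """DerSimonian–Laird random-effects pooling of single-arm log-odds.

    The inverse-variance fixed-effect mean gives the heterogeneity statistic
    Q; tau-squared is the moment estimate max(0, (Q-(k-1)) / (S1 - S2/S1))
    with S1 = sum of weights, S2 = sum of squared weights.  Passing
    ``tau_squared=0.0`` forces the fixed-effect analysis; a single study is
    returned as its own estimate with tau-squared 0.

    Returns the pooled log-odds with its Wald 95% CI mapped to the
    probability scale.
    """
    if not studies:
        raise ValueError("at least one study is required")
    ys, vs = zip(*(study_log_odds(s) for s in studies))
    k = len(studies)

    w = [1.0 / v for v in vs]
    s1 = sum(w)
    y_fixed = sum(wi * yi for wi, yi in zip(w, ys)) / s1
    q = sum(wi * (yi - y_fixed) ** 2 for wi, yi in zip(w, ys))

    if tau_squared is None:
        if k == 1:
            tau2 = 0.0
        else:
            s2 = sum(wi * wi for wi in w)
            tau2 = max(0.0, (q - (k - 1)) / (s1 - s2 / s1))
    else:
        if tau_squared < 0:
            raise ValueError("tau_squared must be >= 0")
        tau2 = float(tau_squared)

    w_re = [1.0 / (v + tau2) for v in vs]
    sw = sum(w_re)
    mu = sum(wi * yi for wi, yi in zip(w_re, ys)) / sw
    se = math.sqrt(1.0 / sw)

    odds = math.exp(mu)
    return PooledRisk(
        pooled_log_odds=mu,
        pooled_odds=odds,
        pooled_probability=odds_to_probability(odds),
        tau_squared=tau2,
        ci_low=odds_to_probability(math.exp(mu - _Z95 * se)),
        ci_high=odds_to_probability(math.exp(mu + _Z95 * se)),
        q_statistic=q,
        n_studies=k,
        se_log_odds=se,
    )


def read_studies_csv(path) -> list[StudyCounts]:
    """Read studies from a CSV with header ``study_id,events,n``."""
    df = pd.read_csv(path)
    missing = {"study_id", "events", "n"} - set(df.columns)
    if missing:
        raise ValueError(f"study CSV missing columns: {sorted(missing)}")
    return [
        StudyCounts(str(r.study_id), int(r.events), int(r.n))
        for r in df.itertuples(index=False)
    ]


def forest_table(studies: list[StudyCounts], pooled: PooledRisk) -> pd.DataFrame:
    """Per-study corrected proportions plus the pooled row, forest-style."""
    rows = [
        {
            "study_id": s.study_id,
            "events": s.events,
            "n": s.denominator,
            "proportion": s.corrected_proportion,
            "weight": None,
        }
        for s in studies
    ]
    rows.append(
        {
            "study_id": "pooled (DL random effects)",
            "events": sum(s.events for s in studies),
            "n": sum(s.denominator for s in studies),
            "proportion": pooled.pooled_probability,
            "weight": 1.0,
        }
    )
    df = pd.DataFrame(rows)
    df["ci_low"] = None
    df["ci_high"] = None
    df.loc[df.index[-1], ["ci_low", "ci_high"]] = [pooled.ci_low, pooled.ci_high]
    return df
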