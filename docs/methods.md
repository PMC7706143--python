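# Methods

`fidcea` estimates the cost-effectiveness of implanting Gold Anchor 22G
fiducial markers versus conventional 17–18G markers in the prostate gland
before external-beam radiotherapy. The analysis has four stages: pooling of
published single-arm complication risks, a decision-tree-plus-Markov cohort
model of lifetime discounted costs, life years and QALYs, an incremental
comparison with dominance logic, and one-way deterministic sensitivity
scenarios. This note records the model, its assumptions, the numerical
choices, and what the synthetic inputs do and do not emulate.

## Risk pooling

Published complication rates for fiducial markers come from single-arm
series, so the pooled quantity is each study's odds of the event. For study
*i* with *e* events out of *n* patients the effect is
`y_i = ln(e/(n−e))` with variance `v_i = 1/e + 1/(n−e)`; a study with zero
(or all) events receives the conventional 0.5 continuity correction on both
cells, applied to that study only. Effects are combined with the
DerSimonian–Laird moment estimator: the inverse-variance fixed-effect mean
gives the heterogeneity statistic Q, and

    tau² = max(0, (Q − (k−1)) / (S₁ − S₂/S₁)),   S₁ = Σwᵢ, S₂ = Σwᵢ²,

after which random-effects weights `1/(vᵢ + tau²)` produce the pooled
log-odds, its Wald 95% CI (z = 1.96), and the transition probability
`odds/(1+odds)` the cohort model consumes. A single study is returned as
its own estimate with tau² = 0. Q is always computed from the
inverse-variance fixed-effect fit — the standard DL construction — because
a Mantel-Haenszel heterogeneity estimate is not defined for single-arm
log-odds.

Two properties of this estimator matter for interpretation. First, with
rare events the inverse-variance weights correlate with the estimates
(studies that happen to see more events get more weight), so the pooled
log-odds targets the cohort-level *marginal* event risk
`E[expit(θ + u)]`, `u ~ N(0, tau²)`, rather than the median-study θ; the
simulation-recovery tests assert coverage of the marginal risk, which is
the quantity a transition probability should be. Second, increasing every
study's event count does not always increase the DL pooled probability,
because the re-estimated tau² reshuffles the weights; monotonicity is only
guaranteed (and only tested) for a single study or identical studies.

## Cohort model

A closed cohort starts at age 65 (configurable) at marker implantation.
All implantation complications resolve within the first annual cycle via a
decision tree with four terminal pathways:

    p_no_event        = 1 − p_inf
    p_infection_only  = p_inf · (1 − p_sep|inf)
    p_sepsis_survive  = p_inf · p_sep|inf · (1 − p_death|sep)
    p_sepsis_death    = p_inf · p_sep|inf · p_death|sep

with first-cycle risks per strategy: infection 0.003 (22G) vs 0.024
(17–18G), sepsis given infection 0 vs 0.285, and 28-day sepsis mortality
0.186 for both arms (one source prints 0.1863 for the comparator; the
difference is below the model's resolution and a single value is used).
Sepsis mortality is applied as an immediate first-cycle death probability.

Every later cycle is a plain alive/dead step: the annual death probability
is the life-table `qx(age)` plus a constant additive excess annual death
probability for prostate cancer, capped at 1. The model runs until cohort
extinction ("lifetime" horizon; the terminal life-table row has qx = 1) or
for a fixed number of cycles.

**Quality weights.** Living cycles accrue the EQ-5D male population norm of
the age band (0.845 for 50–59, 0.829 for 60–69, 0.797 for 70–79; bands are
closed-open so a 65-year-old uses the 60–69 weight) minus a lifelong
prostate-cancer decrement of 0.1, floored at zero. The 80+ band is not
published and is a calibrated parameter (below). Sepsis survivors spend the
12 hospital days of cycle 0 at utility 0.53 and the remainder of that year
at 0.62, returning to the decremented age-band weight afterwards — reading
the source's "t=1" sepsis weight as the first post-sepsis year. A strategy
that cannot image on the implantation day charges a waiting-anxiety
decrement of 0.1 for the 6 waiting days (6/365 × 0.1 ≈ 0.0016 QALYs) to the
whole cohort in cycle 0; with same-day imaging the term is zero. In the
base case only the comparator waits.

**Discounting and half-cycle credit.** Life years and QALYs of cycle *t*
are discounted by `(1+r)^(−t)` with r = 3%/year (cycle 0 undiscounted).
Members dying within a cycle receive half that cycle's life-year and QALY
credit; first-cycle sepsis deaths take their half-cycle at the in-hospital
sepsis weight. The half-cycle convention is switchable
(`ModelSettings.half_cycle_credit`) because the source does not state its
convention; results move by far less than the reporting precision.

## Calibration

Two inputs of the published analysis are unavailable: the national male
life table it used and the added annual prostate-cancer mortality (value
never printed), and the 80+ utility. Both are pinned by bisection on the
comparator arm:

1. **Excess mortality** — a constant additive annual death probability is
   bisected on [0, 1] until the comparator's total discounted life years
   equal the external anchor (13.459). Discounted life years are strictly
   decreasing in the excess, so the solution is unique; tolerance 1e−6.
   The demo life table yields an excess of ≈ 0.0089/year.
2. **80+ utility** — holding the published utilities fixed, the 80+ band
   weight is bisected on [0, 1] until the comparator's discounted QALYs
   equal their anchor (9.273); QALYs are strictly increasing in that
   weight. The demo calibration lands at ≈ 0.713, plausibly below the
   70–79 norm of 0.797.

Calibration is performed once on the base case and **not** redone per
sensitivity scenario, so each scenario isolates the assumption it varies.
Round-trip tests recover known excess-mortality and 80+ values to 1e−4.

## Costing

All costs are incurred at implantation (cycle 0) and are therefore
undiscounted; later cycles cost nothing. The expected first-cycle cost of a
strategy is

    markers_used × unit_price + implantation (493) + prophylaxis (2)
    + p_analgesics × 22 + p_infection × (1.5 visits × visit_price + 15)
    + p_sepsis × 6276 + extra-visit logistics,

in USD (the source converts SEK at a fixed 8.65 SEK/USD). The extra
treatment-planning visit of a non-same-day strategy costs one additional
round trip (130 km / 10 × 2 = 26 USD) plus expected rebooking
administration (0.015 × 0.71 h × 25 ≈ 0.27 USD); charging a 250 USD
sick-leave day for it is configurable and off by default, because the
published cost shift of the different-days scenario (≈ 28.6 USD) matches
travel-plus-administration scale, not a full absence day. Two unit prices
are not published: the Gold Anchor 22G per-marker price (censored at
source; a required user input — the demo assumes 55 USD) and the
infection doctor-visit tariff (defaults to 200 USD, a typical specialist
outpatient rate; it enters both arms' costs through their infection risks).

## Comparison and scenarios

Increments are intervention minus comparator. A strategy that is cheaper
and more effective is *dominant*; costlier and less effective is
*dominated*; otherwise the ICER is Δcost/Δeffect computed from unrounded
increments (recomputing from 1-decimal/3-decimal rounded increments can be
off by tens of percent). Zero effect difference with a cost difference is
reported as an undefined ratio with the cost sign noted.

The eight one-way scenarios override the calibrated base configuration:
discount rates 0% and 5%; start ages 60 and 70 (the calibrated excess
mortality and 80+ utility are held fixed); equal conditional sepsis risk
(the 22G arm receives the comparator's 0.285, infection risks stay
distinct); equal infection and sepsis risk (both equalized, leaving only
the waiting-time disutility between arms); implantation and imaging on
different days for the 22G arm (both arms wait 6 days, removing the
logistics advantage); and a one-year horizon.

## Synthetic inputs

The life-table generator is Gompertz–Makeham,
`q(a) = 1 − exp(−(λ + α·e^(β·a)))`, with defaults λ = 5e−4, α = 1.2e−5,
β = 0.104/year and max age 105 — parameters chosen to emulate the adult
mortality of men in a contemporary high-income country (remaining life
expectancy at 65 near 19 undiscounted years), smooth and monotone in age,
with the terminal q forced to 1 so lifetime runs extinguish. Any monotone
`age,qx` CSV can replace it. The generator does not emulate period-vs-
cohort effects, infant-mortality structure, or year-specific fluctuations;
since the survival *scale* is re-anchored by calibration, passing tests
show the engine and calibration are correct, not that the synthetic table
equals any specific national table.

Simulated study sets draw per-study log-odds from
`Normal(θ, between_study_sd)` and events binomially — exactly the
random-effects generative model, with no publication bias, no selective
outcome reporting and no cross-study covariates, so recovery tests validate
the estimator under its own assumptions only.

The parameter fixture reproduces the published parameter table verbatim and
round-trips through YAML losslessly.

## Numerical choices and limitations

* Cycle length is 1 year; problem size is ~41 cycles for a start age of 65
  and a 105-year table, so every pipeline run completes in well under a
  second.
* Bisection uses at most 100 iterations with a 1e−6 target tolerance on
  the calibrated total; both objective functions are strictly monotone.
* Probabilities, utilities and costs are validated at construction
  (dataclass `__post_init__`); the four tree pathways must sum to 1 within
  1e−12.
* Determinism: there is no global random state; study simulation takes an
  explicit seed, and the pipeline writes byte-identical CSVs on reruns of
  the same configuration.
* The published base-case QALY increment (0.015) is reproduced to within
  one unit in the third decimal (this package computes 0.014, and 0.012 vs
  0.013 for the sepsis-equalizing and different-days scenarios): the split
  of the first post-sepsis year, the half-cycle convention, and the shape
  of the unpublished life table all move the increment at the 0.001 level,
  which is exactly the reporting resolution of the source. The life-year
  increment (0.017), the equal-risks increment (0.002), and the full
  dominance pattern are reproduced exactly.
* Probabilistic sensitivity analysis is deliberately out of scope: the
  source analysis is purely deterministic, and no parameter distributions
  exist to propagate.
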