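# Methods

This note documents the statistical procedures biocombo implements, the
choices made where the methodology was genuinely open, and what the
synthetic data generator does and does not emulate.

## Control correction and interaction classification

Treated mortality is corrected replicate-wise against the *same
replicate's* control with Schneider–Orelli's formula
c = (b − k)/(1 − k), where b is the treated and k the control
proportion dead. When b < k the formula goes negative; the corrected
value is floored at 0 with a warning, since a mortality proportion
cannot be negative. A control with k = 1 leaves nothing to correct
against and is an error.

For a combination arm, the Bliss-independence expectation is formed
**within each replicate** from the corrected single-agent mortalities
A (fungus alone) and B (pyrethrum alone) at the same doses:
Mₑ = 1 − (1 − A)(1 − B). Observed and expected corrected mortalities
are then summarised as medians (with quartiles) across replicates, and
one interaction statistic per combination is computed from those
medians **on the percentage scale**:

    χ² = (M₀ − Mₑ)² / Mₑ,   critical value χ²₀.₀₅(1) = 3.841.

Two details matter for reproducing published classification tables:

1. *Scale.* The statistic on proportions is exactly 1/100 of the
   statistic on percentages. Only the percentage scale reproduces
   values such as (20 − 54)²/54 = 21.41.
2. *Aggregation order.* Correct per replicate → median across
   replicates → one statistic from the medians. Correcting pooled
   mortalities, or averaging per-replicate statistics, gives different
   numbers.

Quantiles use linear interpolation between order statistics (numpy's
default, the "type 7" definition); report tables round half-up to two
decimals while all internal computation is unrounded. The critical
value is computed from the χ² distribution at the requested α, never
hard-coded; 3.841 is the checked special case.

**Calibration caveat.** The statistic is a descriptive decision rule,
not a calibrated hypothesis test: Mₑ is itself estimated, medians are
not binomial counts, and no variance enters the denominator. Measured
over 500 simulated experiments of the standard design (4 replicates ×
10 larvae, ψ = 1, exact independence), the pipeline's acceptance test
records a non-additive call fraction of ≈ 0.35 — far above the nominal
5 % — stable to within ±0.01 across seed batches. Classification
results at this design scale should be read with that false-call rate
in mind (the test suite freezes the observed rate as a regression
value). Halving the fungal cumulative hazard (ψ = 0.5) roughly triples
the antagonistic call rate, so the rule does respond to real
interaction at realistic effect sizes.

If a combination's expected median is exactly zero (possible in small
simulations when both single-agent arms kill no more than control),
the statistic is degenerate: zero observed mortality is reported as
χ² = 0 (additive), any observed mortality as an unbounded departure
(synergistic), each with a warning.

## Dose–response models

Three two-parameter families with asymptotes fixed at 0 and 1, each
parameterised by a signed log-dose slope b and a location e in dose
units:

| family | f(x) | LC-level inversion |
|---|---|---|
| LL2 (log-logistic) | 1/(1 + exp(b(ln x − ln e))) | ln x = ln e + ln((1−p)/p)/b |
| W1_2 (Weibull 1) | exp(−exp(b(ln x − ln e))) | ln x = ln e + ln(−ln p)/b |
| W2_2 (Weibull 2) | 1 − exp(−exp(b(ln x − ln e))) | ln x = ln e + ln(−ln(1−p))/b |

For LL2 and W1_2 the response increases with dose when b < 0; for W2_2
when b > 0. For LL2, LC50 = e exactly.

Replicates are pooled into per-dose binomial totals; zero-dose controls
are excluded (log dose undefined) and no control pre-correction is
applied before fitting — the curves describe raw observed mortality.
Parameters maximise the binomial log-likelihood, fitted
deterministically: Nelder-Mead polish from every point of a fixed grid
(slopes {±0.25, ±1, ±4} restricted to the sign consistent with the
empirical dose trend × five log-locations spanning the dose range),
keeping the best optimum; convergence tolerances 1e−8 (parameters) and
1e−10 (objective). Data with no partially-killed dose group raise a
separation error (the slope is unbounded) with advice to widen the
dose range.

Goodness of fit is the deviance against the saturated binomial model,
referred to χ² with (#dose groups − 2) degrees of freedom. Model
selection fits all three families and keeps the highest
goodness-of-fit p-value, breaking exact ties by log-likelihood; all
candidates stay available for reporting. Lethal doses invert the
fitted curve in closed form; their confidence intervals use the delta
method on the log-dose scale with the observed-information covariance
of (b, ln e) obtained by central finite differences (step 1e−5
relative). If the information matrix is singular the point estimate is
returned with a degenerate interval rather than failing.

At the bench-scale design the package targets (5 doses × 30 larvae),
the acceptance test measures: median recovered LC50 within a fraction
of a percent of truth over 200 simulated series, with delta-method
95 % CI coverage ≈ 0.96.

## Survival analysis

Checkpoint counts convert to subject records: each death is assigned
the **first checkpoint day it was observed dead** (not an interval
midpoint — interval-censored likelihoods are out of scope), survivors
are right-censored at the final observation day, and counts are
conserved by construction. Kaplan–Meier curves and log-rank tests are
computed with lifelines (product-limit estimate; hypergeometric
variance with the usual simultaneous-death tie handling, no continuity
correction). The global test across k arms has k − 1 degrees of
freedom (8 for the standard 9-arm design). Pairwise tests cover all
C(k, 2) pairs with Bonferroni adjustment min(1, p·C(k, 2)); compact
significance letters are built by insert-and-absorb over the
non-significant adjacency and are presentation-only. The test suite
verifies the log-rank statistic against an independent brute-force
O/E/V summation to 1e−10.

## Hyphal outgrowth

Counts of cadavers producing hyphae per treatment are compared with a
binomial logistic regression likelihood-ratio test: deviance of the
intercept-only model minus deviance of the treatment-factor model
(IRLS via statsmodels GLM), df = #treatments − 1. With one count pair
per treatment the factor model is saturated, so the statistic equals
the classical G-test of homogeneity — asserted against the closed form
2·Σ[y ln(y/ŷ) + (n−y) ln((n−y)/(n−ŷ))] to 1e−6 in the tests. Pooled
(not replicate-level) counts are used; groups with zero dead larvae
carry no information and are dropped with a warning; 0 %/100 % groups
are handled by the 0·ln 0 = 0 convention. Percentages are reported
rounded half-up to whole percent, the statistic to one decimal.

## Radial growth

The full mixed-model treatment of plate growth curves (random
replicate and plate effects, time × concentration interaction tested
by deletion) needs the raw plate series and heavier machinery than
this package carries; biocombo implements the standard two-stage
summary-slope analysis instead, which tests the same scientific
question — does pyrethrum concentration change the growth rate? —
with plate slope as the summary statistic. Stage one fits a
least-squares slope (mm/day) per plate, excluding measurements after
the plate's radius first reaches 42.5 mm (edge of a 90 mm dish minus
margin). Stage two fits OLS of slopes on concentration with replicate
run as a blocking factor, reports the concentration F test, and makes
all-pairs Tukey–Kramer comparisons using the studentized range on the
blocked model's residual variance, summarised as letter groups.
Because the two-stage analysis weights plates equally rather than by
their within-plate information, its χ² values are not comparable to a
mixed model's deletion statistics; the ordering and significance
pattern of concentration effects is what it is designed to recover
(verified by simulation in the tests).

## Synthetic data generator

The generator emulates the combination-assay design and its
qualitative dynamics; defaults are fixed at the study conditions:

- **Design**: 9 arms (control; 25 and 100 ppm pyrethrum; 10⁴ and 10⁵
  conidia mL⁻¹; the four combinations) × 4 replicates × 10 larvae,
  observed days {1, 2, 4, 7, 10, 14}. Simulation steps every calendar
  day; checkpoints record cumulative deaths.
- **Control**: constant daily hazard 0.0158, giving ≈ 20 % mortality
  by day 14 with a near-linear decline. Background mortality composes
  independently into every arm, which is exactly the regime the
  Schneider–Orelli correction removes.
- **Pyrethrum**: a day-1 knockdown point mass following a log-logistic
  in dose (b = −2, e = 193 ppm, the pyrethrum median lethal
  concentration), ≈ 0.21 at 100 ppm — matching the observed ≈ 20 %
  day-1 drop — plus a residual daily hazard of 0.0075 thereafter.
  These values put the expected day-14 corrected mortality at ≈ 0.12
  (25 ppm) and ≈ 0.29 (100 ppm), the published single-agent medians.
- **Fungus**: no effect before the onset day (default 4), then a
  constant daily hazard back-solved from the dose's day-14 corrected
  mortality target m via h = 1 − (1 − m)^(1/11): targets 0.42 at 10⁴
  and 0.44 at 10⁵ conidia mL⁻¹ (the published corrected medians);
  unlisted doses fall back to a log-logistic in dose centred at the
  fungal LC50 1.48 × 10⁶ conidia mL⁻¹ with slope −0.25.
- **Interaction**: per-day combination kill probability
  1 − (1 − p_pyr)(1 − p_epf)^ψ. At ψ = 1 this is exact Bliss
  independence day by day, hence also cumulatively; ψ rescales the
  fungal cumulative hazard (ψ = 0.5 halves it), mirroring the
  delayed-fungal-kill antagonism mechanism. ψ applies only to
  combination arms.

What the generator does **not** emulate: between-replicate cohort
effects and overdispersion beyond binomial sampling, larval moulting
dynamics, dose-measurement error, and the reduced mid-period decline
seen in real pyrethrum arms. Passing tests therefore demonstrate that
the pipeline's computations are correct and that its decision rules
behave as documented under clean binomial sampling at the study's
design scale — not that real bioassays satisfy those sampling
assumptions.

Auxiliary generators mirror the other assays: binomial dose series
from any model family; radial-growth series radius = 5 mm + (rate +
replicate effect + plate effect)·day + noise, floored non-decreasing
and capped at the 45 mm dish radius; binomial hyphae counts. All
generators are deterministic given a seed.

## Problem sizes used in the automated checks

The acceptance suite runs 200 dose-series refits (5 doses × 30 larvae)
for LC50 recovery and 500 + 500 + 200 simulated combination
experiments for the classifier's null-rate stability and antagonism
response; these sizes give Monte-Carlo error comfortably below the
asserted margins while keeping the suite quick on a laptop.
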