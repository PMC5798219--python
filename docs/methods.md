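# Methods

## Estimation model

The estimator is a period abridged life table in the Chiang II form.
Age is grouped into 19 bands by default ([0,1) with fraction-of-
interval-lived a=0.1, [1,5) and 5-year bands with a=0.5, open 85+); a
20-band variant ending at 90+ and an 18-band variant with a collapsed
0–4 band are selectable for data sources that only report those
groupings. Central rates m_i = D_i/P_i are converted to conditional
death probabilities q_i = n_i m_i / (1 + n_i(1−a_i)m_i), the table is
propagated from a radix of 100,000, and the open terminal band
contributes L_w = l_w/m_w (so e_w = 1/m_w). All rates are treated as
period rates; no cohort adjustment is made.

The variance of e0 combines Chiang's closed-band sum with a terminal-
interval adjustment. Closed bands contribute
l_i²[(1−a_i)n_i + e_{i+1}]²·q_i²(1−q_i)/D_i (zero when D_i = 0); the
terminal band contributes (l_w/l_0)²/(m_w²D_w), the delta-method
variance of 1/m̂_w when terminal deaths are Poisson. The exact algebraic
form of the terminal correction is not standardized across published
variants, so this form is validated behaviorally rather than against a
printed formula: across seeded replicate simulations the mean analytic
SE matches the empirical SD of e0 within 15% at both 5,000 and 20,000
person-years-at-risk, and 95% normal-approximation intervals cover the
true e0 for 93–97% of replicates at 20,000 person-years-at-risk.
Confidence intervals are e0 ± z·SE with no transformation, matching
how SEs and CIs are used for small-area LE in practice.

Zero-cell policy: a closed band with D_i = 0 gets q_i = 0 and zero
variance contribution; P_i = 0 with D_i = 0 additionally raises a
ZERO_EXPOSURE flag; P_i = 0 with D_i > 0 is a hard data error. A
terminal band with no deaths or no exposure makes the estimate
non-computable (flag FINAL_BAND_NO_DEATHS) rather than infinite. A
computed q_i > 1 is clamped to 1 and flagged so batch runs survive
implausible cells.

## Reliability rules

Defaults: suppress when SE > 2 years or exposure < 5,000 person-years;
exclude when total person-years are zero or more than 50% of residents
live in group quarters. Optional rules: minimum 60 deaths, LE floor of
66 years, and a 15,000 minimum population for single-year runs. All
comparisons are strict in the quoted direction, so boundary values
(SE exactly 2, exactly 5,000 person-years) pass. Suppressed estimates
are retained internally and blanked on output (reasons stay visible),
which supports sensitivity analyses of alternative rule combinations
such as SE < 3 versus SE < 2.

## Aggregation

`pool_years` sums deaths and person-years across calendar years.
`merge_to_thresholds` merges adjacent units until every region passes
the selected criteria (min_deaths, min_pyar, se_max — the last
recomputes a life table per candidate region, acceptable at desk
scale of thousands of units). The heuristic — grow the failing region
with the fewest deaths by its fewest-deaths neighbor, ties broken by
person-years then lexicographic member id — is a design choice made
for determinism and for strengthening the weakest regions fastest; no
claim of equivalence with any particular published regionalization
tool is made. Islands and failing whole components are flagged
UNMERGEABLE and reported, never silently dropped. Region ids are the
unit id for singletons and "R"+smallest member id otherwise, keeping
crosswalks human-traceable.

## Hardship index and disparity summaries

The EHI is the unweighted mean of six indicators (crowded housing,
poverty, unemployment, low educational attainment, population
dependency, low income), each min–max standardized to [0,100] across
the units being compared; the construction is therefore invariant to
affine rescaling of any indicator. Indicators must be oriented
larger-is-worse; attainment and income columns reported on the
opposite scale are flipped via the `invert` option. A constant
indicator contributes 0 with a warning. The LE gap is max−min of e0
over reliable units only. The LE–hardship association defaults to
Spearman rank correlation, robust to the (unconstrained) shape of the
relationship; Pearson is available.

## Synthetic studies

The generator emulates a census-tract jurisdiction: a 20×20 grid (400
units, rook adjacency), populations lognormal with median 4,000
(σ=0.45) clipped to [1,200, 12,000], and 5 observation years. Baseline
mortality is Gompertz–Makeham, m(x) = c + b·e^{gx} at band midpoints
(terminal band: lower bound + 5), with defaults c = 7.0e-4,
b = 2.6e-5, g = 0.0965 chosen once so the baseline exact e0 is 77.05
years, inside the [75,82] window enforced at construction. Latent
hardship H is a west–east gradient plus N(0, 0.12) noise clipped to
[0,1]; unit frailty is proportional hazards HR = exp(β(H − H̄)) with
β = 1.1, which yields true LE spreads of one to three decades between
extreme tracts — the scale of reported metropolitan disparities. Each
unit's age structure is the stationary population of its own schedule
(self-consistent and data-free, not a real census pyramid); exposures
P_i = pop·proportion_i per year are deterministic and deaths are
Poisson(P_i m_i). Six hardship indicators are distinct monotone
transforms of H plus N(0, 2) noise on native percentage scales.
Group-quarters fractions are Beta(0.5, 10) capped below 0.5, with 10
units forced above 0.5 (~2.5%, the order of real institutional-tract
exclusions). All randomness flows from one seed.

Truth is recorded via `closed_form_le`, the exact expected lifetime
under piecewise-constant hazards — the generating model — so estimator
error is measured against an analytic target, never against the
estimator itself. `microsimulate_le` gives a third, stochastic
evaluator by simulating individual lifetimes band-by-band; the three
evaluators agree within 0.5 years (deterministic) and 3 Monte Carlo
SEs (stochastic) on random schedules with closed-band rates ≤ 0.05.

What passing tests do and do not show: the generator has no migration,
no cause structure, no mortality trend, no real census age pyramid,
and its hardship–mortality coupling is exactly proportional hazards.
Passing calibration here shows the estimator and rules behave
correctly under their own assumptions at realistic tract scale; it
does not certify performance under numerator/denominator mismatch,
geocoding error, or inter-census population drift in real data.

## Problem sizes and numerical choices

The statistical test suite uses 500 replicates for the mean-SE check,
1,000 for SE calibration, 1,500 for CI coverage, the 400-unit default
study for parameter recovery, and 10 seeds for the association sign —
sizes at which the checked quantities are stable to well within their
tolerances while the whole suite runs in seconds. The gap-recovery
check uses a dedicated 8×8 high-exposure, wide-spread study (β=1.6,
populations 6,000–12,000, 10 years) because the max−min statistic is
biased upward by per-unit noise at the extremes; high exposure makes
the check measure gap recovery rather than that order-statistic bias,
which on noisier default studies adds a few years to the reported gap
(a known property of extreme-based gap summaries, worth remembering
when reading real suppression-screened LE maps).

## Known limitations

Complete (single-year-of-age) tables, Bayesian/model-based smoothing,
LE decomposition, geocoding, optimal regionalization and cartography
are out of scope. The merge heuristic is greedy, not globally optimal,
and does not optimize compactness. The group-quarters rule depends on
a caller-supplied fraction; detection from raw census tables is not
attempted.
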