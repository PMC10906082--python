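# Methods

`seqcea` implements a cost-effectiveness analysis of *when* to use
high-efficacy ALK tyrosine-kinase inhibitors (TKIs) in ALK-positive advanced
non-small-cell lung cancer: brigatinib followed by lorlatinib used first
line, versus reserving both drugs until after platinum–pemetrexed
chemotherapy. This note documents the model, its assumptions, the numerical
choices, and what the synthetic data do and do not establish.

## Model structure

A six-state semi-Markov cohort model with monthly cycles: treatment lines
1–4, best supportive care (BSC), and death. Strategy A sequences
brigatinib → lorlatinib → chemotherapy → docetaxel → BSC; strategy B
sequences chemotherapy → brigatinib → lorlatinib → docetaxel → BSC. Both
arms share docetaxel as fourth line and remain in BSC until death.

Progression risk in a line depends on time since *entering* that line, so
each living state is expanded into tunnel strata indexed by cycles-in-state
(a deterministic, exactly reproducible alternative to microsimulation). The
per-cycle progression probability comes from the line's parametric
progression-free-survival law S through the survival ratio

    p(t, u) = 1 − S(t) / S(t − u),

with u the cycle length and t the time since line entry at cycle end. For
the Weibull family, S(t) = exp(−λ t^γ), this is exactly
1 − exp{λ(t−u)^γ − λ t^γ}; for the other six families the survival-ratio
form is the unique consistent generalization.

Death from active treatment lines occurs at the age-matched background rate
only: the annual life-table probability q at the cohort's current age is
converted to a cycle probability 1 − (1−q)^(u/12). Within a cycle death is
applied first and progression is scaled by the surviving fraction, so
stay/progress/die always sum to one. In BSC the per-cycle death probability
is the larger of the BSC overall-survival hazard ratio and background
mortality — BSC patients never die more slowly than the general population.
Ages past the life-table end are treated as certain death within the year,
and the run stops when death occupancy exceeds 1 − 1e−6 or at the age cap
(100 years); "lifetime horizon" is realized as that cap.

Start age defaults to 58 (configurable; a typical trial-population median
for this indication — the analysis is insensitive to it because background
mortality is small relative to disease progression at these survival times).

## Survival fitting and curve reconstruction

Published figures provide only the Kaplan–Meier curve and a numbers-at-risk
row. `km.reconstruct_ipd` inverts the product-limit estimator (the standard
Guyot-type procedure): within each interval between risk-table times it
allocates integer event and censoring counts such that the reconstructed KM
matches the digitized coordinates and the number at risk is matched exactly
at every risk-table time. Implementation choices:

* digitized survival values are clipped to non-increasing before
  reconstruction (hand-digitized curves wobble);
* per-interval censoring counts are solved by integer bisection, which is
  robust to rounding in coarse digitizations;
* censoring is spread uniformly within each interval; at tied times events
  precede censorings;
* a drop recorded at a grid coordinate is only known to lie in the gap since
  the previous coordinate, so reconstructed events are placed at the gap
  midpoint — placing them on the grid shifts every event late by half a gap
  and biases fitted Weibull rates upward of 30%;
* subjects still at risk after the last coordinate are censored
  administratively at that time; a reported total event count, when given,
  is honoured by relabelling the latest records.

Seven parametric families (exponential, Weibull, gamma, Gompertz,
generalized gamma, log-normal, log-logistic) are fitted to the
reconstructed records by maximizing the right-censored log-likelihood
Σ_events ln f + Σ_censored ln S. The parameterization table (time in
months) is in `survival.py`; conversions to the common scale/shape
conventions are given there. Positive parameters are optimized on the log
scale from several method-of-moments starting points (L-BFGS-B, ftol
1e−12, with a Nelder-Mead polish if the quasi-Newton run reports abnormal
termination); the exponential rate uses its closed form events/follow-up.
Model screening minimizes AIC or BIC, breaking ties by fewer parameters and
then alphabetical family name. Interval censoring induced by digitization
granularity is ignored (right-censoring only). The generalized gamma's
(rate, k) pair lies on a flat likelihood ridge: at n = 2,000 its rate
carries 10–60% sampling error while the fitted curve is within 0.006 of
truth; users extrapolating with that family should compare curves, not
parameters.

## Costs, utilities and discounting

Utilities attach to line *position* (0.71 / 0.67 / 0.59 / 0.46 for lines
1–4, 0.46 for BSC); drug acquisition costs, dosing schedules and
adverse-event profiles attach to the *drug*, so the same agent keeps its
cost and toxicity wherever it appears in a sequence. Doses follow the
reference patient (body surface area 1.72 m², weight 65 kg, creatinine
clearance 70 mL/min); carboplatin uses the Calvert formula
dose = AUC × (CrCl + 25). A line's cycle cost is drug acquisition +
administration fees + monthly follow-up (labs and office visit) + quarterly
imaging amortized over three cycles, all scaled by a user-supplied
consumer-price-index ratio (no price-database lookups).

Costs accrue at the beginning of each cycle with no half-cycle correction;
costs and utilities are discounted identically by 1.03^(−months/12). Only
grade ≥3 adverse events are modelled: each carries an incidence, a one-time
cost and a QALY decrement, charged once to the fraction of the cohort
entering the line (each line's profile comes from its own trial). The
alternative literal reading — the full expected adverse-event burden charged
at model cycle 0 — is available via `settings.ae_timing = "model_start"`.

Incremental results report Δcost, ΔQALYs, the signed ratio Δcost/ΔQALYs and
a dominance label ("dominated": more cost, fewer QALYs). The signed ratio is
reported *alongside* dominance because a dominated comparison still prints a
negative ratio; when ΔQALYs = 0 no ratio is defined and dominance is decided
on cost alone.

## Sensitivity analysis

One-way analysis re-runs the model at the low and high end of each
parameter with everything else at base and tabulates the two ratios and
their absolute spread (tornado order). Default ranges are ±20% of base;
established TKI list prices vary downward only (high = base), which makes
the brigatinib cycle-cost range [16,115.128, 20,143.91] — the base-case
acquisition cost is pinned at the upper end of that range for the same
reason: prices were varied downward only, implying base = upper bound.

Probabilistic analysis draws all uncertain parameters simultaneously:
gamma distributions moment-matched to (base, SE) for costs and QALY
decrements, beta for utilities and incidences, SE = 20% of base, with a
uniform fallback (logged) where beta moment-matching is infeasible. One
draw per parameter per iteration is shared by both strategies — parameters
are properties of the world, not of an arm. Survival parameters are held
fixed by default (selectable); since price and utility draws cannot alter
transitions, the cohort traces are computed once and only the accumulation
is repeated, which keeps 1,000 iterations under a second. Acceptability
curves report, per willingness-to-pay, the fraction of iterations in which
each strategy attains the maximal net monetary benefit (ties split
equally); the scatter exports per-iteration (Δcost, ΔQALYs) pairs.
Every draw derives from (seed, iteration), so results are bitwise
reproducible.

## Synthetic data and calibration

No trial data ship with the package. `synthetic.simulate_km` draws event
times from a known law by inversion, applies administrative censoring,
and digitizes the resulting KM curve at monthly coordinates with a
6-monthly risk table — emulating what a digitizer extracts from a published
figure. The life table is a Gompertz-shaped annual-mortality curve anchored
at 0.7%/year at age 58. Pre-calibration progression curves echo the pivotal
trials' 12-month progression-free survival (0.67 first-line brigatinib,
0.43 first-line chemotherapy); unit prices and adverse-event profiles are
realistic synthetic fixture values, never presented as the study's inputs.

`calibrate_to_base_case` adjusts designated free parameters — the eight
strategy-line survival *rate* (scale) parameters and two unprinted prices —
until both strategies' discounted totals match the published base-case
table (219,712 / 0.70 and 196,513 / 0.76) within 1%. Printed inputs
(utilities, discount rate, brigatinib cycle cost) are excluded from the
free set by construction, so calibration can never silently alter them. A
one-dimensional pre-stage finds a common rate multiplier putting mean QALYs
in the target neighbourhood; bounded log-scale least squares then matches
all four totals. Two consequences worth stating plainly:

* the published totals force *per-arm* survival entries: with fully shared
  per-drug curves both arms would have near-identical exposure and QALYs,
  and the published increments (+$23,199, −0.06 QALYs) would be
  unreachable;
* total QALYs near 0.7 with utilities near 0.6 imply roughly 14 months of
  mean survival, so the calibrated curves are substantially shorter than
  the trials' own. The calibrated configuration is a device for studying
  the decision problem at the published operating point, not a re-estimate
  of the trials.

What passing tests show: the engine's arithmetic (conservation, discounting,
closed-form decay), the reconstruction/fitting chain's statistical
behaviour under known truth, and that at the published operating point the
first-line strategy is dominated with ~0% probability of cost-effectiveness
at $150,000/QALY. What they do not show: anything about the real trials'
curves, real prices, or the external validity of the published totals.

## Problem sizes and tolerances

Recovery tests use n = 500 (single-trial scale) and n = 2,000 (asymptotic
check); the probabilistic analysis uses 1,000 iterations. Cohort traces run
to the age cap of 100 years (≤ 504 monthly cycles). Calibration tolerance
is 1% relative on all four totals; likelihood convergence tolerance 1e−12
on the objective; occupancy conservation asserted at 1e−10. At n = 500 the
Weibull rate MLE itself carries ~10% sampling error, so the 15% recovery
bound is a per-seed property; the suite fixes one master seed throughout.

## Known limitations

Right-censoring only in the likelihood; no spline or cure-fraction models;
no covariate adjustment; no vial rounding or wastage; no treatment waning;
no half-cycle correction (by design, matching the analysis's convention);
no expected-value-of-perfect-information analysis. The platinum partner is
configurable (carboplatin in the base fixture, cisplatin equally valid);
nothing in the package asserts which one the published base case used.
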