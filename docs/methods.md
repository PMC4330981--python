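# Methods

## Cohort model

The engine (`aitcea.markov`) is a discrete-time Markov cohort model with
annual cycles over a 9-year horizon. The state space crosses a treatment
regime — `on_treatment` (years 1–3 of the immunotherapy course),
`completed_treatment` (course finished), `discontinued`, `symptomatic_only`
— with a chronic-asthma flag, plus a single absorbing dead state (9 states).
Key structural assumptions:

- **Event ordering.** Within a cycle, death, discontinuation and asthma
  onset compose multiplicatively in that order. At the modelled magnitudes
  the ordering changes results by well under 0.1%.
- **Discontinuation** applies in treatment years 1–2 only; year-3 survivors
  are relabelled `completed` at the cycle boundary, so year-3 state time is
  still on-treatment time. Discontinuers revert to the symptomatic-arm
  symptom score, costs and asthma risk in the same cycle (through the
  half-cycle average); there is no re-initiation.
- **Treatment-effect persistence.** The on-treatment symptom score carries
  into the post-treatment years for patients who completed the course
  ("on-effect" = on-treatment ∪ completed); discontinued and never-treated
  patients are "off-effect".
- **Asthma** is an absorbing comorbidity flag: onset at 0.0046/yr
  off-effect, × RR 0.505 on-effect; asthmatic patients keep their regime
  (they continue immunotherapy — the alternative is not identifiable from
  the printed results and changes between-arm increments by < 3%) and retain
  their regime's rhinitis score.
- **Mortality** is age-constant at the cohort-entry (age 29) values,
  0.00046/yr (0.00069/yr with asthma, interpreted as the total death
  probability in the asthma state, not an increment). Over nine years the
  age trend in mortality at this age is negligible relative to every
  reported quantity.
- **Half-cycle correction.** All accruals (costs, QALYs, person-years) use
  the mid-cycle occupancy, the average of cycle-start and cycle-end
  occupancy, approximating uniformly timed events. This convention is what
  reproduces the published treatment-cost components (EUR 1,381 / 809);
  start- or end-of-cycle accrual misses them by 10–15%.

## Valuation

Utility of an alive state (mode `rsui`, the default):
`u₀ − (m/12)·k·RTSS − d_asthma·[asthma]`, clamped at zero with a warning.
The seasonal fraction m/12 confines the symptom burden to the pollen season
(m = 3 months base case). Mode `eq5d` (scenario 4) replaces the map with flat
year-round utilities: 0.976 while the treatment effect persists, 0.947
otherwise. Discounting for costs and effects: `(1+r)^−(t−1)` at r = 3%, the
first model year undiscounted — the only convention consistent with the
published discounted/undiscounted QALY pair (0.081/0.090).

Costs accrue per cycle from mid-cycle occupancies: drug acquisition
(on-treatment share × annual cost), specialist visits (per-arm counts on
treatment, 1.9/yr off treatment, EUR 13.29 each), injections (allergoid
only, plus one supervised first administration of the tablet in cycle 1),
diagnostics (EUR 20.61, cycle 1, full entering cohort, AIT arms),
seasonal co-medication (loratadine + budesonide at EUR 7.33/season
on-effect, EUR 11.37 off-effect; treated as fixed per-season packs, not
scaled by season length), asthma care (EUR 186.30/yr, 2013 prices), and —
societal perspective only — a productivity stream. The tablet's acquisition
cost is per treated month (EUR 2,100.10 over 21 months = EUR 100.005/month,
4 pre-seasonal months + the season), so a 2-month season implies 6 treated
months; the allergoid mix is per-pack, EUR 1,449.60 over 3 years,
season-independent.

## Calibration of unpublished inputs

Four quantities the published model uses but does not print are recovered by
inverting the full model against one published target each
(`aitcea.calibration`); every map is monotone affine, solved by a bracketed
Brent root search to 1e−12:

| quantity | target | fitted |
|---|---|---|
| utility slope k (per RTSS point) | ΔQALY undiscounted, tablet vs symptomatic = 0.090 | 0.05908 |
| tablet visits/treatment-year | visit component EUR 267 | 3.43 |
| allergoid visits/treatment-year | visit component EUR 299 | 5.15 |
| allergoid injections/year | injection component EUR 69 | 8.07 |
| productivity saving/season | societal Δcost, tablet vs symptomatic = EUR 784 | EUR 133.3 (≈ 4.3 h × EUR 30.70) |
| baseline utility u₀ (optional) | symptomatic discounted QALYs = 7.235 | 0.96997 |

The system is triangular (the slope touches only QALYs, the counts only
costs, the saving only the societal perspective), so the calibrations are
independent and the sequence is a fixed point. The shipped base-case config
carries these values; `aitcea calibrate` re-derives them with residuals.
All other published figures — the three remaining QALY contrasts (0.041,
0.081, 0.036), the ICERs, the remaining cost components, the scenario
table — are held out as validation and reproduced within 0.2–2%.

The linear RTSS→utility slope is an explicit proxy for the Rhinitis Symptom
Utility Index; the instrument's item-level scoring is not reconstructed.
That the single calibrated slope reproduces all four QALY contrasts to ≤ 2%
is the evidence that the linear proxy is adequate for this model's range.
The chronic-asthma utility decrement is not identifiable from the published
results (it shifts between-AIT increments by < 3%); it defaults to 0 and is
exposed in the config.

## Indirect treatment comparison

`aitcea.itc` implements per-trial standardized mean differences
(Cohen's d on the pooled SD; variance (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂));
optional Hedges small-sample correction, off by default), fixed-effect
inverse-variance pooling per treatment class, and the anchored (Bucher)
contrast through the common symptomatic comparator (difference of pooled
SMDs, variances additive). Negative SMD = symptom improvement. A pooled SMD
maps back to the symptom-score scale as `control_mean + smd × reference_SD`.
The trial-level summaries behind the published pooled scores are not part of
this package's inputs, so the module is validated on synthetic evidence
(parameter recovery and interval coverage); the published pooled RTSS values
enter the economic model directly as config constants. Random-effects
pooling is deliberately omitted: the source analysis is fixed-effect.

## Sensitivity analysis

Distribution families: beta (probabilities), gamma (unit costs, season
length), normal (relative risk, efficacy contrasts), shapes by method of
moments, SE = 20% of the mean where no variance is reported. Parameters are
drawn independently; normal draws are clipped to their supports with a
warning, and independently drawn mortality pairs are repaired to keep the
asthma excess non-negative. Drug acquisition prices (administered list
prices) and the calibrated slope/resource counts are held fixed. The
baseline utility u₀ cancels exactly in every incremental outcome and is
excluded from the sampled set (the 20% rule is also method-of-moments
infeasible for a beta that close to 1).

Two conventions deserve emphasis:

- **Efficacy dispersion.** The SEs of the two symptom-score differences
  (treatment vs symptomatic) are not published. They are parameterized as
  `efficacy_se_scale × 0.20 × mean difference` and the single scale factor
  is calibrated (8,000-draw solve, quadratic width law, one refinement
  pass) so the draw-wise 95% interval of incremental QALYs (tablet vs
  allergoid) matches the published 0.002–0.078. Fitted scale: 0.7673,
  stored in the shipped config and re-derivable via
  `calibrate_efficacy_dispersion`.
- **Fixed administration months in PSA.** By default
  (`settings.psa_fixed_administration_months`) the season draw does not
  change the tablet's total treated months: the acquisition price behaves
  as a fixed administered annual price, and the season draw varies the
  symptom burden only. This convention reproduces the published
  probabilistic incremental-cost interval (≈ EUR 200–710 at 1,000 draws)
  at both bounds; letting the draw re-price administration overdisperses
  incremental costs by ~30%. The one-way DSA and the scenarios keep the
  full season→cost linkage (season length is then the top cost driver, and
  efficacy the top QALY driver, matching the published tornado ordering).

The CEAC reports, at each willingness-to-pay λ, the fraction of draws in
which an arm attains the maximal net monetary benefit among the arms
compared. The headline acceptability at EUR 20,000/QALY is the pairwise
tablet-vs-allergoid probability (the published 76% is defined against the
allergoid mix). Under the calibrated dispersion this lands at ≈ 0.79–0.82
across seeds, with ≈ 98% of draws in the north-east quadrant. The residual
gap to 0.76 is structural: the published interval widths, quadrant share and
acceptability are jointly consistent only if incremental costs and effects
are uncorrelated, whereas a mechanistic cohort model necessarily correlates
them (ρ ≈ 0.5) through the persistence→treatment-cost channel; the package
reports its own draws rather than forcing the published figure.

## Scenarios

Declarative, pure config transformations (`aitcea.scenarios`): (1) lump-sum
and (2) ambulatory remuneration — these swap per-setting unit-cost tables
that are not publishable from the source (the bundled tables are
placeholders repeating the base case and are flagged non-validated);
(3) societal perspective — adds the calibrated productivity stream on
off-effect person-years rather than replacing cost tables (reproduces both
published societal contrasts within 2%; a literal sick-day × wage
computation, 2.5 days × 8 h × EUR 30.70, would imply a far larger saving
than the published table admits, so the calibrated per-season saving ≈ 4.3
labour hours is used); (4) EQ-5D utilities year-round — the source text
assigns both AIT classes 0.947, which would zero the between-AIT QALY gain
and contradict its own results table; it is read as a typo for 0.976, the
mono-grass tablet EQ-5D value from the cited study, which reproduces both
published rows (0.026 and 0.131); (5) two-month pollen season — also
shortens tablet administration to 6 months/year. Scenarios 3–4 re-value an
unchanged cohort trace; scenario 5 leaves transitions untouched and scales
the symptom-driven QALY gain by exactly 2/3.

## Synthetic data

The trial generator emulates the evidence structure behind the indirect
comparison — 4 tablet trials and 5 allergoid trials, 100 patients/arm,
anchored on a common control (mean 4.47, SD 2 on the symptom-score scale),
with true SMDs −0.605/−0.415 matching the published pooled scores at the
working SD. Individual scores are normal (the SMD framework's working
model); scores are not truncated at zero, a deliberate simplification —
synthetic summaries therefore behave like idealised trial reports, and
passing recovery/coverage tests validates the estimator arithmetic, not
robustness to skewed real-world score distributions. The config fuzzer
draws random valid parameter sets across full supports (discontinuation up
to 0.95, RR up to 2) for engine property tests.

## Numerical choices and problem sizes

Root solves: Brent on a bracket, xtol 1e−12. Trace conservation holds to
1e−12 by construction (row-stochastic matrices). The test suite and the
acceptance script use the model's native sizes — 9 annual cycles, 1,000 PSA
draws, 500 synthetic meta-analyses, 200 fuzzed configs — chosen to match the
source analysis and keep Monte-Carlo error on reported probabilities near 1
percentage point; a deterministic model evaluation costs well under a
millisecond, a full 1,000-draw PSA a few seconds. The default seed
(20150121) is arbitrary and date-derived; all stochastic entry points take
explicit seeds.

## Known limitations

- Adverse events, hospitalizations and new sensitizations are outside the
  model, as in the source analysis.
- Absolute QALY levels depend on the optional baseline-utility calibration;
  only incremental results are contract-grade.
- Scenarios 1–2 cannot be validated without per-setting fee-catalogue
  prices; the remuneration mix percentages in the source overlap and are
  not modelled mechanistically.
- Parameters are sampled independently in the PSA; no correlation structure
  (e.g. between the two discontinuation years) is imposed.
- The published probabilistic acceptability (76%) is not exactly
  reproducible for the structural reason discussed above; the package's
  value is ≈ 0.80.
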