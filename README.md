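# aitcea

Markov cohort cost-utility model comparing three strategies for seasonal
grass-pollen allergic rhinoconjunctivitis in the German healthcare setting:

- **5-grass tablet** — sublingual immunotherapy (SLIT), taken pre- and
  co-seasonally (7 months/year at a 3-month pollen season) for 3 years;
- **allergoid mix** — a market-weighted average of subcutaneous (SCIT)
  chemically modified allergen products, injected by a specialist;
- **symptomatic treatment** — antihistamine/corticosteroid control only.

The package is aimed at health-economic analysts who want the full pipeline —
cohort engine, costing, calibration, sensitivity analysis, evidence
synthesis — as tested, scriptable Python rather than a spreadsheet.

## Model

A cohort of 29-year-old patients is propagated through annual cycles over a
9-year horizon. States cross a treatment regime (on treatment years 1–3,
completed, discontinued, symptomatic-only) with a chronic-asthma flag and an
absorbing dead state. Annual discontinuation probabilities apply in treatment
years 1–2 (tablet 0.29/0.28, allergoid 0.41/0.34); asthma onset is 0.0046/yr
off treatment, reduced by RR = 0.505 while the immunotherapy effect persists;
mortality is 0.00046/yr (0.00069 with asthma). State time is valued at the
half-cycle-corrected occupancy (average of cycle start and end).

QALYs use a linear symptom-utility proxy applied during the pollen season:

    u(state) = u₀ − (m/12)·k·RTSS(state) − d_asthma·1[asthma]

with season length m = 3 months, RTSS the rhinoconjunctivitis total symptom
score (3.26 / 3.64 / 4.47 for tablet / allergoid / symptomatic), and the
slope k calibrated to the published QALY gain. Costs accrue per cycle from
drug acquisition, specialist visits, injections, first-year diagnostics,
seasonal co-medication, and asthma care; costs and effects are discounted at
3%/yr with the first year undiscounted:

    ICER = ΔC/ΔE,   NMB(λ) = λ·ΔE − ΔC

Uncertainty is handled with one-way deterministic sweeps (95% CI bounds,
tornado ordering) and a 1,000-draw probabilistic sensitivity analysis (beta
for probabilities, gamma for unit costs and season length, normal for the
relative risk and the efficacy contrasts; SE = 20% of the mean where
unreported), summarised as a cost-effectiveness acceptability curve (CEAC).
An anchored indirect treatment comparison (fixed-effect inverse-variance
pooling of standardized mean differences through the common symptomatic
comparator) underpins the relative efficacy inputs.

## Worked example

```sh
$ aitcea base-case --out out/
five_grass: QALYs 7.316 disc / 8.209 undisc, costs EUR 1,710 disc / 1,782 undisc
allergoid: QALYs 7.279 disc / 8.168 undisc, costs EUR 1,251 disc / 1,310 undisc
symptomatic: QALYs 7.235 disc / 8.119 undisc, costs EUR 322 disc / 363 undisc
wrote 8 files to out
```

Each arm accumulates about 7.2–7.3 discounted QALYs over nine years; the
tablet adds 0.037 QALYs over the allergoid mix for an extra EUR 459 —
`out/icers.csv` holds the resulting ratio, about **EUR 12,500 per QALY**
discounted (EUR 17,100/QALY vs symptomatic care). `out/cost_components.csv`
breaks the totals into the component ledger (drug acquisition dominates at
62–78% of AIT-arm costs), and `out/trace_*.csv` exports the underlying
cohort occupancies.

```sh
$ aitcea psa --out out/ --seed 1
P(five_grass most cost-effective at EUR 20,000) = 80.5%; NE-quadrant share 97.6%
```

The same library surface is importable (`aitcea.run_arm`,
`aitcea.compare`, `aitcea.run_psa`, …); see `docs/methods.md` for the model
assumptions, the calibration of unpublished inputs, and known limitations.
Other subcommands: `scenarios` (five scenario analyses incl. societal
perspective and EQ-5D valuation), `dsa` (tornado), `calibrate`
(re-derives the calibrated quantities with residuals), `itc-pool` (pool
trial summaries from CSV).

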