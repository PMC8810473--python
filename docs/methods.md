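# Methods

## Model structure

Each comparison (WW vs APR, WW vs LAR) is a patient-level state-transition
model over six health states:

| state | entered from | monthly exits |
|---|---|---|
| stable disease (WW surveillance) | cohort entry (WW arm) | local regrowth, distant recurrence, natural death |
| stable disease (post-surgery) | initial operation or salvage resection | local recurrence, distant recurrence, natural death |
| local recurrence, salvaged | post-operative recurrence with salvage | distant progression, cancer death, natural death |
| local recurrence, unsalvaged | regrowth/recurrence without salvage | distant progression, cancer death, natural death |
| distant recurrence | distant event without concurrent local | cancer death, natural death |
| local and distant recurrence | concurrent diagnoses or progression from a local state | cancer death, natural death |
| death (absorbing) | any | — |

Surgical-arm patients face a one-time perioperative death risk (3.5%) at the
operation, an acute postoperative window (2 cycles), 4 cycles of adjuvant
chemotherapy, and an ostomy — permanent for APR (ostomy-care costs accrue
for all remaining alive cycles), temporary for LAR (6 cycles, then a
takedown procedure, both accrued only while the patient remains in
post-surgery stable disease). WW patients enter stable disease directly
under an intensive surveillance calendar; on regrowth, 94% undergo salvage
resection (the model's operation, APR or LAR, with the perioperative risk
re-applied) and then follow the post-surgery pathway with its own
recurrence schedule and clocks reset — including the possibility of a
second salvage. Adjuvant chemotherapy is accrued once per patient, in the
first stable phase (this mirrors the stated perfect-adherence assumption
applying to all strategies, WW included; a `ww_adjuvant_chemo` switch
restores the surgery-only variant).

Within each cycle events resolve in a fixed order: natural death → cancer
(or perioperative) death → progression draws → accrual for the state then
occupied. On a local event, a concurrent-distant diagnosis (5.6%) routes to
the combined state; otherwise the salvage draw applies (94% WW regrowth,
59% post-operative recurrence). On a distant event, a concurrent-local
diagnosis (17%) routes to the combined state. Patients in a local state
face a monthly distant-progression hazard from the 3-year 11% figure.

## Probability conversions

All source risks are interval-cumulative; within each interval the hazard
is constant, so `p = 1 − (1−P)^(1/n)` per cycle. Local recurrence is
piecewise: cycles 1–24 use the 2-year cumulative over 24 cycles (the
schedule's cumulative incidence at cycle 24 reproduces the 2-year value
exactly); cycles 25–60 use the 5-year row converted over the full 60-cycle
horizon, treating the two published rows as independent hazard sources.
This reading reproduces the reported ~31% five-year WW regrowth proportion,
whereas a single-cumulative-curve reading would give 24% — and, for the
surgical arm, would imply a decreasing cumulative incidence (2-year 0.016
versus 5-year 0.010). State-specific cancer mortality converts 5-year
figures to constant monthly probabilities that apply for as long as the
state is occupied. Background mortality interpolates a sex-averaged 2015 US
period life table at the attained age (baseline 63 years — a typical median
age at rectal cancer diagnosis — advancing one year every 12 cycles) and
converts the annual probability over 12 cycles.

## Utilities

The stable WW state carries utility 0.80. The published acute
postoperative figure (0.110) is applied as a *disutility decrement* from
that baseline, giving an acute level of 0.69 during the 2-cycle recovery
window — identical to the salvage-resection disutility state (0.69) and
consistent with the cited "approximately 17% decrease in health utility"
after surgery (0.80 → 0.69 is −14%; reading 0.110 as the level itself
would be −86%). Long-term surgical utilities are 0.75 (APR), 0.70 (LAR
with ostomy) and 0.78 (LAR after reversal); recurrence states carry 0.67
(local), 0.70 (distant) and 0.48 (combined); death is fixed at 0.

## Costs

Payer-perspective 2019 US$ throughout: the operation (salvage resection
priced as the model's operation), adjuvant chemotherapy per 28-day cycle,
ostomy care and takedown, itemized surveillance (office visit, rectal exam,
flexible sigmoidoscopy, CEA, colonoscopy — through the stoma after APR —
CT chest/abdomen-pelvis, pelvic MRI), restaging at recurrence diagnosis,
re-irradiation on salvaged pelvic recurrence, palliative capecitabine
(unsalvaged pelvic recurrence) and mFOLFOX6 (distant disease) monthly, and
a terminal-care cost at death by cause. The default surveillance calendar
(WW: exams every 3 months in years 1–2 then every 6 months, MRI every 6
months then annually, annual CTs, colonoscopy at 1 year; surgical arms:
office visit + CEA on the same cadence, annual CTs, colonoscopy at 1 year)
is explicit configuration — the decision is insensitive to every cost
parameter, so reasonable calendar variations do not move the conclusions.

## Discounting

3% per year with half-cycle correction: recurring accruals (utilities,
monthly costs) are discounted at exponent (t − 0.5)/12; one-time transition
costs (surgery, restaging, re-irradiation, takedown, death costs) at their
event cycle, (t − 1)/12. A patient dying in cycle t accrues no utility for
that cycle.

## Randomness and reproducibility

A single Philox counter-based stream keyed by the master seed supplies each
patient a fixed block of uniforms addressed by (cycle, draw channel), so
patient *i*'s trajectory is bit-identical whatever the cohort size or
evaluation order, and identical (spec, arm, n, seed) runs are byte-equal.
The per-patient engine is vectorized across the cohort; a 10,000-patient
arm simulates in well under a second.

## Deterministic oracle

`cohort_expected_value` propagates state-occupancy probabilities through
exactly the same schedules, event logic and accrual rules, expanding the
post-surgery stable state by entry cycle (its recurrence schedule,
chemotherapy, recovery and ostomy windows are clocked from surgery) and
recurrence states by permanent-ostomy status. It yields exact expected
costs/QALYs (occupancy rows sum to 1 by construction) and serves two
roles: a closed-form-checked oracle for the stochastic engine, and the
noise-free evaluator behind the one-way sensitivity analysis, whose
classification thresholds are refined by bisection to 1e-3 (probabilities,
utilities) or $1 (costs).

## Sensitivity analyses

One-way sweeps cover every probability and utility over its published
range (upper bounds of 1 capped at 0.99, since the per-cycle conversion
needs P < 1) and every cost over 5%–195% of base; each point is classified
as "WW dominates", "surgery not cost effective", or "surgery cost
effective" at the $100,000/QALY threshold.

The PSA draws probabilities and utilities from method-of-moments β
distributions and costs from γ distributions (SD = 20% of the mean where
no SD is reported). A β SD at or above the variance bound
`sqrt(mean·(1−mean))` is clipped to 95% of the bound with a logged
warning (a few published rows sit at that bound). Probabilities and costs
are sampled independently; health-state utilities are sampled
comonotonically — one shared quantile per realization across all utility
parameters, leaving each marginal β distribution intact. The utilities
come from a single patient survey and patient-reported quality of life
after chemoradiation alone consistently ranks above life after radical
surgery, so preserving the cross-state ordering is the realistic
correlation structure; fully independent draws (available via
`correlated_utilities=False`) would instead rank surgery above WW in ~40%
of realizations on sampling noise alone. Each outer draw is evaluated by a
full microsimulation per arm with nested, reproducible substreams.

## Synthetic scenarios and what the tests show

The scenario module provides degenerate parameter sets with closed-form
expectations (all risks zero → the discounted annuity
`Σ u/12 · 1.03^(−(t−0.5)/12)`; certain perioperative death; zero costs;
utility ceiling), the adjuvant-timing variants (chemotherapy starting 4, 8
or 12 weeks post-intervention), and uniformly randomized valid parameter
sets for property sweeps. Passing tests therefore establish internal
consistency (engine vs oracle vs closed forms, conservation, moment
identities, reproducibility) and faithful reproduction of the published
tables under this parameterization — they do not validate the underlying
clinical inputs, which come from the cited literature, nor predict
real-world outcomes.

## Numerical and design choices

- Event-order tie-breaks within a cycle are fixed as listed; at monthly
  granularity order effects are second-order.
- The salvage decision is drawn once at recurrence diagnosis;
  re-irradiation attaches to salvaged post-operative pelvic recurrence
  (WW regrowth salvage follows recent chemoradiation and is not
  re-irradiated).
- A second local recurrence after WW salvage uses the post-surgical
  salvage probability (0.59).
- "Distant only" cohort proportions are reported as *any* distant
  recurrence (the combined-state row overlaps it), which is how the
  published outcome table tallies; the strictly-exclusive proportion is
  also available on `MicrosimResult`.
- Sweep and PSA parameter addressing uses dotted paths
  (`transitions.local_recurrence_2y.WW`); the natural-mortality sweep
  replaces the life table with a constant monthly probability.

## Known limitations

- The five-year horizon truncates lifetime costs and benefits; no
  extrapolation is attempted.
- Cohorts are homogeneous: no age/sex mix, no adherence modelling.
- At the extreme low end of the LAR-price sweep (≲ $3.4k, 5–10% of base)
  the surgical arm becomes marginally cheaper than WW while remaining less
  effective and far from cost effective, so strict dominance — though not
  the decision — briefly breaks; the published table reports dominance
  throughout, a hair's difference in unstated cost structure at a
  clinically irrelevant extreme.
- The life-table fixture is an abridged approximate transcription;
  the one-way sweep over natural mortality shows the conclusions tolerate
  errors orders of magnitude larger than the transcription error.
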