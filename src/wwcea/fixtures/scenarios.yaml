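# Named scenario recipes: overrides applied to a base-case parameter set.
# "set_all: {section: value}" sets every non-fixed parameter mean in that
# section (with sd 0); "overrides" then set individual values. Paths use the
# dotted addressing of wwcea.parameters.set_parameter;
# "natural_mortality_monthly" replaces the life-table lookup.

zero_risk:
  comparison: WW_vs_APR
  set_all: {transitions: 0.0}
  overrides: {natural_mortality_monthly: 0.0}
  expected: "no events; discounted QALYs equal the closed-form annuity"
  description: all event and death risks zero

certain_perioperative_death:
  comparison: WW_vs_APR
  set_all: {transitions: 0.0}
  overrides:
    natural_mortality_monthly: 0.0
    transitions.perioperative_death: 1.0
  expected: "surgery arm: all perioperative deaths, zero QALYs"
  description: perioperative death certain, all other risks zero

certain_regrowth_certain_salvage:
  comparison: WW_vs_APR
  set_all: {transitions: 0.0}
  overrides:
    natural_mortality_monthly: 0.0
    transitions.local_recurrence_2y.WW: 0.99
    transitions.local_recurrence_5y.WW: 0.99
    transitions.salvage_given_local.WW: 1.0
  expected: "nearly all WW patients regrow and every regrowth is salvaged"
  description: near-certain WW regrowth with certain salvage

zero_costs:
  comparison: WW_vs_APR
  set_all: {costs: 0.0}
  expected: "both arms cost exactly 0"
  description: every cost zero

perfect_health_no_mortality:
  comparison: WW_vs_APR
  set_all: {utilities: 1.0}
  overrides:
    # the acute postoperative row is a disutility decrement: ceiling = 0
    utilities.initial_postop: 0.0
    natural_mortality_monthly: 0.0
    transitions.perioperative_death: 0.0
    transitions.mortality_local_salvaged_5y: 0.0
    transitions.mortality_local_unsalvaged_5y: 0.0
    transitions.mortality_distant_5y: 0.0
    transitions.mortality_local_and_distant_5y: 0.0
  expected: "QALYs equal the discounted 5-year annuity regardless of arm"
  description: utilities at ceiling, no mortality from any cause

adjuvant_start_4w:
  comparison: WW_vs_APR
  overrides: {timeline.adjuvant_chemo_start_offset_cycles: 1}
  description: adjuvant chemotherapy starts 4 weeks post-intervention

adjuvant_start_8w:
  comparison: WW_vs_APR
  overrides: {timeline.adjuvant_chemo_start_offset_cycles: 2}
  description: adjuvant chemotherapy starts 8 weeks post-intervention (base case)

adjuvant_start_12w:
  comparison: WW_vs_APR
  overrides: {timeline.adjuvant_chemo_start_offset_cycles: 3}
  description: adjuvant chemotherapy starts 12 weeks post-intervention
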