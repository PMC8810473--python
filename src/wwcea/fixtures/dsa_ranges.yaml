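# One-way deterministic sensitivity sweep ranges for probability and utility
# parameters (lower, upper), mirroring the published per-row ranges. Cost
# parameters are swept over 5%-195% of base and are generated in code.
# Upper bounds of 1 are capped at 0.99 at load (per-cycle conversion needs
# cumulative probability < 1).
transitions.perioperative_death: [0.001, 0.9]
transitions.local_recurrence_2y.WW: [0.16, 1.0]
transitions.local_recurrence_5y.WW: [0.21, 1.0]
transitions.local_recurrence_2y.TME: [0.01, 1.0]
transitions.local_recurrence_5y.TME: [0.005, 1.0]
transitions.salvage_given_local.WW: [0.1, 0.95]
transitions.salvage_given_local.TME: [0.01, 0.8]
transitions.distant_recurrence_5y.WW: [0.05, 1.0]
transitions.distant_recurrence_5y.TME: [0.05, 1.0]
transitions.concurrent_distant_given_local: [0.01, 0.9]
transitions.concurrent_local_given_distant: [0.01, 0.9]
transitions.distant_after_local_3y: [0.01, 1.0]
transitions.mortality_local_salvaged_5y: [0.1, 1.0]
transitions.mortality_local_unsalvaged_5y: [0.1, 1.0]
transitions.mortality_distant_5y: [0.1, 1.0]
transitions.mortality_local_and_distant_5y: [0.1, 1.0]
natural_mortality_monthly: [0.001, 0.9]
utilities.initial_postop: [0.05, 0.95]
utilities.initial_ww: [0.05, 0.95]
utilities.salvage_tme_disutility_state: [0.05, 0.95]
utilities.longterm_apr: [0.1, 0.9]
utilities.longterm_lar_with_ostomy: [0.05, 0.95]
utilities.longterm_lar_without_ostomy: [0.05, 0.95]
utilities.local_recurrence: [0.01, 0.95]
utilities.distant_recurrence: [0.01, 0.95]
utilities.local_and_distant: [0.0048, 0.96]
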