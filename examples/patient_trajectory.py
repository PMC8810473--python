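"""Follow single simulated patients through the model.

Each patient starts in stable disease (under WW surveillance or after
surgery) and transitions month by month among the six health states,
accruing discounted costs and quality-adjusted life-years until death or
the five-year horizon.
"""

from wwcea import ARM_WW, base_case_spec, simulate_patient

spec = base_case_spec("WW_vs_APR")

for idx in range(6):
    traj = simulate_patient(spec, ARM_WW, master_seed=2021, patient_index=idx)
    events = [(c, e) for c, _, ev in traj.steps for e in ev]
    path = " | ".join(f"month {c}: {e}" for c, e in events) or \
        "stable under surveillance for all 60 months"
    print(f"patient {idx}: {path}")
    print(f"  accrued ${traj.discounted_cost:,.2f} and "
          f"{traj.discounted_qalys:.3f} QALYs (discounted); "
          f"death cause: {traj.death_cause}")

print()
print("Transitions show regrowth/salvage and recurrence events; costs jump "
      "at salvage surgery and recurrence management, QALYs accrue at the "
      "occupied state's utility weight each month.")
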