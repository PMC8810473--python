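"""Markov microsimulation over the six health states, plus a deterministic
cohort-expected-value oracle.

Six states: stable disease (carrying watch-and-wait versus post-surgery
context), local recurrence with salvage, local recurrence without salvage,
distant recurrence, combined local and distant recurrence, and death.
Watch-and-wait (WW) patients enter stable disease under surveillance and may
undergo salvage resection on regrowth, after which they follow the surgical
pathway (including a possible second salvage on post-operative recurrence).
Surgical patients face a one-time perioperative death risk, an acute
post-operative disutility window, adjuvant chemotherapy, and an ostomy
(temporary for LAR, permanent for APR).

Within-cycle event order is fixed: natural death, then cancer death, then
progression draws, then accrual for the (post-transition) state occupied
that cycle. Recurring accruals are discounted at cycle midpoints
(half-cycle correction); one-time transition costs at their event cycle.

Randomness is counter-based: a single Philox stream keyed by the master seed
supplies each patient a fixed block of uniforms addressed by
(cycle, draw channel), so patient ``i``'s trajectory is identical whatever
the cohort size or iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import ARM_SURGERY, ARM_WW, ModelSpec
from .rates import schedule_table

# State codes
S_WW, S_POST, S_LS, S_LU, S_D, S_LD, S_DEAD = range(7)
STATE_NAMES = {
    S_WW: "STABLE_WW",
    S_POST: "STABLE_POST_SURGERY",
    S_LS: "LOCAL_SALVAGED",
    S_LU: "LOCAL_UNSALVAGED",
    S_D: "DISTANT",
    S_LD: "LOCAL_AND_DISTANT",
    S_DEAD: "DEAD",
}

# Death causes
DC_NONE, DC_PERIOP, DC_CANCER, DC_NATURAL = range(4)
CAUSE_NAMES = {DC_NONE: "none", DC_PERIOP: "perioperative",
               DC_CANCER: "cancer", DC_NATURAL: "natural"}

# Uniform-draw channels, fixed per (patient, cycle)
CH_NATURAL, CH_CANCER, CH_LOCAL, CH_DISTANT, CH_CONCURRENT, CH_SALVAGE, \
    CH_PERIOP_SALVAGE, CH_PERIOP_INITIAL = range(8)
N_CHANNELS = 8


class EngineError(RuntimeError):
    pass


@dataclass
class PatientTrajectory:
    """One simulated patient's path with accrued discounted cost and QALYs."""

    steps: list[tuple[int, str, list[str]]]
    discounted_cost: float
    discounted_qalys: float
    death_cause: str
    regrowth_during_ww: bool
    salvage_received: bool
    local_recurrence_post_op: bool
    distant_recurrence: bool
    combined_recurrence: bool

    def as_rows(self):
        """(cycle, state, events) rows for delimited-text export."""
        return [(c, s, ";".join(e)) for c, s, e in self.steps]


@dataclass
class MicrosimResult:
    """Cohort summaries of one simulated arm."""

    arm: str
    n_patients: int
    seed: int
    mean_cost: float
    mean_qalys: float
    regrowth_during_ww: float
    local_recurrence_post_op: float
    distant_only: float            # entered DISTANT, never the combined state
    distant_recurrence_any: float  # any distant event, incl. combined
    local_and_distant: float
    overall_5y_mortality: float
    cancer_specific_5y_mortality: float
    perioperative_mortality: float
    natural_5y_mortality: float
    se_cost: float = 0.0
    se_qalys: float = 0.0


@dataclass
class _Inputs:
    """Dense per-cycle schedules and scalar constants derived from a spec."""

    horizon: int
    q_nat: np.ndarray
    local_ww: np.ndarray          # indexed by calendar cycle - 1
    local_tme: np.ndarray         # indexed by cycles-since-surgery - 1
    p_dist_ww: float
    p_dist_tme: float
    p_dist_after_local: float
    p_conc_d: float
    p_conc_l: float
    p_salv_ww: float
    p_salv_tme: float
    p_periop: float
    q_cancer_by_state: np.ndarray  # length 7, nonzero at S_LS..S_LD
    u_ww: float
    u_acute_initial: float
    u_acute_salvage: float
    u_apr: float
    u_lar_ost: float
    u_lar_noost: float
    u_local: float
    u_distant: float
    u_ld: float
    is_apr: bool
    surgery_cost: float
    chemo_cost: float
    chemo_lo: int
    chemo_hi: int
    ww_chemo: bool
    recovery: int
    lar_ostomy: int
    ostomy_care: float
    takedown: float
    restaging_local: float
    restaging_distant: float
    reirradiation: float
    capecitabine: float
    folfox: float
    c_death_periop: float
    c_death_cancer: float
    c_death_natural: float
    surv_ww: np.ndarray            # surveillance cost by calendar cycle - 1
    surv_surg: np.ndarray          # surveillance cost by cycles-since-surgery - 1
    disc_mid: np.ndarray           # (1+r)^(-(t-0.5)/12), index t-1
    disc_event: np.ndarray         # (1+r)^(-(t-1)/12), index t-1


def _build_inputs(spec: ModelSpec) -> _Inputs:
    sched = schedule_table(spec)
    tl = spec.timeline
    horizon = tl.horizon_cycles
    t = np.arange(1, horizon + 1)
    r = 1.0 + tl.annual_discount_rate
    qc = np.zeros(7)
    qc[S_LS] = sched["mort_local_salvaged"][0]
    qc[S_LU] = sched["mort_local_unsalvaged"][0]
    qc[S_D] = sched["mort_distant"][0]
    qc[S_LD] = sched["mort_local_and_distant"][0]

    costs = spec.costs
    surv = {ARM_WW: np.zeros(horizon), ARM_SURGERY: np.zeros(horizon)}
    for arm, cal in spec.surveillance.items():
        for cycle, items in cal.items():
            surv[arm][cycle - 1] += sum(
                getattr(costs, item).mean for item in items
            )

    offset = tl.adjuvant_chemo_start_offset_cycles
    u = spec.utilities
    return _Inputs(
        horizon=horizon,
        q_nat=sched["natural"],
        local_ww=sched["local_WW"],
        local_tme=sched["local_TME"],
        p_dist_ww=float(sched["distant_WW"][0]),
        p_dist_tme=float(sched["distant_TME"][0]),
        p_dist_after_local=float(sched["distant_after_local"][0]),
        p_conc_d=spec.transitions.concurrent_distant_given_local.mean,
        p_conc_l=spec.transitions.concurrent_local_given_distant.mean,
        p_salv_ww=spec.transitions.salvage_given_local["WW"].mean,
        p_salv_tme=spec.transitions.salvage_given_local["TME"].mean,
        p_periop=spec.transitions.perioperative_death.mean,
        q_cancer_by_state=qc,
        u_ww=u.initial_ww.mean,
        # the acute postoperative row is a disutility decrement from the
        # stable-disease baseline; the salvage-TME row is already the acute
        # state level (0.80 - 0.110 = 0.69 at base case, i.e. identical)
        u_acute_initial=max(u.initial_ww.mean - u.initial_postop.mean, 0.0),
        u_acute_salvage=u.salvage_tme_disutility_state.mean,
        u_apr=u.longterm_apr.mean,
        u_lar_ost=u.longterm_lar_with_ostomy.mean,
        u_lar_noost=u.longterm_lar_without_ostomy.mean,
        u_local=u.local_recurrence.mean,
        u_distant=u.distant_recurrence.mean,
        u_ld=u.local_and_distant.mean,
        is_apr=spec.surgery_name == "APR",
        surgery_cost=spec.surgery_cost.mean,
        chemo_cost=costs.adjuvant_chemo_per_cycle.mean,
        chemo_lo=offset + 1,
        chemo_hi=offset + tl.adjuvant_chemo_cycles,
        ww_chemo=tl.ww_adjuvant_chemo,
        recovery=tl.postop_recovery_cycles,
        lar_ostomy=tl.lar_ostomy_cycles,
        ostomy_care=costs.ostomy_care_monthly.mean,
        takedown=costs.ostomy_takedown.mean,
        restaging_local=costs.restaging_local.mean,
        restaging_distant=costs.restaging_distant.mean,
        reirradiation=costs.reirradiation_course.mean,
        capecitabine=costs.palliative_capecitabine_per_cycle.mean,
        folfox=costs.palliative_mfolfox6_per_cycle.mean,
        c_death_periop=costs.death_perioperative.mean,
        c_death_cancer=costs.death_cancer.mean,
        c_death_natural=costs.death_non_cancer.mean,
        surv_ww=surv[ARM_WW],
        surv_surg=surv[ARM_SURGERY],
        disc_mid=r ** (-(t - 0.5) / 12.0),
        disc_event=r ** (-(t - 1.0) / 12.0),
    )


def _draw_block(seed, n: int, horizon: int) -> np.ndarray:
    """Patient-blocked uniforms: element [i, t, ch] depends only on (seed, i)."""
    rng = np.random.Generator(np.random.Philox(seed))
    return rng.random((n, horizon, N_CHANNELS))


def _simulate_kernel(spec: ModelSpec, arm: str, n: int, seed,
                     record_states: bool = False) -> dict:
    """Vectorized cohort simulation; returns per-patient accrual arrays."""
    if arm not in (ARM_WW, ARM_SURGERY):
        raise EngineError(f"arm must be {ARM_WW!r} or {ARM_SURGERY!r}, got {arm!r}")
    if n < 1:
        raise EngineError(f"cohort size must be >= 1, got {n}")
    inp = _build_inputs(spec)
    H = inp.horizon
    draws = _draw_block(seed, n, H)

    state = np.full(n, S_WW if arm == ARM_WW else S_POST, dtype=np.int8)
    entry = np.ones(n, dtype=np.int32)
    salvage_entry = np.zeros(n, dtype=bool)
    ostomy_perm = np.zeros(n, dtype=bool)
    death_cause = np.zeros(n, dtype=np.int8)
    cost = np.zeros(n)
    qaly = np.zeros(n)
    qaly_undisc = np.zeros(n)
    regrowth_ww = np.zeros(n, dtype=bool)
    recur_post = np.zeros(n, dtype=bool)
    salvaged = np.zeros(n, dtype=bool)
    ever_d = np.zeros(n, dtype=bool)
    ever_ld = np.zeros(n, dtype=bool)
    states_log = np.zeros((n, H + 1), dtype=np.int8) if record_states else None

    if arm == ARM_SURGERY:
        # surgery cost at entry (cycle-1 event, undiscounted), one-time
        # perioperative-death draw before the first cycle
        cost += inp.surgery_cost * inp.disc_event[0]
        pdead = draws[:, 0, CH_PERIOP_INITIAL] < inp.p_periop
        state[pdead] = S_DEAD
        death_cause[pdead] = DC_PERIOP
        cost[pdead] += inp.c_death_periop * inp.disc_event[0]
        ostomy_perm[~pdead] = inp.is_apr
    if record_states:
        states_log[:, 0] = state

    for t in range(1, H + 1):
        U = draws[:, t - 1, :]
        de = inp.disc_event[t - 1]
        dm = inp.disc_mid[t - 1]
        start = state.copy()
        alive = start != S_DEAD

        # 1. natural death
        d_nat = alive & (U[:, CH_NATURAL] < inp.q_nat[t - 1])
        state[d_nat] = S_DEAD
        death_cause[d_nat] = DC_NATURAL
        cost[d_nat] += inp.c_death_natural * de

        # 2. cancer death in recurrence states
        in_rec = (start >= S_LS) & (start <= S_LD)
        d_can = alive & ~d_nat & in_rec & (
            U[:, CH_CANCER] < inp.q_cancer_by_state[start]
        )
        state[d_can] = S_DEAD
        death_cause[d_can] = DC_CANCER
        cost[d_can] += inp.c_death_cancer * de

        alive = state != S_DEAD

        # 3a. progression from WW-surveillance stable
        m = alive & (start == S_WW)
        if m.any():
            loc = m & (U[:, CH_LOCAL] < inp.local_ww[t - 1])
            regrowth_ww |= loc
            cost[loc] += inp.restaging_local * de
            conc = loc & (U[:, CH_CONCURRENT] < inp.p_conc_d)
            state[conc] = S_LD
            ever_ld |= conc
            cost[conc] += inp.restaging_distant * de
            rest = loc & ~conc
            salv = rest & (U[:, CH_SALVAGE] < inp.p_salv_ww)
            state[rest & ~salv] = S_LU
            cost[salv] += inp.surgery_cost * de
            salvaged |= salv
            pdead = salv & (U[:, CH_PERIOP_SALVAGE] < inp.p_periop)
            state[pdead] = S_DEAD
            death_cause[pdead] = DC_PERIOP
            cost[pdead] += inp.c_death_periop * de
            newpost = salv & ~pdead
            state[newpost] = S_POST
            entry[newpost] = t
            salvage_entry[newpost] = True
            if inp.is_apr:
                ostomy_perm[newpost] = True
            nol = m & ~loc
            dist = nol & (U[:, CH_DISTANT] < inp.p_dist_ww)
            cost[dist] += inp.restaging_distant * de
            concl = dist & (U[:, CH_CONCURRENT] < inp.p_conc_l)
            state[concl] = S_LD
            ever_ld |= concl
            cost[concl] += inp.restaging_local * de
            donly = dist & ~concl
            state[donly] = S_D
            ever_d |= donly

        # 3b. progression from post-surgery stable
        m = alive & (start == S_POST)
        if m.any():
            rel = np.clip(t - entry + 1, 1, H)
            loc = m & (U[:, CH_LOCAL] < inp.local_tme[rel - 1])
            recur_post |= loc
            cost[loc] += inp.restaging_local * de
            conc = loc & (U[:, CH_CONCURRENT] < inp.p_conc_d)
            state[conc] = S_LD
            ever_ld |= conc
            cost[conc] += inp.restaging_distant * de
            rest = loc & ~conc
            salv = rest & (U[:, CH_SALVAGE] < inp.p_salv_tme)
            state[rest & ~salv] = S_LU
            cost[salv] += (inp.surgery_cost + inp.reirradiation) * de
            salvaged |= salv
            pdead = salv & (U[:, CH_PERIOP_SALVAGE] < inp.p_periop)
            state[pdead] = S_DEAD
            death_cause[pdead] = DC_PERIOP
            cost[pdead] += inp.c_death_periop * de
            state[salv & ~pdead] = S_LS
            nol = m & ~loc
            dist = nol & (U[:, CH_DISTANT] < inp.p_dist_tme)
            cost[dist] += inp.restaging_distant * de
            concl = dist & (U[:, CH_CONCURRENT] < inp.p_conc_l)
            state[concl] = S_LD
            ever_ld |= concl
            cost[concl] += inp.restaging_local * de
            donly = dist & ~concl
            state[donly] = S_D
            ever_d |= donly

        # 3c. distant progression from local-recurrence states
        m = alive & ((start == S_LS) | (start == S_LU))
        dl = m & (U[:, CH_DISTANT] < inp.p_dist_after_local)
        state[dl] = S_LD
        ever_ld |= dl
        cost[dl] += inp.restaging_distant * de

        # 4. accrual for the state occupied this cycle
        util = np.zeros(n)
        rc = np.zeros(n)
        ww = state == S_WW
        util[ww] = inp.u_ww
        rc[ww] += inp.surv_ww[t - 1]
        if inp.ww_chemo and inp.chemo_lo <= t <= inp.chemo_hi:
            rc[ww] += inp.chemo_cost
        post = state == S_POST
        if post.any():
            rel = np.clip(t - entry + 1, 1, H)
            acute = post & (rel <= inp.recovery)
            util[acute & salvage_entry] = inp.u_acute_salvage
            util[acute & ~salvage_entry] = inp.u_acute_initial
            longterm = post & ~acute
            if inp.is_apr:
                util[longterm] = inp.u_apr
            else:
                util[longterm & (rel <= inp.lar_ostomy)] = inp.u_lar_ost
                util[longterm & (rel > inp.lar_ostomy)] = inp.u_lar_noost
            rc[post] += inp.surv_surg[rel[post] - 1]
            # one adjuvant block per patient: attached to the initial
            # operation only, not repeated after salvage resection
            rc[post & ~salvage_entry
               & (rel >= inp.chemo_lo) & (rel <= inp.chemo_hi)] += \
                inp.chemo_cost
            if not inp.is_apr:
                rc[post & (rel <= inp.lar_ostomy)] += inp.ostomy_care
                cost[post & (rel == inp.lar_ostomy + 1)] += inp.takedown * de
        local = (state == S_LS) | (state == S_LU)
        util[local] = inp.u_local
        util[state == S_D] = inp.u_distant
        util[state == S_LD] = inp.u_ld
        rc[state == S_LU] += inp.capecitabine
        rc[(state == S_D) | (state == S_LD)] += inp.folfox
        rc[ostomy_perm & (state != S_DEAD)] += inp.ostomy_care

        qaly += util / 12.0 * dm
        qaly_undisc += util / 12.0
        cost += rc * dm
        if record_states:
            states_log[:, t] = state

    return {
        "cost": cost,
        "qaly": qaly,
        "qaly_undisc": qaly_undisc,
        "death_cause": death_cause,
        "state": state,
        "regrowth_ww": regrowth_ww,
        "recur_post": recur_post,
        "salvaged": salvaged,
        "ever_d": ever_d,
        "ever_ld": ever_ld,
        "states_log": states_log,
    }


def simulate_cohort(spec: ModelSpec, arm: str, n: int, master_seed) -> MicrosimResult:
    """Simulate ``n`` independent patients and aggregate cohort outcomes.

    Identical (spec, arm, n, master_seed) gives a bit-identical result.
    """
    out = _simulate_kernel(spec, arm, n, master_seed)
    cost, qaly = out["cost"], out["qaly"]
    dead = out["state"] == S_DEAD
    cause = out["death_cause"]
    return MicrosimResult(
        arm=arm,
        n_patients=n,
        seed=master_seed if np.isscalar(master_seed) else tuple(master_seed),
        mean_cost=float(cost.mean()),
        mean_qalys=float(qaly.mean()),
        regrowth_during_ww=float(out["regrowth_ww"].mean()),
        local_recurrence_post_op=float(out["recur_post"].mean()),
        distant_only=float(out["ever_d"].mean()),
        distant_recurrence_any=float((out["ever_d"] | out["ever_ld"]).mean()),
        local_and_distant=float(out["ever_ld"].mean()),
        overall_5y_mortality=float(dead.mean()),
        cancer_specific_5y_mortality=float((cause == DC_CANCER).mean()),
        perioperative_mortality=float((cause == DC_PERIOP).mean()),
        natural_5y_mortality=float((cause == DC_NATURAL).mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        se_qalys=float(qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
    )


def simulate_patient(spec: ModelSpec, arm: str, master_seed,
                     patient_index: int = 0) -> PatientTrajectory:
    """Simulate one patient, bit-identical to row ``patient_index`` of a
    cohort run with the same master seed."""
    out = _simulate_kernel(spec, arm, patient_index + 1, master_seed,
                           record_states=True)
    i = patient_index
    log = out["states_log"][i]
    steps: list[tuple[int, str, list[str]]] = []
    for t in range(1, len(log)):
        events: list[str] = []
        if log[t] != log[t - 1]:
            events.append(f"{STATE_NAMES[int(log[t - 1])]}->"
                          f"{STATE_NAMES[int(log[t])]}")
        steps.append((t, STATE_NAMES[int(log[t])], events))
    return PatientTrajectory(
        steps=steps,
        discounted_cost=float(out["cost"][i]),
        discounted_qalys=float(out["qaly"][i]),
        death_cause=CAUSE_NAMES[int(out["death_cause"][i])],
        regrowth_during_ww=bool(out["regrowth_ww"][i]),
        salvage_received=bool(out["salvaged"][i]),
        local_recurrence_post_op=bool(out["recur_post"][i]),
        distant_recurrence=bool(out["ever_d"][i]),
        combined_recurrence=bool(out["ever_ld"][i]),
    )


# ---------------------------------------------------------------------------
# Deterministic cohort-expected-value oracle
# ---------------------------------------------------------------------------

def cohort_expected_value(spec: ModelSpec, arm: str):
    """Exact expected (cost, QALYs) by forward propagation of occupancy.

    Propagates state-occupancy probability through the same schedules, event
    logic and accrual rules as the microsimulation, expanding the
    post-surgery stable state by its entry cycle (its recurrence schedule,
    chemotherapy and ostomy windows are clocked from surgery). Returns
    ``(expected_cost, expected_qalys, occupancy)`` with ``occupancy`` of
    shape (horizon+1, 7) over the aggregate states; each row sums to 1.
    """
    if arm not in (ARM_WW, ARM_SURGERY):
        raise EngineError(f"unknown arm {arm!r}")
    inp = _build_inputs(spec)
    H = inp.horizon
    cost = 0.0
    qaly = 0.0
    occupancy = np.zeros((H + 1, 7))

    # mass keyed by:
    #  ("WW",) | ("POST", entry_cycle, salvage_entry) |
    #  (code, has_permanent_ostomy) for recurrence states | ("DEAD",)
    mass: dict[tuple, float] = {}
    if arm == ARM_WW:
        mass[("WW",)] = 1.0
    else:
        cost += inp.surgery_cost * inp.disc_event[0]
        pd = inp.p_periop
        mass[("DEAD",)] = pd
        cost += pd * inp.c_death_periop * inp.disc_event[0]
        mass[("POST", 1, False)] = 1.0 - pd

    def agg(key) -> int:
        if key[0] == "WW":
            return S_WW
        if key[0] == "POST":
            return S_POST
        if key[0] == "DEAD":
            return S_DEAD
        return key[0]

    for key, m in mass.items():
        occupancy[0, agg(key)] += m

    for t in range(1, H + 1):
        de = inp.disc_event[t - 1]
        dm = inp.disc_mid[t - 1]
        q_nat = inp.q_nat[t - 1]
        new: dict[tuple, float] = {}

        def add(key, m):
            if m != 0.0:
                new[key] = new.get(key, 0.0) + m

        dead_flux_cost = 0.0

        for key, m in mass.items():
            if m == 0.0:
                continue
            kind = key[0]
            if kind == "DEAD":
                add(key, m)
                continue
            # 1. natural death
            f_nat = m * q_nat
            dead_flux_cost += f_nat * inp.c_death_natural * de
            add(("DEAD",), f_nat)
            m = m - f_nat
            if kind == "WW":
                p_loc = inp.local_ww[t - 1]
                f_loc = m * p_loc
                cost += f_loc * inp.restaging_local * de
                f_conc = f_loc * inp.p_conc_d
                cost += f_conc * inp.restaging_distant * de
                add((S_LD, False), f_conc)
                rest = f_loc - f_conc
                f_salv = rest * inp.p_salv_ww
                add((S_LU, False), rest - f_salv)
                cost += f_salv * inp.surgery_cost * de
                f_pd = f_salv * inp.p_periop
                dead_flux_cost += f_pd * inp.c_death_periop * de
                add(("DEAD",), f_pd)
                add(("POST", t, True), f_salv - f_pd)
                nol = m - f_loc
                f_dist = nol * inp.p_dist_ww
                cost += f_dist * inp.restaging_distant * de
                f_cl = f_dist * inp.p_conc_l
                cost += f_cl * inp.restaging_local * de
                add((S_LD, False), f_cl)
                add((S_D, False), f_dist - f_cl)
                add(("WW",), nol - f_dist)
            elif kind == "POST":
                _, e, salvage_in = key
                ost = inp.is_apr
                rel = min(t - e + 1, H)
                p_loc = inp.local_tme[rel - 1]
                f_loc = m * p_loc
                cost += f_loc * inp.restaging_local * de
                f_conc = f_loc * inp.p_conc_d
                cost += f_conc * inp.restaging_distant * de
                add((S_LD, ost), f_conc)
                rest = f_loc - f_conc
                f_salv = rest * inp.p_salv_tme
                add((S_LU, ost), rest - f_salv)
                cost += f_salv * (inp.surgery_cost + inp.reirradiation) * de
                f_pd = f_salv * inp.p_periop
                dead_flux_cost += f_pd * inp.c_death_periop * de
                add(("DEAD",), f_pd)
                add((S_LS, ost), f_salv - f_pd)
                nol = m - f_loc
                f_dist = nol * inp.p_dist_tme
                cost += f_dist * inp.restaging_distant * de
                f_cl = f_dist * inp.p_conc_l
                cost += f_cl * inp.restaging_local * de
                add((S_LD, ost), f_cl)
                add((S_D, ost), f_dist - f_cl)
                add(key, nol - f_dist)
            else:
                code, ost = key
                # 2. cancer death
                f_can = m * inp.q_cancer_by_state[code]
                dead_flux_cost += f_can * inp.c_death_cancer * de
                add(("DEAD",), f_can)
                m = m - f_can
                if code in (S_LS, S_LU):
                    f_dl = m * inp.p_dist_after_local
                    cost += f_dl * inp.restaging_distant * de
                    add((S_LD, ost), f_dl)
                    add(key, m - f_dl)
                else:
                    add(key, m)

        cost += dead_flux_cost

        # 4. accrual on post-transition occupancy
        for key, m in new.items():
            if m == 0.0 or key[0] == "DEAD":
                occupancy[t, S_DEAD] += m if key[0] == "DEAD" else 0.0
                continue
            kind = key[0]
            occupancy[t, agg(key)] += m
            if kind == "WW":
                qaly += m * inp.u_ww / 12.0 * dm
                rc_ww = inp.surv_ww[t - 1]
                if inp.ww_chemo and inp.chemo_lo <= t <= inp.chemo_hi:
                    rc_ww += inp.chemo_cost
                cost += m * rc_ww * dm
            elif kind == "POST":
                _, e, salvage_in = key
                rel = min(t - e + 1, H)
                if rel <= inp.recovery:
                    u = inp.u_acute_salvage if salvage_in else inp.u_acute_initial
                elif inp.is_apr:
                    u = inp.u_apr
                elif rel <= inp.lar_ostomy:
                    u = inp.u_lar_ost
                else:
                    u = inp.u_lar_noost
                qaly += m * u / 12.0 * dm
                rc = inp.surv_surg[rel - 1]
                if not salvage_in and inp.chemo_lo <= rel <= inp.chemo_hi:
                    rc += inp.chemo_cost
                if inp.is_apr:
                    rc += inp.ostomy_care
                else:
                    if rel <= inp.lar_ostomy:
                        rc += inp.ostomy_care
                    if rel == inp.lar_ostomy + 1:
                        cost += m * inp.takedown * de
                cost += m * rc * dm
            else:
                code, ost = key
                u = {S_LS: inp.u_local, S_LU: inp.u_local,
                     S_D: inp.u_distant, S_LD: inp.u_ld}[code]
                qaly += m * u / 12.0 * dm
                rc = 0.0
                if code == S_LU:
                    rc += inp.capecitabine
                if code in (S_D, S_LD):
                    rc += inp.folfox
                if ost:
                    rc += inp.ostomy_care
                cost += m * rc * dm
        mass = new

    return float(cost), float(qaly), occupancy
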