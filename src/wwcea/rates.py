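"""Converting interval-cumulative probabilities to per-cycle probabilities.

The source tables state risks as cumulative probabilities over 2-, 3- or
5-year horizons; the simulation runs on monthly cycles. Within each interval
the hazard is taken as constant (the minimal assumption given only an
interval-cumulative value), so a cumulative probability ``P`` over ``n``
cycles converts to the per-cycle probability ``p`` with ``1-(1-p)**n = P``.
"""

from __future__ import annotations

import numpy as np

from .parameters import LifeTable, ModelSpec

MONTHS_2Y = 24
MONTHS_3Y = 36
MONTHS_5Y = 60


def per_cycle_from_cumulative(P: float, n: int) -> float:
    """Per-cycle probability ``p`` such that ``1 - (1-p)**n = P``."""
    if not 0.0 <= P < 1.0:
        raise ValueError(
            f"cumulative probability must be in [0, 1), got {P}"
            + (" (P = 1 implies an infinite hazard)" if P == 1.0 else "")
        )
    if n < 1:
        raise ValueError(f"number of cycles must be >= 1, got {n}")
    return float(-np.expm1(np.log1p(-P) / n))


def piecewise_local_schedule(P2y: float, P5y: float,
                             horizon: int = MONTHS_5Y) -> np.ndarray:
    """Monthly local-recurrence/regrowth probabilities over the horizon.

    The published 2-year and 5-year rows are treated as two independent
    hazard sources: cycles 1-24 use the 2-year cumulative converted over 24
    cycles, and cycles 25 onward use the 5-year cumulative converted over the
    full 60-cycle horizon. This piecewise form reproduces the reported
    cohort regrowth proportions; reading the 5-year row instead as the
    continuation of one cumulative curve would not (and for the surgical arm
    would imply a decreasing cumulative incidence, 0.016 at 2 years versus
    0.010 at 5).

    Returns an array of length ``horizon`` indexed by cycle-1.
    """
    p_early = per_cycle_from_cumulative(P2y, MONTHS_2Y)
    p_late = per_cycle_from_cumulative(P5y, MONTHS_5Y)
    sched = np.empty(horizon)
    sched[:MONTHS_2Y] = p_early
    sched[MONTHS_2Y:] = p_late
    return sched


def per_cycle_mortality(P5y: float) -> float:
    """Constant monthly probability from a 5-year state-specific mortality."""
    return per_cycle_from_cumulative(P5y, MONTHS_5Y)


def natural_death_probability(life_table: LifeTable, baseline_age: float,
                              cycle: int) -> float:
    """Monthly background-mortality probability at the attained age.

    Cycle 1 is the first month; the attained age advances one year every 12
    cycles (cycle 13 uses baseline + 1).
    """
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle}")
    age = baseline_age + (cycle - 1) // 12
    annual = life_table.annual_probability(age)
    return per_cycle_from_cumulative(annual, 12)


def natural_death_schedule(spec: ModelSpec) -> np.ndarray:
    """Monthly natural-death probabilities for cycles 1..horizon."""
    horizon = spec.timeline.horizon_cycles
    if spec.natural_mortality_monthly is not None:
        return np.full(horizon, float(spec.natural_mortality_monthly))
    return np.array([
        natural_death_probability(spec.life_table,
                                  spec.timeline.baseline_age_years, t)
        for t in range(1, horizon + 1)
    ])


def schedule_table(spec: ModelSpec) -> dict[str, np.ndarray]:
    """All per-cycle transition probabilities implied by a spec.

    Keys: ``local_WW``, ``local_TME`` (arrays indexed by cycle-within-phase),
    ``distant_WW``, ``distant_TME``, ``distant_after_local``,
    ``mort_local_salvaged``, ``mort_local_unsalvaged``, ``mort_distant``,
    ``mort_local_and_distant`` (scalars broadcast to arrays), and
    ``natural`` (by calendar cycle).
    """
    tr = spec.transitions
    horizon = spec.timeline.horizon_cycles
    const = lambda p: np.full(horizon, p)
    out = {
        "natural": natural_death_schedule(spec),
        "distant_after_local": const(
            per_cycle_from_cumulative(tr.distant_after_local_3y.mean, MONTHS_3Y)
        ),
        "mort_local_salvaged": const(
            per_cycle_mortality(tr.mortality_local_salvaged_5y.mean)),
        "mort_local_unsalvaged": const(
            per_cycle_mortality(tr.mortality_local_unsalvaged_5y.mean)),
        "mort_distant": const(per_cycle_mortality(tr.mortality_distant_5y.mean)),
        "mort_local_and_distant": const(
            per_cycle_mortality(tr.mortality_local_and_distant_5y.mean)),
    }
    for arm in ("WW", "TME"):
        out[f"local_{arm}"] = piecewise_local_schedule(
            tr.local_recurrence_2y[arm].mean,
            tr.local_recurrence_5y[arm].mean,
            horizon,
        )
        out[f"distant_{arm}"] = const(
            per_cycle_from_cumulative(tr.distant_recurrence_5y[arm].mean,
                                      MONTHS_5Y)
        )
    return out
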