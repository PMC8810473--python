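"""Cost-effectiveness arithmetic: ICER, dominance, net monetary benefit and
acceptability curves.

Conventions: ``compare(a, b, wtp)`` reports strategy *a* against comparator
*b*. The incremental cost-effectiveness ratio (ICER) is the incremental cost
divided by the incremental QALYs; it is undefined when the strategies are in
a dominance quadrant (one is both cheaper and more effective) or equally
effective. A strategy that lowers cost and raises QALYs dominates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Classification labels
A_DOMINATES = "A_dominates"
B_DOMINATES = "B_dominates"
ICER_BELOW_WTP = "icer_below_wtp"
ICER_ABOVE_WTP = "icer_above_wtp"
EQUAL = "equal"


@dataclass(frozen=True)
class CeaResult:
    """Pairwise comparison of strategy A against comparator B."""

    cost_a: float
    qaly_a: float
    cost_b: float
    qaly_b: float
    wtp: float
    incremental_cost: float
    incremental_effect: float
    icer: float | None
    classification: str

    @property
    def icer_label(self) -> str:
        if self.classification == B_DOMINATES:
            return "Dominated"
        if self.classification == A_DOMINATES:
            return "Dominant"
        if self.icer is None:
            return "Equal effectiveness"
        return f"{self.icer:,.2f}"


def _cost_qaly(result) -> tuple[float, float]:
    if hasattr(result, "mean_cost"):
        return float(result.mean_cost), float(result.mean_qalys)
    cost, qaly = result
    return float(cost), float(qaly)


def compare(result_a, result_b, wtp: float) -> CeaResult:
    """Classify strategy A against B at a willingness-to-pay threshold.

    Accepts ``MicrosimResult``-like objects or plain (cost, qaly) pairs.
    """
    cost_a, qaly_a = _cost_qaly(result_a)
    cost_b, qaly_b = _cost_qaly(result_b)
    d_cost = cost_a - cost_b
    d_eff = qaly_a - qaly_b
    icer: float | None = None
    if d_cost == 0.0 and d_eff == 0.0:
        classification = EQUAL
    elif d_eff > 0 and d_cost <= 0:
        classification = A_DOMINATES
    elif d_eff < 0 and d_cost >= 0:
        classification = B_DOMINATES
    elif d_eff == 0.0:
        # same effectiveness, different cost: cheaper strategy dominates
        classification = A_DOMINATES if d_cost < 0 else B_DOMINATES
    else:
        icer = d_cost / d_eff
        if d_eff > 0:  # A costlier and more effective
            classification = ICER_BELOW_WTP if icer <= wtp else ICER_ABOVE_WTP
        else:  # A cheaper and less effective: B's ICER vs A is |d_cost/d_eff|
            classification = ICER_ABOVE_WTP if icer <= wtp else ICER_BELOW_WTP
    return CeaResult(
        cost_a=cost_a, qaly_a=qaly_a, cost_b=cost_b, qaly_b=qaly_b, wtp=wtp,
        incremental_cost=d_cost, incremental_effect=d_eff,
        icer=icer, classification=classification,
    )


def nmb(result, wtp: float) -> float:
    """Net monetary benefit, ``wtp * QALYs - cost``."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be >= 0, got {wtp}")
    cost, qaly = _cost_qaly(result)
    return wtp * qaly - cost


def default_wtp_grid(upper: float = 250_000.0, step: float = 10_000.0) -> np.ndarray:
    return np.arange(0.0, upper + step / 2, step)


def acceptability_curve(psa_draws, wtp_grid) -> np.ndarray:
    """Fraction of PSA draws in which WW is optimal at each WTP.

    ``psa_draws`` supply per-arm (cost, QALY) pairs (see
    :class:`wwcea.sensitivity.PsaDraw`); WW is optimal when its net monetary
    benefit strictly exceeds the surgical arm's, or when it dominates.
    """
    draws = list(psa_draws)
    if not draws:
        raise ValueError("acceptability_curve needs at least one PSA draw")
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    cost_ww = np.array([d.cost_ww for d in draws])
    qaly_ww = np.array([d.qaly_ww for d in draws])
    cost_s = np.array([d.cost_surgery for d in draws])
    qaly_s = np.array([d.qaly_surgery for d in draws])
    frac = np.empty_like(wtp_grid)
    for j, w in enumerate(wtp_grid):
        frac[j] = np.mean(
            w * qaly_ww - cost_ww > w * qaly_s - cost_s
        )
    return frac
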