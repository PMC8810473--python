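"""Deterministic one-way sensitivity analysis and probabilistic sensitivity
analysis (PSA).

One-way analysis sweeps a single parameter across its range with every other
parameter at base case, classifies each point with the deterministic
cohort-expected-value evaluator (so band boundaries are noise-free), and
refines the boundaries by bisection. PSA draws parameter sets — β
distributions for probabilities and utilities, γ for costs, both fit by
method of moments — and evaluates each draw with a full microsimulation per
arm.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as scipy_stats

from . import cea
from .engine import cohort_expected_value, simulate_cohort
from .parameters import (ARM_SURGERY, ARM_WW, ModelSpec, ParameterValue,
                         iter_parameters, set_parameter)

logger = logging.getLogger("wwcea")

# One-way classification labels, from the surgery-versus-WW perspective
WW_DOMINATES = "ww_dominates"
SURGERY_NOT_CE = "surgery_not_cost_effective"
SURGERY_CE = "surgery_cost_effective"

BETA_CLIP_FRACTION = 0.95  # sd clipped to 0.95 * sqrt(mean(1-mean))


def beta_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments (alpha, beta) for a β distribution."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must be in (0, 1), got {mean}")
    var_bound = mean * (1.0 - mean)
    if not 0.0 < sd**2 < var_bound:
        raise ValueError(
            f"beta sd must satisfy 0 < sd^2 < mean*(1-mean) = {var_bound:.4g}; "
            f"got sd = {sd}. Clip the sd below sqrt(mean*(1-mean)) "
            f"(see clip_beta_sd)."
        )
    nu = var_bound / sd**2 - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments (shape, scale) for a γ distribution."""
    if mean <= 0 or sd <= 0:
        raise ValueError(f"gamma mean and sd must be > 0, got {mean}, {sd}")
    return mean**2 / sd**2, sd**2 / mean


def clip_beta_sd(mean: float, sd: float) -> float:
    """Clip an sd that violates the β-variance bound (warns when it does)."""
    bound = np.sqrt(mean * (1.0 - mean))
    if sd >= bound:
        clipped = BETA_CLIP_FRACTION * bound
        logger.warning(
            "beta sd %.4g >= variance bound for mean %.4g; clipped to %.4g",
            sd, mean, clipped,
        )
        return clipped
    return sd


def sample_parameter(pv: ParameterValue, rng: np.random.Generator,
                     quantile: float | None = None) -> float:
    """One random realization of a parameter from its distribution family.

    When ``quantile`` is given, the value is the inverse CDF at that
    quantile instead of an independent draw (used for rank-correlated
    utility sampling).
    """
    if pv.family == "fixed" or pv.sd == 0.0:
        return pv.mean
    if pv.family == "beta":
        if pv.mean <= 0.0 or pv.mean >= 1.0:
            return pv.mean  # degenerate endpoint, no spread possible
        sd = clip_beta_sd(pv.mean, pv.sd)
        a, b = beta_params_from_moments(pv.mean, sd)
        x = (scipy_stats.beta.ppf(quantile, a, b) if quantile is not None
             else rng.beta(a, b))
        # keep draws strictly below 1 so cumulative->per-cycle conversion
        # stays defined
        return min(float(x), 1.0 - 1e-9)
    if pv.family == "gamma":
        if pv.mean <= 0.0:
            return pv.mean
        shape, scale = gamma_params_from_moments(pv.mean, pv.sd)
        if quantile is not None:
            return float(scipy_stats.gamma.ppf(quantile, shape) * scale)
        return float(rng.gamma(shape) * scale)
    raise ValueError(f"unknown family {pv.family!r}")


def sample_spec(spec: ModelSpec, rng: np.random.Generator,
                correlated_utilities: bool = True) -> ModelSpec:
    """Draw one full parameter-set realization (fixed parameters untouched).

    Parameters are sampled in sorted-path order, so the draw is reproducible
    from the generator state alone. Probabilities and costs are sampled
    independently. Health-state utilities are, by default, drawn at one
    shared quantile per realization (comonotone): they come from a common
    survey population, and patient-reported quality of life after
    chemoradiation alone consistently ranks above life after radical
    surgery, so the cross-state ordering is preserved while each utility
    still varies over its full marginal β distribution. Pass
    ``correlated_utilities=False`` for fully independent draws.
    """
    new = spec.copy()
    u_quantile = float(rng.random()) if correlated_utilities else None
    for path, pv in iter_parameters(spec):
        if pv.family == "fixed":
            continue
        q = u_quantile if path.startswith("utilities.") else None
        value = sample_parameter(pv, rng, quantile=q)
        parts = path.split(".")
        obj = new
        for part in parts[:-1]:
            obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
        leaf = parts[-1]
        sampled = dataclasses.replace(pv, mean=value, sd=0.0)
        if isinstance(obj, dict):
            obj[leaf] = sampled
        else:
            setattr(obj, leaf, sampled)
    return new.validate()


# ---------------------------------------------------------------------------
# One-way (deterministic) sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class DsaResult:
    """Outcome bands of one parameter sweep."""

    parameter: str
    lower: float
    upper: float
    bands: list[tuple[float, float, str]]  # (lo, hi, label), partition
    thresholds: list[float]                # band boundaries inside the range

    @property
    def remains_dominated(self) -> bool:
        return all(label == WW_DOMINATES for _, _, label in self.bands)

    def threshold_for(self, label: str) -> float | None:
        """Lower edge of the first band carrying ``label``, if any."""
        for lo, _, lab in self.bands:
            if lab == label:
                return lo
        return None


def oracle_evaluator(spec: ModelSpec, arm: str) -> tuple[float, float]:
    cost, qaly, _ = cohort_expected_value(spec, arm)
    return cost, qaly


def classify_point(spec: ModelSpec, wtp: float, evaluator=oracle_evaluator) -> str:
    """Three-way label of surgery relative to WW at one parameter setting."""
    ww = evaluator(spec, ARM_WW)
    surg = evaluator(spec, ARM_SURGERY)
    res = cea.compare(surg, ww, wtp)
    if res.classification == cea.B_DOMINATES:
        return WW_DOMINATES
    if res.classification in (cea.A_DOMINATES, cea.ICER_BELOW_WTP):
        return SURGERY_CE
    return SURGERY_NOT_CE


def _with_value(spec: ModelSpec, path: str, value: float) -> ModelSpec:
    if path == "natural_mortality_monthly":
        new = spec.copy()
        new.natural_mortality_monthly = float(value)
        return new
    return set_parameter(spec, path, mean=value)


def one_way(spec: ModelSpec, parameter: str, lower: float, upper: float,
            wtp: float | None = None, evaluator=oracle_evaluator,
            n_grid: int = 17) -> DsaResult:
    """Sweep one parameter, classify each grid point, bisect band boundaries.

    Boundaries are refined to 1e-3 absolute for probabilities/utilities and
    $1 for costs.
    """
    if lower > upper:
        raise ValueError(f"{parameter}: lower {lower} > upper {upper}")
    if wtp is None:
        wtp = spec.timeline.wtp_threshold
    tol = 1.0 if parameter.startswith("costs.") else 1e-3

    def label_at(x: float) -> str:
        return classify_point(_with_value(spec, parameter, x), wtp, evaluator)

    if lower == upper:
        lab = label_at(lower)
        return DsaResult(parameter, lower, upper,
                         bands=[(lower, upper, lab)], thresholds=[])

    grid = np.linspace(lower, upper, n_grid)
    labels = [label_at(x) for x in grid]

    boundaries: list[float] = []
    merged: list[tuple[float, str]] = [(grid[0], labels[0])]
    for (x0, l0), (x1, l1) in zip(zip(grid[:-1], labels[:-1]),
                                  zip(grid[1:], labels[1:])):
        if l1 == l0:
            continue
        lo, hi = x0, x1
        lab_lo = l0
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if label_at(mid) == lab_lo:
                lo = mid
            else:
                hi = mid
        boundary = 0.5 * (lo + hi)
        boundaries.append(boundary)
        merged.append((boundary, l1))

    bands: list[tuple[float, float, str]] = []
    for i, (start, lab) in enumerate(merged):
        end = merged[i + 1][0] if i + 1 < len(merged) else upper
        if bands and bands[-1][2] == lab:
            bands[-1] = (bands[-1][0], end, lab)
        else:
            bands.append((start, end, lab))
    return DsaResult(parameter, lower, upper, bands=bands,
                     thresholds=boundaries)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PsaDraw:
    """One PSA iteration: a sampled parameter set and its per-arm outcomes."""

    iteration: int
    seed: int
    cost_ww: float
    qaly_ww: float
    cost_surgery: float
    qaly_surgery: float
    sampled_spec: ModelSpec | None = None


def microsim_evaluator(spec: ModelSpec, arm: str, n: int, seed) -> tuple[float, float]:
    res = simulate_cohort(spec, arm, n, seed)
    return res.mean_cost, res.mean_qalys


def psa(spec: ModelSpec, n_outer: int, n_inner: int, master_seed: int,
        evaluator=microsim_evaluator, keep_specs: bool = False) -> list[PsaDraw]:
    """Run ``n_outer`` parameter draws, each evaluated with an
    ``n_inner``-patient microsimulation per arm.

    Fully reproducible from ``master_seed``: draw ``i`` samples parameters
    from a stream keyed (master_seed, i) and simulates each arm with nested
    substreams keyed (master_seed, i, arm).
    """
    if n_outer < 1 or n_inner < 1:
        raise ValueError("n_outer and n_inner must be >= 1")
    draws: list[PsaDraw] = []
    for i in range(n_outer):
        rng = np.random.default_rng([master_seed, i])
        sampled = sample_spec(spec, rng)
        cost_ww, qaly_ww = evaluator(sampled, ARM_WW, n_inner,
                                     [master_seed, i, 0])
        cost_s, qaly_s = evaluator(sampled, ARM_SURGERY, n_inner,
                                   [master_seed, i, 1])
        draws.append(PsaDraw(
            iteration=i, seed=master_seed,
            cost_ww=cost_ww, qaly_ww=qaly_ww,
            cost_surgery=cost_s, qaly_surgery=qaly_s,
            sampled_spec=sampled if keep_specs else None,
        ))
    return draws


def ww_optimal_fraction(draws, wtp_grid=None) -> float:
    """Fraction of PSA draws in which WW is dominant or has the higher net
    monetary benefit at *every* willingness-to-pay on the grid."""
    if wtp_grid is None:
        wtp_grid = cea.default_wtp_grid(200_000.0)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    wins = 0
    for d in draws:
        nmb_ww = wtp_grid * d.qaly_ww - d.cost_ww
        nmb_s = wtp_grid * d.qaly_surgery - d.cost_surgery
        if np.all(nmb_ww > nmb_s):
            wins += 1
    return wins / len(draws)
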