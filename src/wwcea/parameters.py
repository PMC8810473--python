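"""Model parameterization: loading, validation and serialization.

A :class:`ModelSpec` carries everything one comparison (watch-and-wait versus
APR, or versus LAR) needs: the transition-probability table, health-state
utilities, payer-perspective costs in 2019 US$, timeline constants, a
background-mortality life table, and the surveillance calendar. The two
base-case parameter sets ship as packaged YAML fixtures whose rows mirror the
published parameter tables.

Probabilities and utilities carry β sampling distributions, costs carry γ
distributions; a parameter whose standard deviation is not reported gets
SD = 20% of its mean.
"""

from __future__ import annotations

import copy
import dataclasses
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterator

import numpy as np
import yaml

logger = logging.getLogger("wwcea")

# Strategy arms within one model
ARM_WW = "WW"
ARM_SURGERY = "SURGERY"

# Transition-parameter arms: WW surveillance vs the surgical (TME) pathway
TRANS_ARMS = ("WW", "TME")

COMPARISONS = ("WW_vs_APR", "WW_vs_LAR")

FAMILIES = ("beta", "gamma", "fixed")

SD_FRACTION_DEFAULT = 0.20  # SD = 20% of mean when not reported


class SpecValidationError(ValueError):
    """A parameter document violated the schema or a range constraint."""


@dataclass(frozen=True)
class ParameterValue:
    """One uncertain scalar: a probability, utility, or 2019 US$ amount."""

    mean: float
    sd: float
    family: str  # "beta" | "gamma" | "fixed"
    source_label: str = ""

    def validate(self, name: str) -> None:
        if self.family not in FAMILIES:
            raise SpecValidationError(
                f"{name}: unknown distribution family {self.family!r}"
            )
        if not np.isfinite(self.mean):
            raise SpecValidationError(f"{name}: non-finite mean")
        if self.sd < 0:
            raise SpecValidationError(f"{name}: sd must be >= 0, got {self.sd}")
        if self.family == "beta":
            if not 0.0 <= self.mean <= 1.0:
                raise SpecValidationError(
                    f"{name}: probability/utility mean {self.mean} outside [0, 1]"
                )
            var_bound = self.mean * (1.0 - self.mean)
            if self.sd > 0 and self.sd**2 >= var_bound:
                # Several published rows sit at/over the β-variance bound;
                # sampling clips them (see sensitivity module), loading warns.
                logger.warning(
                    "%s: sd %.4g exceeds the beta-variance bound for mean %.4g; "
                    "PSA sampling will clip it",
                    name,
                    self.sd,
                    self.mean,
                )
        elif self.family == "gamma":
            if self.mean < 0:
                raise SpecValidationError(
                    f"{name}: cost mean must be >= 0, got {self.mean}"
                )


def _pv(node: Any, name: str, default_family: str) -> ParameterValue:
    """Build a ParameterValue from a YAML node, filling a missing sd."""
    if isinstance(node, (int, float)):
        node = {"mean": float(node)}
    if not isinstance(node, dict) or "mean" not in node:
        raise SpecValidationError(f"{name}: expected a mapping with a 'mean' entry")
    mean = float(node["mean"])
    family = str(node.get("family", default_family))
    if "sd" in node and node["sd"] is not None:
        sd = float(node["sd"])
    else:
        sd = 0.0 if family == "fixed" else SD_FRACTION_DEFAULT * mean
        if family != "fixed":
            logger.info("%s: sd not given, filled as 20%% of mean (%.4g)", name, sd)
    pv = ParameterValue(mean=mean, sd=sd, family=family,
                        source_label=str(node.get("source", "")))
    pv.validate(name)
    return pv


def _pv_dict(pv: ParameterValue) -> dict:
    out: dict[str, Any] = {"mean": pv.mean, "sd": pv.sd, "family": pv.family}
    if pv.source_label:
        out["source"] = pv.source_label
    return out


@dataclass
class TransitionTable:
    """Table of transition probabilities; arm-specific rows keyed WW / TME."""

    perioperative_death: ParameterValue
    local_recurrence_2y: dict[str, ParameterValue]
    local_recurrence_5y: dict[str, ParameterValue]
    salvage_given_local: dict[str, ParameterValue]
    distant_recurrence_5y: dict[str, ParameterValue]
    concurrent_distant_given_local: ParameterValue
    concurrent_local_given_distant: ParameterValue
    distant_after_local_3y: ParameterValue
    mortality_local_salvaged_5y: ParameterValue
    mortality_local_unsalvaged_5y: ParameterValue
    mortality_distant_5y: ParameterValue
    mortality_local_and_distant_5y: ParameterValue

    ARM_FIELDS = (
        "local_recurrence_2y",
        "local_recurrence_5y",
        "salvage_given_local",
        "distant_recurrence_5y",
    )

    def validate(self) -> None:
        for name, value in _walk_table(self, "transitions"):
            value.validate(name)
            if not 0.0 <= value.mean <= 1.0:
                raise SpecValidationError(
                    f"{name}: probability {value.mean} outside [0, 1]"
                )
        for f in self.ARM_FIELDS:
            arms = getattr(self, f)
            if set(arms) != set(TRANS_ARMS):
                raise SpecValidationError(
                    f"transitions.{f}: arms must be exactly {set(TRANS_ARMS)}, "
                    f"got {set(arms)}"
                )


@dataclass
class UtilityTable:
    """Health-state utilities in QALY weight (0 = death, 1 = perfect health)."""

    initial_ww: ParameterValue
    initial_postop: ParameterValue
    salvage_tme_disutility_state: ParameterValue
    longterm_apr: ParameterValue
    longterm_lar_with_ostomy: ParameterValue
    longterm_lar_without_ostomy: ParameterValue
    local_recurrence: ParameterValue
    distant_recurrence: ParameterValue
    local_and_distant: ParameterValue
    death: ParameterValue = field(
        default_factory=lambda: ParameterValue(0.0, 0.0, "fixed")
    )

    def validate(self) -> None:
        for name, value in _walk_table(self, "utilities"):
            value.validate(name)
            if not 0.0 <= value.mean <= 1.0:
                raise SpecValidationError(f"{name}: utility {value.mean} outside [0,1]")
        if self.death.mean != 0.0 or self.death.family != "fixed":
            raise SpecValidationError("utilities.death: must be fixed at exactly 0")


@dataclass
class CostTable:
    """Payer-perspective costs in 2019 US$."""

    surgery_lar: ParameterValue
    surgery_apr: ParameterValue
    adjuvant_chemo_per_cycle: ParameterValue
    ostomy_takedown: ParameterValue
    ostomy_care_monthly: ParameterValue
    office_visit: ParameterValue
    rectal_exam: ParameterValue
    flex_sig: ParameterValue
    cea: ParameterValue
    colonoscopy: ParameterValue
    colonoscopy_stoma: ParameterValue
    ct_abd_pelvis: ParameterValue
    ct_chest: ParameterValue
    mri_pelvis: ParameterValue
    restaging_local: ParameterValue
    restaging_distant: ParameterValue
    reirradiation_course: ParameterValue
    palliative_capecitabine_per_cycle: ParameterValue
    palliative_mfolfox6_per_cycle: ParameterValue
    death_perioperative: ParameterValue
    death_cancer: ParameterValue
    death_non_cancer: ParameterValue

    def validate(self) -> None:
        for name, value in _walk_table(self, "costs"):
            value.validate(name)
            if value.mean < 0:
                raise SpecValidationError(f"{name}: cost {value.mean} must be >= 0")


@dataclass
class TimelineConstants:
    """Cycle structure, discounting and cohort-size constants."""

    cycle_length_months: int = 1
    horizon_cycles: int = 60
    annual_discount_rate: float = 0.03
    postop_recovery_cycles: int = 2
    adjuvant_chemo_cycles: int = 4
    adjuvant_chemo_start_offset_cycles: int = 2  # months; 1/2/3 = 4/8/12 weeks
    lar_ostomy_cycles: int = 6
    wtp_threshold: float = 100_000.0
    cohort_size: int = 10_000
    psa_outer_iterations: int = 100
    baseline_age_years: float = 63.0
    # All strategies carry perfect adherence to one 4-cycle adjuvant block;
    # set False to restrict adjuvant chemotherapy to the surgical pathway.
    ww_adjuvant_chemo: bool = True

    def validate(self) -> None:
        if self.cycle_length_months != 1:
            raise SpecValidationError("timeline: cycle length must be 1 month")
        if self.horizon_cycles != 60:
            raise SpecValidationError("timeline: horizon must be 60 cycles")
        for f in ("postop_recovery_cycles", "adjuvant_chemo_cycles",
                  "adjuvant_chemo_start_offset_cycles", "lar_ostomy_cycles"):
            v = getattr(self, f)
            if not (isinstance(v, int) and 0 < v <= self.horizon_cycles):
                raise SpecValidationError(
                    f"timeline.{f}: must be a positive integer <= horizon, got {v}"
                )
        if not 0.0 <= self.annual_discount_rate < 1.0:
            raise SpecValidationError("timeline: discount rate outside [0, 1)")
        if self.wtp_threshold < 0 or self.cohort_size < 1:
            raise SpecValidationError("timeline: bad wtp threshold or cohort size")


@dataclass
class LifeTable:
    """Annual background-mortality probabilities by attained age (sex-averaged).

    Stored as (age, annual probability) anchors; lookups interpolate linearly
    between anchors, so an abridged table suffices.
    """

    ages: np.ndarray
    annual_q: np.ndarray

    def validate(self) -> None:
        if len(self.ages) != len(self.annual_q) or len(self.ages) < 2:
            raise SpecValidationError("life table: need >= 2 (age, q) rows")
        if not np.all(np.diff(self.ages) > 0):
            raise SpecValidationError("life table: ages must be strictly increasing")
        if np.any(self.annual_q < 0) or np.any(self.annual_q > 1):
            raise SpecValidationError("life table: probabilities outside [0, 1]")
        if np.any(np.diff(self.annual_q) < 0):
            raise SpecValidationError(
                "life table: annual probabilities must be non-decreasing over "
                "adult ages"
            )

    def annual_probability(self, age_years: float) -> float:
        if age_years < self.ages[0] or age_years > self.ages[-1]:
            raise SpecValidationError(
                f"life table: age {age_years} outside table range "
                f"[{self.ages[0]}, {self.ages[-1]}]"
            )
        return float(np.interp(age_years, self.ages, self.annual_q))

    @classmethod
    def from_csv(cls, path: Path | str) -> "LifeTable":
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("age"):
                continue
            age_s, q_s = line.split(",")[:2]
            rows.append((float(age_s), float(q_s)))
        lt = cls(
            ages=np.array([r[0] for r in rows]),
            annual_q=np.array([r[1] for r in rows]),
        )
        lt.validate()
        return lt


def default_surveillance_calendar(comparison: str) -> dict[str, dict[int, list[str]]]:
    """Default surveillance schedules, as cost-item names per cycle per arm.

    Cycles are counted from entry into the relevant stable phase (for WW,
    cohort start; for the surgical pathway, the operation). WW surveillance
    follows an intensive nonoperative-management program: office visit, digital
    rectal exam, flexible sigmoidoscopy and CEA every 3 months in years 1-2
    then every 6 months; pelvic MRI every 6 months in years 1-2 then annually;
    annual CT chest/abdomen-pelvis; colonoscopy at 1 year. Post-resection
    surveillance follows guideline-based follow-up: office visit + CEA on the
    same cadence, annual CTs, colonoscopy at 1 year (through the stoma after
    APR).
    """
    ww: dict[int, list[str]] = {}
    surg: dict[int, list[str]] = {}
    exam_cycles = [c for c in range(3, 25, 3)] + [c for c in range(30, 61, 6)]
    for c in exam_cycles:
        ww.setdefault(c, []).extend(
            ["office_visit", "rectal_exam", "flex_sig", "cea"]
        )
        surg.setdefault(c, []).extend(["office_visit", "cea"])
    for c in (12, 24, 36, 48, 60):
        ww.setdefault(c, []).extend(["ct_abd_pelvis", "ct_chest"])
        surg.setdefault(c, []).extend(["ct_abd_pelvis", "ct_chest"])
    for c in (6, 12, 18, 24, 36, 48, 60):
        ww.setdefault(c, []).append("mri_pelvis")
    ww.setdefault(12, []).append("colonoscopy")
    scope = "colonoscopy_stoma" if comparison == "WW_vs_APR" else "colonoscopy"
    surg.setdefault(12, []).append(scope)
    return {ARM_WW: ww, ARM_SURGERY: surg}


@dataclass
class ModelSpec:
    """Complete parameterization of one WW-versus-surgery comparison."""

    comparison: str
    transitions: TransitionTable
    utilities: UtilityTable
    costs: CostTable
    timeline: TimelineConstants
    life_table: LifeTable
    surveillance: dict[str, dict[int, list[str]]]
    # When set, replaces the life-table lookup with a constant monthly
    # probability (used by the natural-mortality sensitivity sweep).
    natural_mortality_monthly: float | None = None

    @property
    def surgery_name(self) -> str:
        return "APR" if self.comparison == "WW_vs_APR" else "LAR"

    @property
    def surgery_cost(self) -> ParameterValue:
        return (self.costs.surgery_apr if self.surgery_name == "APR"
                else self.costs.surgery_lar)

    def validate(self) -> "ModelSpec":
        if self.comparison not in COMPARISONS:
            raise SpecValidationError(
                f"comparison must be one of {COMPARISONS}, got {self.comparison!r}"
            )
        self.transitions.validate()
        self.utilities.validate()
        self.costs.validate()
        self.timeline.validate()
        self.life_table.validate()
        cost_fields = {f.name for f in dataclasses.fields(CostTable)}
        for arm, cal in self.surveillance.items():
            if arm not in (ARM_WW, ARM_SURGERY):
                raise SpecValidationError(f"surveillance: unknown arm {arm!r}")
            for cycle, items in cal.items():
                if not 1 <= int(cycle) <= self.timeline.horizon_cycles:
                    raise SpecValidationError(
                        f"surveillance[{arm}]: cycle {cycle} outside horizon"
                    )
                for item in items:
                    if item not in cost_fields:
                        raise SpecValidationError(
                            f"surveillance[{arm}][{cycle}]: unknown cost item "
                            f"{item!r}"
                        )
        if self.natural_mortality_monthly is not None:
            if not 0.0 <= self.natural_mortality_monthly <= 1.0:
                raise SpecValidationError(
                    "natural_mortality_monthly outside [0, 1]"
                )
        return self

    def copy(self) -> "ModelSpec":
        return copy.deepcopy(self)


def _walk_table(table: Any, prefix: str) -> Iterator[tuple[str, ParameterValue]]:
    for f in dataclasses.fields(table):
        value = getattr(table, f.name)
        if isinstance(value, ParameterValue):
            yield f"{prefix}.{f.name}", value
        elif isinstance(value, dict):
            for arm, pv in value.items():
                yield f"{prefix}.{f.name}.{arm}", pv


def iter_parameters(spec: ModelSpec) -> Iterator[tuple[str, ParameterValue]]:
    """Yield every (dotted path, ParameterValue) in a stable, sorted order."""
    pairs: list[tuple[str, ParameterValue]] = []
    pairs.extend(_walk_table(spec.transitions, "transitions"))
    pairs.extend(_walk_table(spec.utilities, "utilities"))
    pairs.extend(_walk_table(spec.costs, "costs"))
    return iter(sorted(pairs, key=lambda kv: kv[0]))


def get_parameter(spec: ModelSpec, path: str) -> ParameterValue:
    obj: Any = spec
    for part in path.split("."):
        obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
    if not isinstance(obj, ParameterValue):
        raise KeyError(f"{path} does not address a parameter")
    return obj


def set_parameter(spec: ModelSpec, path: str, *, mean: float | None = None,
                  sd: float | None = None) -> ModelSpec:
    """Return a copy of ``spec`` with one parameter's mean and/or sd replaced."""
    new = spec.copy()
    parts = path.split(".")
    obj: Any = new
    for part in parts[:-1]:
        obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
    leaf = parts[-1]
    old = obj[leaf] if isinstance(obj, dict) else getattr(obj, leaf)
    if not isinstance(old, ParameterValue):
        raise KeyError(f"{path} does not address a parameter")
    pv = ParameterValue(
        mean=old.mean if mean is None else float(mean),
        sd=old.sd if sd is None else float(sd),
        family=old.family,
        source_label=old.source_label,
    )
    if isinstance(obj, dict):
        obj[leaf] = pv
    else:
        setattr(obj, leaf, pv)
    return new


# ---------------------------------------------------------------------------
# Loading / serialization
# ---------------------------------------------------------------------------

def _load_table(cls, node: Any, prefix: str, default_family: str):
    if not isinstance(node, dict):
        raise SpecValidationError(f"{prefix}: expected a mapping")
    kwargs = {}
    known = {f.name for f in dataclasses.fields(cls)}
    for key in node:
        if key not in known:
            raise SpecValidationError(f"{prefix}.{key}: unknown parameter name")
    for f in dataclasses.fields(cls):
        if f.name not in node:
            if f.name == "death":  # optional, defaults to fixed 0
                continue
            raise SpecValidationError(f"{prefix}.{f.name}: missing required row")
        sub = node[f.name]
        if cls is TransitionTable and f.name in TransitionTable.ARM_FIELDS:
            if not isinstance(sub, dict) or set(sub) != set(TRANS_ARMS):
                raise SpecValidationError(
                    f"{prefix}.{f.name}: expected per-arm values keyed "
                    f"{set(TRANS_ARMS)}"
                )
            kwargs[f.name] = {
                arm: _pv(sub[arm], f"{prefix}.{f.name}.{arm}", default_family)
                for arm in TRANS_ARMS
            }
        else:
            kwargs[f.name] = _pv(sub, f"{prefix}.{f.name}", default_family)
    return cls(**kwargs)


def load_spec(config: dict | str | Path) -> ModelSpec:
    """Load and fully validate a ModelSpec from a YAML document or mapping.

    Any parameter given without an ``sd`` receives SD = 20% of its mean.
    """
    base_dir: Path | None = None
    if isinstance(config, (str, Path)):
        base_dir = Path(config).parent
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise SpecValidationError("config document must be a mapping")
    for key in ("comparison", "transitions", "utilities", "costs"):
        if key not in config:
            raise SpecValidationError(f"config: missing section {key!r}")

    timeline_node = config.get("timeline", {})
    known_tl = {f.name for f in dataclasses.fields(TimelineConstants)}
    bad = set(timeline_node) - known_tl
    if bad:
        raise SpecValidationError(f"timeline: unknown keys {sorted(bad)}")
    timeline = TimelineConstants(**timeline_node)

    lt_node = config.get("life_table", "life_table_2015_ssa.csv")
    if isinstance(lt_node, dict):
        life_table = LifeTable(
            ages=np.asarray(lt_node["ages"], dtype=float),
            annual_q=np.asarray(lt_node["annual_death_probability"], dtype=float),
        )
    else:
        p = Path(lt_node)
        if not p.is_absolute() and base_dir is not None and (base_dir / p).exists():
            p = base_dir / p
        elif not p.exists():
            p = _fixture_path(str(lt_node))
        life_table = LifeTable.from_csv(p)

    comparison = str(config["comparison"])
    surveillance = config.get("surveillance")
    if surveillance is None:
        surveillance = default_surveillance_calendar(comparison)
    else:
        surveillance = {
            arm: {int(c): list(items) for c, items in cal.items()}
            for arm, cal in surveillance.items()
        }

    spec = ModelSpec(
        comparison=comparison,
        transitions=_load_table(TransitionTable, config["transitions"],
                                "transitions", "beta"),
        utilities=_load_table(UtilityTable, config["utilities"],
                              "utilities", "beta"),
        costs=_load_table(CostTable, config["costs"], "costs", "gamma"),
        timeline=timeline,
        life_table=life_table,
        surveillance=surveillance,
        natural_mortality_monthly=config.get("natural_mortality_monthly"),
    )
    return spec.validate()


def serialize(spec: ModelSpec) -> dict:
    """Serialize a spec to a plain mapping that ``load_spec`` round-trips."""
    def table_dict(table: Any) -> dict:
        out: dict[str, Any] = {}
        for f in dataclasses.fields(table):
            value = getattr(table, f.name)
            if isinstance(value, ParameterValue):
                out[f.name] = _pv_dict(value)
            else:
                out[f.name] = {arm: _pv_dict(pv) for arm, pv in value.items()}
        return out

    out = {
        "comparison": spec.comparison,
        "transitions": table_dict(spec.transitions),
        "utilities": table_dict(spec.utilities),
        "costs": table_dict(spec.costs),
        "timeline": dataclasses.asdict(spec.timeline),
        "life_table": {
            "ages": [float(a) for a in spec.life_table.ages],
            "annual_death_probability": [float(q) for q in spec.life_table.annual_q],
        },
        "surveillance": {
            arm: {int(c): list(items) for c, items in cal.items()}
            for arm, cal in spec.surveillance.items()
        },
    }
    if spec.natural_mortality_monthly is not None:
        out["natural_mortality_monthly"] = spec.natural_mortality_monthly
    return out


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("wwcea").joinpath("fixtures", name)))


def base_case_spec(comparison: str) -> ModelSpec:
    """Return the packaged base-case parameter set for one comparison."""
    if comparison not in COMPARISONS:
        raise SpecValidationError(
            f"unknown comparison {comparison!r}; expected one of {COMPARISONS}"
        )
    name = "ww_vs_apr.yaml" if comparison == "WW_vs_APR" else "ww_vs_lar.yaml"
    return load_spec(_fixture_path(name))


def dsa_ranges(spec: ModelSpec) -> dict[str, tuple[float, float]]:
    """One-way sensitivity sweep ranges for every parameter.

    Probability and utility rows ship with the published per-row ranges
    (upper bounds of 1 are capped at 0.99 because the per-cycle conversion
    requires a cumulative probability < 1); cost rows are swept over
    5%-195% of the base value.
    """
    doc = yaml.safe_load(_fixture_path("dsa_ranges.yaml").read_text())
    out: dict[str, tuple[float, float]] = {}
    for path, rng in doc.items():
        lo, hi = float(rng[0]), float(rng[1])
        out[path] = (lo, min(hi, 0.99))
    for path, pv in iter_parameters(spec):
        if path.startswith("costs."):
            out[path] = (0.05 * pv.mean, 1.95 * pv.mean)
    return out
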