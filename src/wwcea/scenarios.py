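"""Named test scenarios and randomized parameter sets.

Scenarios make every stage of the pipeline testable without external data:
degenerate parameter sets with closed-form expectations (zero event risks,
certain perioperative death, zero costs, utilities at the ceiling), the
adjuvant-chemotherapy timing variants (start at 4, 8 or 12 weeks), and
uniformly randomized — but always valid — parameter sets for property
sweeps. Recipes ship as a structured-text fixture next to the base cases.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .parameters import (COMPARISONS, ModelSpec, ParameterValue,
                         _fixture_path, base_case_spec, iter_parameters,
                         set_parameter)


@dataclass
class ScenarioRecipe:
    """A named modification of a base-case parameter set."""

    name: str
    comparison: str = "WW_vs_APR"
    overrides: dict[str, float] = field(default_factory=dict)
    set_all: dict[str, float] = field(default_factory=dict)  # section -> value
    expected: str = ""
    description: str = ""

    def build(self) -> ModelSpec:
        spec = base_case_spec(self.comparison)
        for section, value in self.set_all.items():
            for path, pv in iter_parameters(spec):
                if path.startswith(section + ".") and pv.family != "fixed":
                    spec = set_parameter(spec, path, mean=value, sd=0.0)
        for path, value in self.overrides.items():
            if path == "natural_mortality_monthly":
                spec.natural_mortality_monthly = float(value)
            elif path.startswith("timeline."):
                setattr(spec.timeline, path.split(".", 1)[1], value)
            else:
                spec = set_parameter(spec, path, mean=float(value), sd=0.0)
        return spec.validate()


def load_recipes() -> dict[str, ScenarioRecipe]:
    doc = yaml.safe_load(_fixture_path("scenarios.yaml").read_text())
    fields = {f.name for f in dataclasses.fields(ScenarioRecipe)}
    return {
        name: ScenarioRecipe(name=name,
                             **{k: v for k, v in node.items() if k in fields})
        for name, node in doc.items()
    }


def degenerate_scenarios() -> list[ScenarioRecipe]:
    """The analytically tractable scenarios (closed-form oracles)."""
    recipes = load_recipes()
    return [recipes[n] for n in
            ("zero_risk", "certain_perioperative_death",
             "certain_regrowth_certain_salvage", "zero_costs",
             "perfect_health_no_mortality")]


def adjuvant_timing_scenarios(comparison: str = "WW_vs_APR") -> list[ScenarioRecipe]:
    """Adjuvant chemotherapy starting 4, 8 and 12 weeks after surgery."""
    out = []
    for weeks, offset in ((4, 1), (8, 2), (12, 3)):
        out.append(ScenarioRecipe(
            name=f"adjuvant_start_{weeks}w",
            comparison=comparison,
            overrides={"timeline.adjuvant_chemo_start_offset_cycles": offset},
            description=f"adjuvant chemotherapy starts {weeks} weeks "
                        f"post-intervention",
        ))
    return out


def random_valid_spec(seed: int, comparison: str = "WW_vs_APR") -> ModelSpec:
    """A uniformly randomized parameter set that always passes validation.

    Probabilities are drawn uniform on [0, 0.99], utilities uniform on
    [0, 1], costs uniform on [0, 2x base]; standard deviations are set to
    20% of the drawn mean. Timeline and life table stay at base case.
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    rng = np.random.default_rng(seed)
    spec = base_case_spec(comparison)
    for path, pv in sorted(iter_parameters(spec), key=lambda kv: kv[0]):
        if pv.family == "fixed":
            continue
        if path.startswith("transitions."):
            mean = float(rng.uniform(0.0, 0.99))
        elif path.startswith("utilities."):
            mean = float(rng.uniform(0.0, 1.0))
        else:
            mean = float(rng.uniform(0.0, 2.0 * pv.mean))
        spec = set_parameter(spec, path, mean=mean, sd=0.2 * mean)
    return spec.validate()
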