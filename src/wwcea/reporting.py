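"""Report generation: cohort-outcome, cost-effectiveness, sensitivity and
PSA tables as CSV, each accompanied by a reproducibility manifest.

CSV column/row names mirror the published result tables so reports diff
cleanly against them. Every run writes a ``manifest.json`` capturing the
command, inputs, seeds and any warnings emitted (β-variance clips and the
like), sufficient to reproduce the run bit-identically.
"""

from __future__ import annotations

import json
import logging
import platform
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__, cea, sensitivity
from .engine import simulate_cohort
from .parameters import (ARM_SURGERY, ARM_WW, ModelSpec, base_case_spec,
                         dsa_ranges, get_parameter)

logger = logging.getLogger("wwcea")


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.records: list[str] = []

    def emit(self, record):
        self.records.append(self.format(record))


def _capture_warnings():
    handler = _WarningCollector()
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    return handler


def _write_manifest(outdir: Path, command: str, args: dict,
                    warnings: list[str]) -> Path:
    manifest = {
        "command": command,
        "arguments": args,
        "software": {"package": "wwcea", "version": __version__,
                     "python": platform.python_version()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "warnings": warnings,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def run_base_case(comparison: str, n: int | None = None,
                  seed: int = 0, outdir: str | Path = ".",
                  spec: ModelSpec | None = None) -> dict:
    """Run both arms of one comparison; write outcome and CEA tables.

    Emits ``outcomes.csv`` (5-year recurrence and mortality proportions, in
    percent), ``cea.csv`` (per-arm discounted cost and QALYs, incrementals,
    ICER or dominance) and ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _capture_warnings()
    try:
        if spec is None:
            spec = base_case_spec(comparison)
        if n is None:
            n = spec.timeline.cohort_size
        surgery = spec.surgery_name
        res_ww = simulate_cohort(spec, ARM_WW, n, [seed, 0])
        res_s = simulate_cohort(spec, ARM_SURGERY, n, [seed, 1])
        comparison_res = cea.compare(res_s, res_ww, spec.timeline.wtp_threshold)

        pct = lambda x: round(100.0 * x, 2)
        outcomes = pd.DataFrame(
            {
                surgery: {
                    "Local regrowth (during the WW period)": float("nan"),
                    "Local recurrence (following first operation)":
                        pct(res_s.local_recurrence_post_op),
                    "Distant only": pct(res_s.distant_recurrence_any),
                    "Local and distant": pct(res_s.local_and_distant),
                    "Overall mortality": pct(res_s.overall_5y_mortality),
                    "Cancer-specific mortality":
                        pct(res_s.cancer_specific_5y_mortality),
                },
                "WW": {
                    "Local regrowth (during the WW period)":
                        pct(res_ww.regrowth_during_ww),
                    "Local recurrence (following first operation)":
                        pct(res_ww.local_recurrence_post_op),
                    "Distant only": pct(res_ww.distant_recurrence_any),
                    "Local and distant": pct(res_ww.local_and_distant),
                    "Overall mortality": pct(res_ww.overall_5y_mortality),
                    "Cancer-specific mortality":
                        pct(res_ww.cancer_specific_5y_mortality),
                },
            }
        )
        outcomes.index.name = "Outcome (%)"
        outcomes.to_csv(outdir / "outcomes.csv")

        cea_table = pd.DataFrame(
            {
                surgery: {
                    "Cost": round(res_s.mean_cost, 2),
                    "Effectiveness (QALY)": round(res_s.mean_qalys, 4),
                    "Incremental cost (vs. WW)":
                        round(comparison_res.incremental_cost, 2),
                    "Incremental effectiveness (vs. WW)":
                        round(comparison_res.incremental_effect, 4),
                    "ICER ($/QALY)": comparison_res.icer_label,
                },
                "WW": {
                    "Cost": round(res_ww.mean_cost, 2),
                    "Effectiveness (QALY)": round(res_ww.mean_qalys, 4),
                    "Incremental cost (vs. WW)": "",
                    "Incremental effectiveness (vs. WW)": "",
                    "ICER ($/QALY)": "",
                },
            }
        )
        cea_table.index.name = "Measure"
        cea_table.to_csv(outdir / "cea.csv")
    finally:
        logger.removeHandler(handler)
    _write_manifest(outdir, "base-case",
                    {"comparison": comparison, "n": n, "seed": seed},
                    handler.records)
    return {"ww": res_ww, "surgery": res_s, "cea": comparison_res,
            "outdir": outdir}


_BAND_LABELS = {
    sensitivity.WW_DOMINATES: "WW dominates",
    sensitivity.SURGERY_NOT_CE: "not cost effective",
    sensitivity.SURGERY_CE: "cost effective",
}


def run_dsa(comparison: str, outdir: str | Path = ".",
            parameters: list[str] | None = None, n_grid: int = 9,
            spec: ModelSpec | None = None) -> pd.DataFrame:
    """One-way sensitivity analysis over every (or selected) parameter.

    Writes ``dsa.csv`` with one row per swept parameter: base value, range,
    and the classification bands of surgery relative to WW.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _capture_warnings()
    try:
        if spec is None:
            spec = base_case_spec(comparison)
        ranges = dsa_ranges(spec)
        if parameters is not None:
            ranges = {p: ranges[p] for p in parameters}
        rows = []
        for path, (lo, hi) in ranges.items():
            if path == "natural_mortality_monthly":
                base = "life table"
            else:
                base = get_parameter(spec, path).mean
            result = sensitivity.one_way(spec, path, lo, hi, n_grid=n_grid)
            bands = "; ".join(
                f"{b_lo:.6g}-{b_hi:.6g}: {_BAND_LABELS[lab]}"
                for b_lo, b_hi, lab in result.bands
            )
            rows.append({
                "parameter": path,
                "base_value": base,
                "lower": lo,
                "upper": hi,
                "bands": bands,
                "summary": ("Remains dominated" if result.remains_dominated
                            else "threshold at "
                            + ", ".join(f"{x:.4g}" for x in result.thresholds)),
            })
        table = pd.DataFrame(rows)
        table.to_csv(outdir / "dsa.csv", index=False)
    finally:
        logger.removeHandler(handler)
    _write_manifest(outdir, "dsa",
                    {"comparison": comparison, "n_grid": n_grid,
                     "parameters": parameters},
                    handler.records)
    return table


def run_psa(comparison: str, n_outer: int | None = None,
            n_inner: int | None = None, seed: int = 0,
            wtp_max: float = 250_000.0, outdir: str | Path = ".",
            spec: ModelSpec | None = None) -> dict:
    """Probabilistic sensitivity analysis; writes the per-draw table and the
    cost-effectiveness acceptability curve (CEAC)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _capture_warnings()
    try:
        if spec is None:
            spec = base_case_spec(comparison)
        if n_outer is None:
            n_outer = spec.timeline.psa_outer_iterations
        if n_inner is None:
            n_inner = spec.timeline.cohort_size
        draws = sensitivity.psa(spec, n_outer, n_inner, seed)
        grid = cea.default_wtp_grid(wtp_max)
        curve = cea.acceptability_curve(draws, grid)
        eval_grid = grid[grid <= 200_000.0]
        draw_table = pd.DataFrame([
            {
                "iteration": d.iteration,
                "cost_ww": round(d.cost_ww, 2),
                "qaly_ww": round(d.qaly_ww, 4),
                f"cost_{spec.surgery_name.lower()}": round(d.cost_surgery, 2),
                f"qaly_{spec.surgery_name.lower()}": round(d.qaly_surgery, 4),
                "ww_optimal_all_wtp": bool(
                    sensitivity.ww_optimal_fraction([d], eval_grid) == 1.0
                ),
            }
            for d in draws
        ])
        draw_table.to_csv(outdir / "psa_draws.csv", index=False)
        ceac = pd.DataFrame({"wtp": grid, "ww_optimal_fraction": curve})
        ceac.to_csv(outdir / "ceac.csv", index=False)
        fraction = sensitivity.ww_optimal_fraction(draws, eval_grid)
    finally:
        logger.removeHandler(handler)
    _write_manifest(outdir, "psa",
                    {"comparison": comparison, "n_outer": n_outer,
                     "n_inner": n_inner, "seed": seed, "wtp_max": wtp_max},
                    handler.records)
    return {"draws": draws, "ceac": ceac, "ww_optimal_fraction": fraction,
            "outdir": outdir}
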