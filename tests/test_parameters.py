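"""Parameter loading, validation, fixture audit and round-tripping."""

import dataclasses

import pytest
import yaml

from wwcea import (SpecValidationError, base_case_spec, get_parameter,
                   iter_parameters, load_spec, serialize, set_parameter)
from wwcea.parameters import LifeTable, _fixture_path

# Every base-case parameter mean, keyed by dotted path, as printed in the
# published tables (shared between the two comparisons).
EXPECTED_MEANS = {
    "transitions.perioperative_death": 0.035,
    "transitions.local_recurrence_2y.WW": 0.19,
    "transitions.local_recurrence_2y.TME": 0.016,
    "transitions.local_recurrence_5y.WW": 0.24,
    "transitions.local_recurrence_5y.TME": 0.010,
    "transitions.salvage_given_local.WW": 0.94,
    "transitions.salvage_given_local.TME": 0.59,
    "transitions.distant_recurrence_5y.WW": 0.10,
    "transitions.distant_recurrence_5y.TME": 0.079,
    "transitions.concurrent_distant_given_local": 0.056,
    "transitions.concurrent_local_given_distant": 0.17,
    "transitions.distant_after_local_3y": 0.11,
    "transitions.mortality_local_salvaged_5y": 0.50,
    "transitions.mortality_local_unsalvaged_5y": 0.70,
    "transitions.mortality_distant_5y": 0.80,
    "transitions.mortality_local_and_distant_5y": 0.80,
    "utilities.initial_ww": 0.80,
    "utilities.initial_postop": 0.110,
    "utilities.salvage_tme_disutility_state": 0.69,
    "utilities.longterm_apr": 0.75,
    "utilities.longterm_lar_with_ostomy": 0.70,
    "utilities.longterm_lar_without_ostomy": 0.78,
    "utilities.local_recurrence": 0.67,
    "utilities.distant_recurrence": 0.70,
    "utilities.local_and_distant": 0.48,
    "utilities.death": 0.0,
    "costs.surgery_lar": 34662.98,
    "costs.surgery_apr": 22015.72,
    "costs.adjuvant_chemo_per_cycle": 1890.00,
    "costs.ostomy_takedown": 906.02,
    "costs.ostomy_care_monthly": 93.25,
    "costs.office_visit": 25.95,
    "costs.rectal_exam": 9.01,
    "costs.flex_sig": 58.74,
    "costs.cea": 23.41,
    "costs.colonoscopy": 194.97,
    "costs.colonoscopy_stoma": 164.34,
    "costs.ct_abd_pelvis": 323.99,
    "costs.ct_chest": 161.09,
    "costs.mri_pelvis": 405.08,
    "costs.restaging_local": 2100.00,
    "costs.restaging_distant": 1200.00,
    "costs.reirradiation_course": 19800.00,
    "costs.palliative_capecitabine_per_cycle": 510.00,
    "costs.palliative_mfolfox6_per_cycle": 850.00,
    "costs.death_perioperative": 11295.38,
    "costs.death_cancer": 11295.38,
    "costs.death_non_cancer": 11295.38,
}

EXPECTED_SDS = {
    "transitions.perioperative_death": 0.007,
    "transitions.salvage_given_local.WW": 0.19,
    "utilities.longterm_apr": 0.15,
    "costs.surgery_lar": 6932.60,
    "costs.death_cancer": 2259.08,
}


@pytest.mark.parametrize("comparison", ["WW_vs_APR", "WW_vs_LAR"])
def test_base_case_fixture_audit(comparison):
    """Every packaged parameter matches its published table cell exactly."""
    spec = base_case_spec(comparison)
    seen = dict(iter_parameters(spec))
    assert set(seen) == set(EXPECTED_MEANS)
    for path, expected in EXPECTED_MEANS.items():
        assert seen[path].mean == pytest.approx(expected, abs=1e-12), path
    for path, expected in EXPECTED_SDS.items():
        assert seen[path].sd == pytest.approx(expected, abs=1e-12), path
    assert spec.surgery_name == ("APR" if comparison == "WW_vs_APR" else "LAR")
    assert spec.utilities.death.family == "fixed"


def test_unknown_comparison_rejected():
    with pytest.raises(SpecValidationError, match="comparison"):
        base_case_spec("WW_vs_TAMIS")


def test_missing_sd_filled_as_20_percent_of_mean(apr_spec):
    doc = serialize(apr_spec)
    del doc["transitions"]["perioperative_death"]["sd"]
    spec = load_spec(doc)
    assert spec.transitions.perioperative_death.sd == pytest.approx(0.007)


def test_probability_out_of_range_rejected(apr_spec):
    doc = serialize(apr_spec)
    doc["transitions"]["local_recurrence_2y"]["WW"]["mean"] = 1.5
    with pytest.raises(SpecValidationError, match="local_recurrence_2y"):
        load_spec(doc)


def test_schema_violations_name_the_offending_field(apr_spec):
    doc = serialize(apr_spec)
    del doc["costs"]["cea"]
    with pytest.raises(SpecValidationError, match="costs.cea"):
        load_spec(doc)
    doc = serialize(apr_spec)
    doc["transitions"]["not_a_row"] = {"mean": 0.5}
    with pytest.raises(SpecValidationError, match="not_a_row"):
        load_spec(doc)
    doc = serialize(apr_spec)
    doc["surveillance"]["WW"][3] = ["not_a_cost_item"]
    with pytest.raises(SpecValidationError, match="not_a_cost_item"):
        load_spec(doc)


@pytest.mark.parametrize("comparison", ["WW_vs_APR", "WW_vs_LAR"])
def test_serialize_round_trip(comparison):
    spec = base_case_spec(comparison)
    again = load_spec(serialize(spec))
    assert serialize(again) == serialize(spec)
    assert yaml.safe_load(yaml.safe_dump(serialize(spec))) == serialize(spec)


def test_set_parameter_returns_modified_copy(apr_spec):
    new = set_parameter(apr_spec, "transitions.local_recurrence_2y.WW",
                        mean=0.5)
    assert get_parameter(new, "transitions.local_recurrence_2y.WW").mean == 0.5
    assert get_parameter(apr_spec,
                         "transitions.local_recurrence_2y.WW").mean == 0.19


def test_life_table_lookup_and_validation():
    lt = LifeTable.from_csv(_fixture_path("life_table_2015_ssa.csv"))
    # interpolated value between the age-60 and age-65 anchors
    assert lt.annual_probability(63.0) == pytest.approx(0.01141, abs=1e-6)
    with pytest.raises(SpecValidationError, match="outside table range"):
        lt.annual_probability(150.0)
    bad = LifeTable(ages=lt.ages, annual_q=lt.annual_q[::-1].copy())
    with pytest.raises(SpecValidationError, match="non-decreasing"):
        bad.validate()


def test_timeline_constraints_enforced(apr_spec):
    doc = serialize(apr_spec)
    doc["timeline"]["horizon_cycles"] = 120
    with pytest.raises(SpecValidationError, match="horizon"):
        load_spec(doc)
    doc = serialize(apr_spec)
    doc["timeline"]["lar_ostomy_cycles"] = 0
    with pytest.raises(SpecValidationError, match="lar_ostomy_cycles"):
        load_spec(doc)


def test_surveillance_calendar_differs_by_operation(apr_spec, lar_spec):
    apr_items = {i for items in apr_spec.surveillance["SURGERY"].values()
                 for i in items}
    lar_items = {i for items in lar_spec.surveillance["SURGERY"].values()
                 for i in items}
    assert "colonoscopy_stoma" in apr_items and "colonoscopy" in lar_items
    ww_items = {i for items in apr_spec.surveillance["WW"].values()
                for i in items}
    assert {"flex_sig", "rectal_exam", "mri_pelvis"} <= ww_items
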