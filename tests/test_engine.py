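"""Microsimulation engine and its deterministic expected-value oracle."""

import numpy as np
import pytest

from wwcea import (ARM_SURGERY, ARM_WW, cohort_expected_value, set_parameter,
                   simulate_cohort, simulate_patient)
from wwcea.engine import _simulate_kernel
from wwcea.scenarios import load_recipes, random_valid_spec

ANNUITY = sum(1.03 ** (-(t - 0.5) / 12) / 12 for t in range(1, 61))

# allowed directed transitions between aggregate states
ALLOWED = {
    ("STABLE_WW", "STABLE_POST_SURGERY"), ("STABLE_WW", "LOCAL_UNSALVAGED"),
    ("STABLE_WW", "DISTANT"), ("STABLE_WW", "LOCAL_AND_DISTANT"),
    ("STABLE_WW", "DEAD"),
    ("STABLE_POST_SURGERY", "LOCAL_SALVAGED"),
    ("STABLE_POST_SURGERY", "LOCAL_UNSALVAGED"),
    ("STABLE_POST_SURGERY", "DISTANT"),
    ("STABLE_POST_SURGERY", "LOCAL_AND_DISTANT"),
    ("STABLE_POST_SURGERY", "DEAD"),
    ("LOCAL_SALVAGED", "LOCAL_AND_DISTANT"), ("LOCAL_SALVAGED", "DEAD"),
    ("LOCAL_UNSALVAGED", "LOCAL_AND_DISTANT"), ("LOCAL_UNSALVAGED", "DEAD"),
    ("DISTANT", "DEAD"), ("LOCAL_AND_DISTANT", "DEAD"),
}


@pytest.fixture(scope="module")
def zero_risk_spec():
    return load_recipes()["zero_risk"].build()


def test_zero_risk_closed_form_annuity(zero_risk_spec):
    """With every risk at zero a WW patient stays stable for 60 cycles and
    the discounted QALYs equal the closed-form annuity at utility 0.80."""
    expected = 0.80 * ANNUITY
    cost, qaly, occ = cohort_expected_value(zero_risk_spec, ARM_WW)
    assert qaly == pytest.approx(expected, abs=1e-9)
    res = simulate_cohort(zero_risk_spec, ARM_WW, 20, 5)
    assert res.mean_qalys == pytest.approx(expected, abs=1e-9)
    assert res.overall_5y_mortality == 0.0
    assert res.regrowth_during_ww == 0.0
    assert res.distant_recurrence_any == 0.0


def test_forced_perioperative_death(zero_risk_spec):
    """Certain perioperative death: zero QALYs, surgery plus death cost."""
    spec = set_parameter(zero_risk_spec, "transitions.perioperative_death",
                         mean=1.0)
    res = simulate_cohort(spec, ARM_SURGERY, 10, 3)
    assert res.mean_qalys == 0.0
    expected_cost = (spec.costs.surgery_apr.mean
                     + spec.costs.death_perioperative.mean)
    assert res.mean_cost == pytest.approx(expected_cost, abs=1e-9)
    assert res.overall_5y_mortality == 1.0
    assert res.perioperative_mortality == 1.0
    assert res.cancer_specific_5y_mortality == 0.0
    traj = simulate_patient(spec, ARM_SURGERY, 3, 0)
    assert traj.death_cause == "perioperative"
    assert traj.discounted_qalys == 0.0


def test_forced_regrowth_with_certain_salvage():
    """Near-certain WW regrowth with certain salvage routes patients through
    salvage surgery into the post-surgery stable state."""
    spec = load_recipes()["certain_regrowth_certain_salvage"].build()
    res = simulate_cohort(spec, ARM_WW, 400, 9)
    assert res.regrowth_during_ww > 0.9
    assert res.overall_5y_mortality == 0.0  # salvage periop risk is zero here
    traj = simulate_patient(spec, ARM_WW, 9, 0)
    assert traj.regrowth_during_ww and traj.salvage_received
    transitions = [e for _, _, ev in traj.steps for e in ev]
    assert "STABLE_WW->STABLE_POST_SURGERY" in transitions
    # salvage surgery cost appears in the accruals
    assert traj.discounted_cost > spec.costs.surgery_apr.mean * 0.8


def test_occupancy_conservation(apr_spec, lar_spec):
    for spec in (apr_spec, lar_spec):
        for arm in (ARM_WW, ARM_SURGERY):
            _, _, occ = cohort_expected_value(spec, arm)
            assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-12)
            # death is absorbing
            assert np.all(np.diff(occ[:, -1]) >= -1e-12)


@pytest.mark.parametrize("arm", [ARM_WW, ARM_SURGERY])
def test_microsim_agrees_with_oracle_within_4_se(base_runs, arm):
    for comparison, runs in base_runs.items():
        cost, qaly, _ = cohort_expected_value(runs["spec"], arm)
        res = runs[arm]
        assert abs(res.mean_cost - cost) < 4 * res.se_cost, comparison
        assert abs(res.mean_qalys - qaly) < 4 * res.se_qalys, comparison


def test_monte_carlo_error_shrinks_with_n(apr_spec):
    """The microsimulation mean stays within 4 standard errors of the oracle
    across three cohort sizes."""
    cost_o, qaly_o, _ = cohort_expected_value(apr_spec, ARM_WW)
    for n in (100, 1000, 10_000):
        res = simulate_cohort(apr_spec, ARM_WW, n, 17)
        assert abs(res.mean_qalys - qaly_o) < 4 * res.se_qalys, n
        assert abs(res.mean_cost - cost_o) < 4 * res.se_cost, n


def test_raising_mortality_never_raises_oracle_qalys(apr_spec):
    base = cohort_expected_value(apr_spec, ARM_WW)[1]
    for path in ("transitions.mortality_distant_5y",
                 "transitions.mortality_local_unsalvaged_5y",
                 "transitions.perioperative_death"):
        worse = set_parameter(apr_spec, path, mean=0.95)
        assert cohort_expected_value(worse, ARM_WW)[1] <= base + 1e-12, path


def test_discounting_and_qaly_bounds_on_random_specs():
    for seed in range(5):
        spec = random_valid_spec(seed)
        for arm in (ARM_WW, ARM_SURGERY):
            res = simulate_cohort(spec, arm, 200, seed)
            assert 0.0 <= res.mean_qalys <= 5.0
            assert res.mean_cost >= 0.0
            assert res.cancer_specific_5y_mortality <= res.overall_5y_mortality
            _, qaly, occ = cohort_expected_value(spec, arm)
            assert 0.0 <= qaly <= 5.0
            assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-10)


def test_seed_reproducibility_is_exact(apr_spec):
    a = simulate_cohort(apr_spec, ARM_WW, 500, 42)
    b = simulate_cohort(apr_spec, ARM_WW, 500, 42)
    assert a == b
    c = simulate_cohort(apr_spec, ARM_WW, 500, 43)
    assert c != a


def test_single_patient_matches_cohort_of_one(apr_spec):
    traj = simulate_patient(apr_spec, ARM_WW, 42, 0)
    res = simulate_cohort(apr_spec, ARM_WW, 1, 42)
    assert traj.discounted_cost == res.mean_cost
    assert traj.discounted_qalys == res.mean_qalys


def test_patient_outcomes_independent_of_cohort_size(apr_spec):
    """Counter-based substreams: patient i is identical in any cohort."""
    small = _simulate_kernel(apr_spec, ARM_WW, 3, 7)
    large = _simulate_kernel(apr_spec, ARM_WW, 50, 7)
    assert np.array_equal(small["cost"], large["cost"][:3])
    assert np.array_equal(small["qaly"], large["qaly"][:3])
    assert np.array_equal(small["state"], large["state"][:3])


@pytest.mark.parametrize("arm", [ARM_WW, ARM_SURGERY])
def test_trajectories_follow_the_transition_diagram(apr_spec, arm):
    """No forbidden transitions; death is absorbing; flags match the path."""
    for i in range(60):
        traj = simulate_patient(apr_spec, arm, 13, i)
        states = [s for _, s, _ in traj.steps]
        prev = states[0] if arm == ARM_WW else states[0]
        seen_dead = False
        for s0, s1 in zip(states[:-1], states[1:]):
            if s0 == s1:
                continue
            assert (s0, s1) in ALLOWED, (s0, s1)
            assert not seen_dead
            seen_dead = s1 == "DEAD"
        assert 0.0 <= traj.discounted_qalys <= 5.0
        assert traj.discounted_cost >= 0.0
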