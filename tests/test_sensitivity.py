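"""Moment fits, one-way sweeps with bisection, and PSA machinery."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wwcea import (ARM_SURGERY, ARM_WW, beta_params_from_moments,
                   cohort_expected_value, gamma_params_from_moments,
                   get_parameter, iter_parameters, one_way, psa,
                   set_parameter, ww_optimal_fraction)
from wwcea.sensitivity import (SURGERY_CE, WW_DOMINATES, classify_point,
                               clip_beta_sd, sample_parameter, sample_spec)


def test_beta_uniform_identity():
    a, b = beta_params_from_moments(0.5, np.sqrt(1 / 12))
    assert a == pytest.approx(1.0) and b == pytest.approx(1.0)


def test_beta_variance_bound_rejected_with_guidance():
    with pytest.raises(ValueError, match="[Cc]lip"):
        beta_params_from_moments(0.5, 0.5)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(mean=st.floats(0.01, 0.99), frac=st.floats(0.05, 0.95))
def test_beta_moment_recovery(mean, frac):
    sd = frac * np.sqrt(mean * (1 - mean))
    a, b = beta_params_from_moments(mean, sd)
    assert a / (a + b) == pytest.approx(mean, abs=1e-9)
    var = a * b / ((a + b) ** 2 * (a + b + 1))
    assert np.sqrt(var) == pytest.approx(sd, abs=1e-9)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(mean=st.floats(1e-3, 1e6), frac=st.floats(0.01, 3.0))
def test_gamma_moment_recovery(mean, frac):
    sd = frac * mean
    shape, scale = gamma_params_from_moments(mean, sd)
    assert shape * scale == pytest.approx(mean, rel=1e-9)
    assert np.sqrt(shape) * scale == pytest.approx(sd, rel=1e-9)


def test_gamma_published_surgery_cost_row():
    shape, scale = gamma_params_from_moments(34_662.98, 6_932.60)
    assert shape == pytest.approx(25.0, rel=1e-5)
    assert scale == pytest.approx(1_386.5192, rel=1e-5)
    with pytest.raises(ValueError):
        gamma_params_from_moments(0.0, 1.0)


def test_clip_rule_logs_and_clips(caplog):
    with caplog.at_level(logging.WARNING, logger="wwcea"):
        clipped = clip_beta_sd(0.94, 0.30)
    bound = np.sqrt(0.94 * 0.06)
    assert clipped == pytest.approx(0.95 * bound)
    assert any("clip" in r.message for r in caplog.records)
    assert clip_beta_sd(0.94, 0.19) == 0.19  # within bound, untouched


def test_sampled_parameter_means_recover_within_4_se(apr_spec):
    rng = np.random.default_rng(12)
    for path in ("transitions.local_recurrence_2y.WW",
                 "utilities.longterm_apr", "costs.surgery_apr"):
        pv = get_parameter(apr_spec, path)
        xs = np.array([sample_parameter(pv, rng) for _ in range(1000)])
        se = pv.sd / np.sqrt(len(xs))
        assert abs(xs.mean() - pv.mean) < 4 * se, path


def test_sample_spec_degenerate_sds_equal_base(apr_spec):
    frozen = apr_spec
    for path, pv in iter_parameters(apr_spec):
        frozen = set_parameter(frozen, path, sd=0.0)
    sampled = sample_spec(frozen, np.random.default_rng(0))
    for path, pv in iter_parameters(frozen):
        assert get_parameter(sampled, path).mean == pv.mean, path


def test_one_way_degenerate_single_point(apr_spec):
    res = one_way(apr_spec, "transitions.perioperative_death", 0.035, 0.035)
    assert res.bands == [(0.035, 0.035, WW_DOMINATES)]
    assert res.thresholds == []


def test_sweep_through_base_value_reproduces_base_classification(apr_spec):
    base_label = classify_point(apr_spec, apr_spec.timeline.wtp_threshold)
    assert base_label == WW_DOMINATES
    res = one_way(apr_spec, "transitions.perioperative_death", 0.001, 0.9,
                  n_grid=5)
    for lo, hi, lab in res.bands:
        if lo <= 0.035 <= hi:
            assert lab == base_label


def test_bisected_threshold_agrees_with_fine_grid(apr_spec):
    """The bisected cost-effectiveness boundary matches a brute-force scan."""
    path = "transitions.local_recurrence_2y.WW"
    res = one_way(apr_spec, path, 0.7, 0.95, n_grid=6)
    threshold = res.threshold_for(SURGERY_CE)
    assert threshold is not None
    grid = np.arange(0.7, 0.95, 0.005)
    labels = [classify_point(set_parameter(apr_spec, path, mean=x),
                             apr_spec.timeline.wtp_threshold) for x in grid]
    first_ce = grid[next(i for i, l in enumerate(labels) if l == SURGERY_CE)]
    assert abs(threshold - first_ce) <= 0.005 + 1e-3
    # bands partition the swept range
    assert res.bands[0][0] == 0.7 and res.bands[-1][1] == 0.95
    for (l0, h0, _), (l1, h1, _) in zip(res.bands[:-1], res.bands[1:]):
        assert h0 == l1


def test_natural_mortality_sweep_addressable(apr_spec):
    res = one_way(apr_spec, "natural_mortality_monthly", 0.001, 0.5, n_grid=5)
    assert res.bands[0][2] == WW_DOMINATES


def _oracle_psa_evaluator(spec, arm, n, seed):
    cost, qaly, _ = cohort_expected_value(spec, arm)
    return cost, qaly


def test_psa_reproducible_and_ww_optimal(apr_spec):
    draws = psa(apr_spec, 10, 1, 2024, evaluator=_oracle_psa_evaluator)
    again = psa(apr_spec, 10, 1, 2024, evaluator=_oracle_psa_evaluator)
    assert [(d.cost_ww, d.qaly_ww) for d in draws] == \
        [(d.cost_ww, d.qaly_ww) for d in again]
    frac = ww_optimal_fraction(draws)
    assert 0.0 <= frac <= 1.0
    with pytest.raises(ValueError):
        psa(apr_spec, 0, 1, 1)


def test_psa_with_microsim_inner_loop(apr_spec):
    draws = psa(apr_spec, 2, 300, 5)
    assert len(draws) == 2
    for d in draws:
        assert d.cost_ww >= 0 and 0 <= d.qaly_ww <= 5
        assert d.cost_surgery >= 0 and 0 <= d.qaly_surgery <= 5
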