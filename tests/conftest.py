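import pytest

from wwcea import ARM_SURGERY, ARM_WW, base_case_spec, simulate_cohort

BASE_N = 10_000
BASE_SEED = 101


@pytest.fixture(scope="session")
def apr_spec():
    return base_case_spec("WW_vs_APR")


@pytest.fixture(scope="session")
def lar_spec():
    return base_case_spec("WW_vs_LAR")


@pytest.fixture(scope="session")
def base_runs(apr_spec, lar_spec):
    """Full-size base-case cohorts for both comparisons, shared across tests."""
    runs = {}
    for name, spec in (("WW_vs_APR", apr_spec), ("WW_vs_LAR", lar_spec)):
        runs[name] = {
            "spec": spec,
            ARM_WW: simulate_cohort(spec, ARM_WW, BASE_N, [BASE_SEED, 0]),
            ARM_SURGERY: simulate_cohort(spec, ARM_SURGERY, BASE_N,
                                         [BASE_SEED, 1]),
        }
    return runs
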