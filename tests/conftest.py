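import pytest

import t2dcea as t


@pytest.fixture(scope="session")
def base_params():
    return t.load_parameters()


@pytest.fixture(scope="session")
def base_results(base_params):
    return {key: t.run_cohort(key, base_params) for key in (t.SU, t.DPP4I)}


@pytest.fixture(scope="session")
def base_cea(base_results):
    return t.compute_cea(base_results[t.SU], base_results[t.DPP4I], discounted=True)


@pytest.fixture(scope="session")
def base_cea_undiscounted(base_results):
    return t.compute_cea(base_results[t.SU], base_results[t.DPP4I], discounted=False)


@pytest.fixture(scope="session")
def sweep_entries(base_params):
    return {e.label: e for e in t.run_full_sweep(base_params)}


@pytest.fixture(scope="session")
def psa_result(base_params):
    return t.run_psa(base_params, n_draws=1000, seed=1234)
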