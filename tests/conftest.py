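import pytest

from anemia_cea import default_bundle, load_default_life_table, run_base_case


@pytest.fixture(scope="session")
def bundle():
    return default_bundle()


@pytest.fixture(scope="session")
def life_table():
    return load_default_life_table()


@pytest.fixture(scope="session")
def base_result(bundle, life_table):
    """Base-case pipeline run at 3% discounting, shared across tests."""
    return run_base_case(bundle, life_table)


@pytest.fixture(scope="session")
def undiscounted_result(bundle, life_table):
    return run_base_case(bundle.replace_param("discount_rate", 0.0), life_table)
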