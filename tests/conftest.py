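import pytest

from ablacost import default_life_table, default_params


@pytest.fixture(scope="session")
def base_params():
    return default_params()


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()
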