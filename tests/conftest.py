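import pytest

from fidcea import calibrate_base, default_config
from fidcea.config import build_life_table


@pytest.fixture(scope="session")
def base_config():
    """Demo configuration with an assumed 22G marker price."""
    return default_config(marker_unit_cost_22g=55.0)


@pytest.fixture(scope="session")
def life_table(base_config):
    return build_life_table(base_config)


@pytest.fixture(scope="session")
def calibrated_config(base_config, life_table):
    """Base configuration with excess mortality and 80+ utility anchored."""
    return calibrate_base(base_config, life_table)
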