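import copy

import pytest
import yaml
from hypothesis import HealthCheck, settings

from ceatree import load_packaged_config
from ceatree.params_io import packaged_config_path

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_config():
    """The packaged two-arm rimegepant-vs-placebo configuration."""
    return load_packaged_config()


@pytest.fixture(scope="session")
def _raw_config_data():
    with packaged_config_path().open() as fh:
        return yaml.safe_load(fh)


@pytest.fixture()
def raw_config(_raw_config_data):
    """A mutable copy of the packaged configuration mapping."""
    return copy.deepcopy(_raw_config_data)
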