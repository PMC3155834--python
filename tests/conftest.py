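import pytest
from hypothesis import HealthCheck, settings

from overgomap import build_design, datasets

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def probes():
    return datasets.make_probe_table()


@pytest.fixture(scope="session")
def chroms():
    return datasets.load_chicken_chromosomes()


@pytest.fixture(scope="session")
def design216(probes):
    return build_design(216, 6, 6, 6, list(probes["probe_id"]))
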