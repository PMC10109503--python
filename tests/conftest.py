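import numpy as np
import pytest

from windup_asic.asic import ASICParams
from windup_asic.cleft import CleftParams
from windup_asic.engine import ScenarioConfig, run_windup


@pytest.fixture(scope="session")
def homomeric():
    return ASICParams.homomeric_native()


@pytest.fixture(scope="session")
def heteromeric():
    return ASICParams.heteromeric_native()


@pytest.fixture(scope="session")
def cleft_params():
    return CleftParams()


class _SimCache:
    """Lazily run and cache windup simulations shared across tests."""

    def __init__(self):
        self._cache = {}

    def run(self, key=None, **config_kwargs):
        key = key or tuple(sorted(config_kwargs.items()))
        if key not in self._cache:
            self._cache[key] = run_windup(ScenarioConfig(**config_kwargs))
        return self._cache[key]

    def windup(self, key=None, **config_kwargs):
        return self.run(key, **config_kwargs).windup()


@pytest.fixture(scope="session")
def sims():
    return _SimCache()
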