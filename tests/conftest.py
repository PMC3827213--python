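import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from shspkit.architecture import load_reference

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference():
    """Packaged synthetic reference fixture (profile + feature map)."""
    return load_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(20131112)


def random_protein(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))
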