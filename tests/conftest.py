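import pytest

from circphot import calibrated_params, lens_transmittance


@pytest.fixture(scope="session")
def bundled_lens():
    return lens_transmittance()


@pytest.fixture(scope="session")
def unity_lens():
    return lens_transmittance(source="unity")


@pytest.fixture(scope="session")
def params():
    """Default calibrated circuit parameters (deterministic, memoized)."""
    return calibrated_params()
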