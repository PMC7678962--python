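import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_population():
    from notchcode import sample_population

    return sample_population(24, seed=3)


@pytest.fixture(scope="session")
def quiet_population():
    """Low-noise population for parameter-recovery checks."""
    from notchcode import sample_population

    return sample_population(
        30, seed=5, jitter_sd_ms=0.5, spont_rate_hz=0.5
    )


@pytest.fixture(scope="session")
def small_fm_dataset(small_population):
    from notchcode import build_fm_protocol, simulate_dataset

    return simulate_dataset(
        small_population, build_fm_protocol(seed=8), seed=9
    )


@pytest.fixture(scope="session")
def quiet_tone_dataset(quiet_population):
    from notchcode import build_tone_protocol, simulate_dataset

    return simulate_dataset(
        quiet_population, build_tone_protocol(seed=6), seed=7
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
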