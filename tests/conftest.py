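import numpy as np
import pytest

from winbci.core_io import RunConfig
from winbci.pipeline import subject_power_series
from winbci.synthetic import SynthConfig, generate_subject


@pytest.fixture(scope="session")
def run_cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def small_synth_cfg():
    """A short cohort configuration (3 trials) for fast end-to-end tests."""
    from winbci.core_io import ProtocolSpec

    return SynthConfig(
        n_subjects=2,
        protocol=ProtocolSpec(n_trials=3),
        seed=42,
    )


@pytest.fixture(scope="session")
def subject(small_synth_cfg):
    """One generated subject (recording + ground truth), 150 s."""
    return generate_subject(small_synth_cfg, 0)


@pytest.fixture(scope="session")
def subject_ps(subject, run_cfg):
    """The same subject run through preprocessing + alpha power."""
    rec, _ = subject
    return subject_power_series(rec, run_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
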