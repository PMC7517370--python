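import numpy as np
import pytest

from ehgphase import Signal, generate_cohort, generate_ehg, p_config, tt_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_signal(rng):
    """A short white-Gaussian signal, enough for SODP/PhEn unit tests."""
    return Signal(rng.standard_normal(500), fs=20.0, subject_id="G1")


@pytest.fixture(scope="session")
def short_tt_p_pair():
    """A fast 60-second synthetic pair for pipeline-level tests."""
    tt = generate_ehg(tt_config(duration_s=60.0, n_contractions=1, seed=11))
    p = generate_ehg(p_config(duration_s=60.0, n_contractions=1, seed=12))
    return (
        tt.replace(subject_id="S01", stage="TT"),
        p.replace(subject_id="S01", stage="P"),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Six paired subjects at full 10-minute length (session-cached)."""
    return generate_cohort(6, seed=202)
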