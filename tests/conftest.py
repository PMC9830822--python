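import numpy as np
import pytest

from milknue.pipeline import prepare_trial
from milknue.simulate import generate_trial, t1_like_config, t2_like_config


@pytest.fixture(scope="session")
def t1_dataset():
    """QC-passed T1-like calibration trial (~600 records, seed 0)."""
    ds, _ = prepare_trial(generate_trial(t1_like_config(0)))
    return ds


@pytest.fixture(scope="session")
def t2_dataset():
    """QC-passed T2-like external trial (~104 records, 3 diet groups, seed 1)."""
    ds, _ = prepare_trial(generate_trial(t2_like_config(1)))
    return ds


@pytest.fixture(scope="session")
def small_t1():
    """Small T1-like trial for fast model fits (12 cows x 6 days)."""
    ds, _ = prepare_trial(generate_trial(t1_like_config(7, n_cows=12, n_days_per_cow=6)))
    return ds


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
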