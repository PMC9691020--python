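import numpy as np
import pytest

from srxfret import SimConfig
from srxfret.synthetic import turnover_measurement


@pytest.fixture
def noiseless_cfg() -> SimConfig:
    return SimConfig(seed=42, noise_sd=0.0)


@pytest.fixture
def wt20() -> "srxfret.SRXMeasurement":  # noqa: F821
    """Reference WT single-turnover parameters at 20 mM KCl."""
    return turnover_measurement("WT", 20)


@pytest.fixture
def e525k150():
    """Reference E525K single-turnover parameters at 150 mM KCl."""
    return turnover_measurement("E525K", 150)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
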