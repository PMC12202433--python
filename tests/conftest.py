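import warnings

import numpy as np
import pandas as pd
import pytest

from bifactorlab import (
    anxiety_population,
    anxiety_spec,
    simulate_latents_and_indicators,
    wm_population,
    wm_spec,
)

warnings.filterwarnings("ignore", message="An ill-conditioned matrix")


@pytest.fixture(scope="session")
def wm_pop():
    return wm_population()


@pytest.fixture(scope="session")
def anx_pop():
    return anxiety_population()


@pytest.fixture(scope="session")
def wm_sample(wm_pop):
    """One simulated WM indicator sample of the study's size."""
    ds = simulate_latents_and_indicators(wm_pop, 340, seed=20260924)
    return ds.indicators[list(wm_spec().indicators)]


@pytest.fixture(scope="session")
def anx_sample(anx_pop):
    ds = simulate_latents_and_indicators(anx_pop, 340, seed=20260924)
    return ds.indicators[list(anxiety_spec().indicators)]


@pytest.fixture(scope="session")
def big_wm_sample(wm_pop):
    """Large sample for moment-convergence checks."""
    ds = simulate_latents_and_indicators(wm_pop, 100_000, seed=7)
    return ds
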