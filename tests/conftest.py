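import numpy as np
import pytest

from tibiaqct.pipeline import PipelineConfig, run_pipeline
from tibiaqct.synthetic_ct import scaled_spec


@pytest.fixture(scope="session")
def full_result():
    """One full default cohort run (48 bones, 128x128, seed 1), shared by
    every test that needs study-scale output."""
    return run_pipeline(PipelineConfig(seed=1))


@pytest.fixture(scope="session")
def small_result():
    """A reduced cohort run (4 bones, 64x64) for cheap structural checks."""
    return run_pipeline(PipelineConfig(cohort=scaled_spec(4), seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture()
def noiseless_spec():
    """Single small bone with no noise and no blur: the exact-arithmetic regime."""
    return scaled_spec(1, hu_noise_sd=0.0, blur_sigma_px=0.0)
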