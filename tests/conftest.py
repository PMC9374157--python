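import warnings

import numpy as np
import pytest

from thetalink import SimConfig, AnalysisConfig

# chatty-but-expected warnings (small-sample notices, statsmodels internals)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_sim():
    """Small, fast simulation: full epoch, reduced rate/trials/subjects."""
    return SimConfig(n_subjects=4, n_trials_per_task=24, srate=128.0, seed=7)


@pytest.fixture
def tiny_analysis():
    return AnalysisConfig(n_permutations=200, mediation_B=60, rng_seed=7)
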