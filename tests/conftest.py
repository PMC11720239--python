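import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from nbprog.synthetic import SynthConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Default synthetic cohort (n = 88, mirrors the study's shape)."""
    return generate(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def recovery_cohort():
    """Larger cohort used for selection-quality checks."""
    return generate(SynthConfig(n_samples=200, seed=3))
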