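import numpy as np
import pytest

from crushkit.config import EffectConfig, StudyConfig
from crushkit.synthetic_cohort import generate_cohort


@pytest.fixture(scope="session")
def default_study() -> StudyConfig:
    return StudyConfig(seed=1)


@pytest.fixture(scope="session")
def cohort_seed1(default_study):
    """Full default cohort (36 animals, iohexol included), generated once."""
    return generate_cohort(default_study, EffectConfig())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
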