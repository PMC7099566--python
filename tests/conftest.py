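import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from dotcad import PhantomConfig, build_dataset, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def default_config() -> PhantomConfig:
    return PhantomConfig()


@pytest.fixture(scope="session")
def benign_volume(default_config):
    return generate_phantom("benign", default_config, seed=101, patient_id="B001")


@pytest.fixture(scope="session")
def malignant_volume(default_config):
    return generate_phantom("malignant", default_config, seed=202, patient_id="M001")


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """8 benign + 6 malignant volumes: enough for split/training smoke tests."""
    return generate_cohort(8, 6, default_config, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return build_dataset(small_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
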