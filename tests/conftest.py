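import numpy as np
import pytest

from sichml.cohort import LatentTruth, Side, generate_cohort
from sichml.phantom import GridSpec


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(shape=(32, 32, 20), upper_start=6, lower_stop=8)


@pytest.fixture(scope="session")
def featureless_truth() -> LatentTruth:
    return LatentTruth(ischemia_present=False, ischemia_fraction_mca=0.0,
                       hyperdense_mca=False, fazekas=0, background_burden=0.0,
                       lesion_side=Side.LEFT, sich_probability=0.0)


@pytest.fixture(scope="session")
def loaded_truth() -> LatentTruth:
    """A subject carrying every radiological feature."""
    return LatentTruth(ischemia_present=True, ischemia_fraction_mca=0.4,
                       hyperdense_mca=True, fazekas=2, background_burden=1.2,
                       lesion_side=Side.RIGHT, sich_probability=0.3)


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 SICH + 20 controls, enough to exercise split plans and scores."""
    return generate_cohort(3, 20, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """The study-sized 16 + 100 cohort at the default parameters."""
    return generate_cohort(16, 100, seed=1)
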