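import numpy as np
import pytest

from lesioncam import synthdata


@pytest.fixture(scope="session")
def small_cohort():
    """50 patients, 32 px frames, balanced enough that every class appears."""
    return synthdata.generate_cohort(
        n_patients=50, class_mix=(0.5, 0.25, 0.25),
        images_per_patient=(2, 4), image_side=32, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
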