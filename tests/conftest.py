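import numpy as np
import pytest

import nirsim as ns

#: seed pinned for the study-shaped fixtures
STUDY_SEED = 20240601
STUDY_CLASS_SIZES = (4, 3, 6, 5, 10, 3, 8, 4, 4, 4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_axis():
    """21-point descending axis, long enough for the default SG window."""
    return ns.make_axis(1000.0, 800.0, 10.0)


@pytest.fixture
def tiny_dataset(small_axis):
    """Small labeled dataset (3 classes x 2 samples) for fast grid runs."""
    profiles = ns.generate_profiles(3, small_axis, separation="high", seed=7)
    noise = ns.NoiseModel(seed=7)
    return ns.generate_dataset(profiles, [2, 2, 2], noise, small_axis)


@pytest.fixture(scope="session")
def study_dataset():
    """Full study-shaped synthetic dataset: 51 samples in 10 classes on the
    751-point 10,000->4,000 cm^-1 axis, high class separation."""
    axis = ns.make_axis()
    profiles = ns.generate_profiles(
        10, axis, separation="high", seed=STUDY_SEED
    )
    return ns.generate_dataset(
        profiles, STUDY_CLASS_SIZES, ns.NoiseModel(seed=STUDY_SEED), axis
    )


@pytest.fixture(scope="session")
def study_grid(study_dataset):
    """The full 32 x 11 grid evaluated on the study-shaped dataset."""
    return ns.run_grid(study_dataset)


@pytest.fixture(scope="session")
def study_materials():
    """Seeded material fixtures: two similar and two dissimilar pairs."""
    axis = ns.make_axis()
    return ns.generate_materials(2, 2, axis, seed=STUDY_SEED)
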