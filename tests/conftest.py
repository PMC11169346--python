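import numpy as np
import pytest

from morphsev.synthetic import (
    SyntheticCohortConfig,
    generate_cohort,
    generate_tissue_template,
)


@pytest.fixture(scope="session")
def template_24():
    return generate_tissue_template((24, 28, 24))


@pytest.fixture(scope="session")
def template_16():
    return generate_tissue_template((16, 16, 16))


@pytest.fixture(scope="session")
def small_cohort():
    """60 subjects on a 12^3 grid; shared by several expensive tests."""
    cfg = SyntheticCohortConfig(
        n_subjects=60,
        grid_shape=(12, 12, 12),
        lesion_volume_range=(8, 40),
        atrophy_voxels=12,
        seed=7,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
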