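import numpy as np
import pytest

from turstage.phantom import default_params, sample_cohort


@pytest.fixture(scope="session")
def tiny_noiseless_cohort():
    """Six 32x32 noiseless phantom patients (3 IA, 3 IB), shared read-only."""
    return sample_cohort(3, 3, default_params(image_size=32, noise_sd=0.0), seed=5)


@pytest.fixture(scope="session")
def tiny_sagittal_pairs(tiny_noiseless_cohort):
    return [(c.slices["sagittal_t2w"].image.pixels, c.slices["sagittal_t2w"].mask)
            for c in tiny_noiseless_cohort]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
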