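import numpy as np
import pytest

from csrseg import phantom
from csrseg.grids import LabelVolume, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noisefree_case():
    """One deterministic noise-free phantom with a lesion in each size bin."""
    cfg = phantom.PhantomConfig(
        lesion_specs=(
            phantom.LesionSpec(8.0, 0.3, "benign"),
            phantom.LesionSpec(20.0, 0.3, "malignant"),
            phantom.LesionSpec(40.0, 0.3, "malignant"),
        ),
        noise_sigma=0.0,
        seed=7,
    )
    return cfg, phantom.generate_case(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten deterministic phantoms with sampled lesions across bins."""
    return phantom.generate_cohort(phantom.PhantomConfig(), 10, seed=5)


def make_volume(values, spacing=(1.0, 1.0, 1.0)):
    return VolumeGrid(np.asarray(values, dtype=np.float32), spacing)


def make_labels(values, spacing=(1.0, 1.0, 1.0)):
    return LabelVolume(np.asarray(values, dtype=np.int16), spacing)
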