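import numpy as np
import pytest

from respvit import synthetic as sy
from respvit import pipeline as pl


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Six cycles over three patients, mixed labels, for plumbing tests."""
    cfg = sy.SimulationConfig(
        n_patients=3, cycles_per_patient=2, class_probs=(0.4, 0.2, 0.2, 0.2), seed=7
    )
    return sy.gen_dataset(cfg)


@pytest.fixture(scope="session")
def wheeze_study():
    """The desk-scale wheeze-vs-normal study: 25 patients x 8 cycles at 10 dB SNR,
    rendered to 64x64 cochleogram images.  Shared across the expensive tests."""
    cfg = sy.SimulationConfig(
        n_patients=25,
        cycles_per_patient=8,
        class_probs=(0.5, 0.0, 0.5, 0.0),
        snr_db=10.0,
        seed=11,
    )
    cycles, manifest = sy.gen_dataset(cfg)
    images, labels4, patients = pl.featurize_cycles(cycles, "cochleogram", image_size=64)
    y = pl.binary_labels(labels4, "wheeze_binary")
    return images, y, patients
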