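import numpy as np
import pytest

from sparsesynergies import SynthSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small, well-separated double-sparse dataset (3 classes x 12 trials)."""
    spec = SynthSpec(
        n_classes=3, trials_per_class=12, s=6, length=10, r_true=5,
        joints_per_atom=2, n_shared_atoms=2, n_selective_atoms_per_class=1,
        sigma_gen=0.01, seed=42,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def default_dataset():
    """The full-size benchmark layout: 9 classes x 50 trials, s=10, len=20."""
    return generate_dataset(SynthSpec(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
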