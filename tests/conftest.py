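import numpy as np
import pytest

from semgrec.preprocessing import FilterSpec
from semgrec.segmentation import WindowSpec, build_dataset, split_dataset
from semgrec.simulate import CLASSES, GeneratorSpec, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """Low-noise, high-contrast generator for fast deterministic fixtures."""
    return GeneratorSpec(seed=7, noise_sd=0.02, powerline_amp=0.05, ecg_amp=0.05)


@pytest.fixture(scope="session")
def small_recordings(small_spec):
    return generate_dataset(small_spec, {c: 3 for c in CLASSES})


@pytest.fixture(scope="session")
def small_dataset(small_recordings):
    """12 cycles -> 28 windows, split 80/20."""
    ds = build_dataset(small_recordings, WindowSpec())
    return split_dataset(ds, 0.25, seed=0)


@pytest.fixture(scope="session")
def filter_spec():
    return FilterSpec()
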