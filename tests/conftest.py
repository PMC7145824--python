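import numpy as np
import pytest

from ecgdx.synthetic import SyntheticRecordSpec, generate_dataset, synthesize_record


@pytest.fixture(scope="session")
def clean_sinus_record():
    """Noise-free normal-sinus record at 400 Hz with its ground truth."""
    spec = SyntheticRecordSpec(labels={}, duration=10.0, fs=400.0, seed=42,
                               noise_sd=0.0, baseline_amp=0.0)
    return synthesize_record(spec)


@pytest.fixture(scope="session")
def small_dataset():
    """60 records with balanced class prevalences (deterministic)."""
    return generate_dataset(60, prevalences=(0.2,) * 6, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
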