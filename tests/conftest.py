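import numpy as np
import pytest

from cogfuse.synthetic import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_binary_dataset():
    """Small strong-signal binary corpus for fast model/training tests."""
    return generate_dataset(
        SynthConfig(n_sentences=60, sentence_length_range=(3, 7), seed=7,
                    bands=("theta", "alpha"))
    )


@pytest.fixture(scope="session")
def tiny_relation_dataset():
    return generate_dataset(
        SynthConfig(n_sentences=60, sentence_length_range=(3, 7), seed=11,
                    task="relation_detection", bands=("theta",))
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
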