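import numpy as np
import pytest

from popmgram.encoding import encode_dataset
from popmgram.properties import STANDARD_RESIDUES, default_property_table
from popmgram.synthetic import generate_dataset, make_spec


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(STANDARD_RESIDUES), size=length))


@pytest.fixture(scope="session")
def table():
    return default_property_table()


@pytest.fixture(scope="session")
def small_dataset():
    """Three well-separated classes, small enough for per-test RFE runs."""
    spec = make_spec(
        {"A": 12, "B": 12, "C": 12},
        class_axes={"A": "aromatic", "B": "aliphatic", "C": "charged"},
        length_range=(30, 80),
        informative_strength=0.9,
        seed=5,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    features = encode_dataset(small_dataset.sequences())
    labels = np.asarray(small_dataset.label_array())
    return features, labels
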