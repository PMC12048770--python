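import numpy as np
import pytest

from vegdet.synthetic import generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Two-class, 12-image synthetic VOC dataset shared across tests."""
    root = tmp_path_factory.mktemp("voc")
    records = generate_dataset(
        {"tomato early blight": 8, "cucumber downy mildew": 4},
        root,
        spec_defaults={"canvas_size": (96, 96), "n_leaves": 2, "stage": "late"},
        seed=7,
    )
    return records
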