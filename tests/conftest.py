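import numpy as np
import pytest

from latatk import fixtures as fx


@pytest.fixture(scope="session")
def small_spec():
    """32-px dataset spec used across unit tests (cheap but non-trivial)."""
    return fx.SyntheticSpec(image_size=32, lesion_radius_range=(5, 9), seed=7)


@pytest.fixture(scope="session")
def small_data(small_spec):
    """(images NHWC, masks, labels) for 32 samples of the small spec."""
    return fx.dataset_arrays(small_spec, 32)


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, small_spec):
    """A written-on-disk dataset (PNGs + manifest) with 8 samples."""
    d = tmp_path_factory.mktemp("dataset")
    fx.generate_dataset(small_spec, 8, d)
    return d


@pytest.fixture(scope="session")
def quick_classifier(small_data):
    """Arch-A classifier briefly trained on the small dataset; used where a
    trained (not necessarily accurate) model is enough."""
    model = fx.build_tiny_classifier("A", 2, seed=0)
    model, _ = fx.train_classifier(model, small_data, epochs=3, seed=0)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
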