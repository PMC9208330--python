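import numpy as np
import pytest

from chrysid.synthetic import SyntheticDatasetConfig, VariationParams, generate_dataset
from chrysid.vocab import LabelVocabulary


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Six cultivars x 10 images at 48 px: shared by pipeline-level tests."""
    out = tmp_path_factory.mktemp("smallds")
    cfg = SyntheticDatasetConfig(n_cultivars=6, images_per_cultivar=10,
                                 image_size=48, seed=7, year_tag="2018",
                                 variation=VariationParams.low())
    manifest = generate_dataset(cfg, out)
    return manifest


@pytest.fixture(scope="session")
def full_vocab():
    return LabelVocabulary()


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
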