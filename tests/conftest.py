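import numpy as np
import pytest

from uigo import prep
from uigo.phantom_forge import PhantomSpec, forge_dataset, load_manifest


@pytest.fixture(scope="session")
def phantom_dir(tmp_path_factory):
    """A 60-sample phantom dataset shared by dataset-level tests."""
    root = tmp_path_factory.mktemp("phantoms")
    forge_dataset(PhantomSpec(seed=42), 60, root)
    return root


@pytest.fixture(scope="session")
def phantom_manifest(phantom_dir):
    manifest = load_manifest(phantom_dir)
    return prep.assign_splits(manifest, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
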