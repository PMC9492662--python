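import numpy as np
import pytest

from cervalign.phantom import PhantomSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small on-disk phantom dataset (10 patients, 64 px) shared by tests."""
    out = tmp_path_factory.mktemp("phantom_ds")
    spec = PhantomSpec(image_size=64, seed=42)
    manifest = generate_dataset(10, spec, out)
    return {"dir": out, "manifest": manifest, "manifest_path": out / "manifest.csv",
            "spec": spec}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
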