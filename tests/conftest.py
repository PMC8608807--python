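import numpy as np
import pytest

from colstore.dataset import Dataset


@pytest.fixture
def store(tmp_path):
    """A writable scratch dataset, closed on teardown."""
    ds = Dataset(tmp_path / "store.h5", "write")
    yield ds
    ds.close()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_store(tmp_path, name="extra.h5"):
    return Dataset(tmp_path / name, "write")
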