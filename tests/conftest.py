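import numpy as np
import pytest

from hippopix import pipeline
from hippopix.imageprep import GreyImage


@pytest.fixture
def rng():
    return np.random.default_rng(20210520)


@pytest.fixture
def random_grey(rng):
    """A seeded 120x100 enhanced-stage grey image."""
    return GreyImage(rng.uniform(0, 255, size=(100, 120)), stage="enhanced")


@pytest.fixture(scope="session")
def benchmark_bundle(tmp_path_factory):
    """One end-to-end run of the 25-image synthetic benchmark, shared by tests."""
    out = tmp_path_factory.mktemp("benchmark")
    bundle = pipeline.run_all(pipeline.benchmark_config(seed=11), out)
    return bundle, out
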