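import numpy as np
import pytest

from ribfrac import PhantomConfig, generate_phantom, preprocess_pipeline


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """One 96^3 easy-setting phantom scan with its ground-truth mask."""
    cfg = PhantomConfig.easy()
    return generate_phantom(cfg, seed=3, scan_id="fixture")


@pytest.fixture(scope="session")
def preprocessed_phantom(small_phantom):
    ct, gt = small_phantom
    normalized, bone = preprocess_pipeline(ct)
    return normalized, bone, gt
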