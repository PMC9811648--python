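import warnings

import numpy as np
import pytest

from vocaldistress.synthetic import make_fixture

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_table():
    """Small study-shaped feature table with the default planted effects."""
    table, truth = make_fixture("tiny_features", seed=1)
    return table, truth


@pytest.fixture(scope="session")
def null_table():
    """Same shape, no planted effects and no distress-mode link."""
    table, truth = make_fixture("null_features", seed=1)
    return table, truth


@pytest.fixture(scope="session")
def tiny_audio(tmp_path_factory):
    """Six synthetic calls (<= 25 s total) written as WAV + labels + metadata."""
    out = tmp_path_factory.mktemp("audio")
    recordings, annotations, meta = make_fixture("tiny_audio", seed=0, out_dir=out)
    return out, recordings, annotations, meta
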