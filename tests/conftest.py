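import numpy as np
import pytest

import ciuq
from ciuq.config import default_config


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def mean_shape(cfg):
    return ciuq.build_cochlea(ciuq.ShapeWeights(0, 0, 0), cfg.geometry)


@pytest.fixture(scope="session")
def mean_fibers(mean_shape, cfg):
    return ciuq.place_fibers(mean_shape, cfg=cfg.geometry)


@pytest.fixture(scope="session")
def mean_ctx(cfg):
    """Mean-shape patient at the default insertion and resistivity."""
    return ciuq.make_context(ciuq.ShapeWeights(0, 0, 0), 27.0, 65.0, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
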