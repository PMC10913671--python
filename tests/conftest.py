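import numpy as np
import pytest

from saxsshape import (
    ParticleModel,
    build_dataset,
    builtin_config,
    polydisperse_intensity,
)


@pytest.fixture(scope="session")
def xeuss():
    return builtin_config("Xeuss1800HR")


@pytest.fixture(scope="session")
def nano():
    return builtin_config("NanoInXiderHR")


@pytest.fixture(scope="session")
def sphere_curve_r100(xeuss):
    """Noiseless, unsmeared sphere R=100 Å intensity on the Xeuss grid."""
    model = ParticleModel("sphere", {"radius": 100.0}, sld_core=20.0)
    q = xeuss.q_grid
    return q, polydisperse_intensity(model, q)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small noisy Xeuss dataset: 4 curves per class, 36 total."""
    return build_dataset(["Xeuss1800HR"], 4, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
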