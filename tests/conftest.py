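import numpy as np
import pytest

from olihl import OLiHL, generate_regression


@pytest.fixture(scope="session")
def lam_grid():
    """Shape parameters spanning left-skewed to right-skewed regimes."""
    return (0.1, 0.5, 0.81, 1.0, 2.0, 5.0)


@pytest.fixture(scope="session")
def medium_sample():
    """A single reproducible OLiHL sample used across estimator tests."""
    return OLiHL(0.5).rvs(400, seed=20240901)


@pytest.fixture(scope="session")
def regression_data():
    """A reproducible censored regression dataset from the LOLiHL model."""
    return generate_regression(lam=2.0, beta=(2.0, -0.5, -0.01), sigma=0.8,
                               n=600, censor_fraction=0.2, seed=11)
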