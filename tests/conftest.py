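import numpy as np
import pytest

from mat_alpha_trace.models import RateModel
from mat_alpha_trace.msa import blosum62


@pytest.fixture(scope="session")
def b62():
    return blosum62()


@pytest.fixture(scope="session")
def toy3_model():
    """A small asymmetric-frequency reversible 3-state model (+G, k=2)."""
    S = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 0.5], [2.0, 0.5, 0.0]])
    pi = np.array([0.5, 0.3, 0.2])
    return RateModel(
        exchangeabilities=S, frequencies=pi, alpha=0.7, n_categories=2, alphabet="ABC"
    )


@pytest.fixture(scope="session")
def toy3_model_plain():
    """Same 3-state model without rate heterogeneity."""
    S = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 0.5], [2.0, 0.5, 0.0]])
    pi = np.array([0.5, 0.3, 0.2])
    return RateModel(exchangeabilities=S, frequencies=pi, alphabet="ABC")
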