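import numpy as np
import pytest

import pnim
from pnim.additive import Bandwidths, reference_bandwidth


@pytest.fixture(scope="session")
def model_ib_small():
    """Model I-B sample with its reduction, shared across test modules."""
    sample, truth = pnim.generate_model_I(800, "B", seed=11)
    reduction = pnim.fit_psdr(sample, K=5, l=10, seed=21)
    return sample, truth, reduction


@pytest.fixture(scope="session")
def model_ib_additive(model_ib_small):
    """Cross-validated additive fit on the shared Model I-B sample."""
    sample, truth, reduction = model_ib_small
    return pnim.fit_additive(sample, reduction, "cv")


def matched_bandwidths(Z, T):
    """Reference-rule bandwidths with the marginal/joint roles matched (h2=h3),
    which makes the density-ratio smoothing biases cancel."""
    Z = np.atleast_2d(Z.T).T
    U = np.column_stack([Z, T])
    h3 = reference_bandwidth(U, Z.shape[1] + 1)
    return Bandwidths(
        h0=h3,
        h1=reference_bandwidth(Z, Z.shape[1]),
        h2=h3,
        h3=h3,
        h4=reference_bandwidth(T, 1),
    )
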