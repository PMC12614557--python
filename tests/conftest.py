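import numpy as np
import pytest

import synpid as sp


@pytest.fixture(scope="session")
def worked_cov():
    """Covariance of X1, X2 iid N(0,1), Y = X1 + X2 + N(0,1)."""
    return np.array([[1.0, 0.0, 1.0],
                     [0.0, 1.0, 1.0],
                     [1.0, 1.0, 3.0]])


@pytest.fixture(scope="session")
def small_community():
    expr, truth = sp.generate_expression_study(
        n_genes=30, n_case=30, n_control=30, n_de=3, effect_size=2.0,
        seed=42, n_groups=2)
    return expr, truth


@pytest.fixture(scope="session")
def clustered_nodes():
    return sp.generate_clustered_community(2, 5, n_obs=400, seed=7)
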