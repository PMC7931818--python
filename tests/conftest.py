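import numpy as np
import pandas as pd
import pytest

import entromix as em


@pytest.fixture
def toy_ref():
    """Tiny handmade reference: 6 genes x 3 cell types, one clear marker each."""
    return pd.DataFrame(
        {
            "T_cell": [100.0, 2.0, 1.0, 5.0, 8.0, 3.0],
            "B_cell": [3.0, 90.0, 2.0, 6.0, 7.0, 4.0],
            "Mono": [1.0, 3.0, 80.0, 5.0, 9.0, 2.0],
        },
        index=["CD3E", "MS4A1", "CD14", "ACTB", "GAPDH", "B2M"],
    )


@pytest.fixture(scope="session")
def synth_ref():
    """Well-separated 10-type synthetic reference shared across tests."""
    return em.make_synthetic_reference(n_genes=1500, n_celltypes=10, seed=7)


@pytest.fixture(scope="session")
def synth_ref_small():
    return em.make_synthetic_reference(n_genes=800, n_celltypes=5, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
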