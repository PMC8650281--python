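import numpy as np
import pandas as pd
import pytest

from ipfnet import generate_compendium


@pytest.fixture(scope="session")
def small_study():
    """A small default-condition synthetic study shared across tests."""
    comp, truth = generate_compendium(
        n_batches=2, cases_per_batch=10, controls_per_batch=10, n_genes=300,
        n_up=20, n_down=10, pathway_size=20, severity_size=15, seed=42,
    )
    return comp, truth


@pytest.fixture()
def toy_matrix():
    """Deterministic 6-gene x 4-sample matrix."""
    rng = np.random.default_rng(7)
    return pd.DataFrame(
        rng.normal(5, 1, size=(6, 4)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{j}" for j in range(4)],
    )
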