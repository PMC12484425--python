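import warnings

import numpy as np
import pytest

from hurdlevp import synthetic as syn


@pytest.fixture(scope="session")
def small_study():
    """A reduced but fully structured study shared across tests."""
    cfg = syn.StudyConfig(
        n_species=8, n_sites=30, n_years=8, grid_rows=10, grid_cols=8
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return syn.generate_study(cfg, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
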