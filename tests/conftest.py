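import numpy as np
import pytest

from methylreg.simulate import promoter_preset, simulate_dataset


@pytest.fixture(scope="session")
def promoter_ds():
    """Small promoter-like dataset shared across tests (5 cell lines)."""
    cfg = promoter_preset(n_regions=60, n_genes=90, n_cell_lines=5, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
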