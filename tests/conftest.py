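import numpy as np
import pytest

from regnet.simulate import SimConfig, gen_atac, gen_rna


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        seed=7, n_donors_per_group=3, n_cells_per_donor=60, n_genes=150,
        n_peaks=60, coaccess_blocks=[((0, 6), 0.9), ((10, 16), 0.9)],
        motif_targets={"TFA": (0, 6)}, motif_insert_rate=1.0,
    )


@pytest.fixture(scope="session")
def small_rna(small_cfg):
    return gen_rna(small_cfg)


@pytest.fixture(scope="session")
def small_atac(small_cfg):
    return gen_atac(small_cfg)


@pytest.fixture(scope="session")
def uniform_rng():
    return np.random.default_rng(0)
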