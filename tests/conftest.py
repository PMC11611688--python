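import numpy as np
import pytest

from scact.model_core import build_model
from scact.preprocess import log_normalize
from scact.synthetic import SimConfig, chrom_layout_for, simulate_multiome
from scact.training import TrainConfig, train


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small paired cohort: 120 cells, 40 genes, 60 peaks, 2 chromosomes."""
    cfg = SimConfig(n_cells=120, n_genes=40, n_peaks=60, n_types=3,
                    n_chroms=2, n_batches=2, seed=7,
                    planted_links=[(5, 3, 2.0)])
    rna, atac, truth = simulate_multiome(cfg)
    return cfg, log_normalize(rna), atac, truth


@pytest.fixture(scope="session")
def tiny_model(tiny_cohort):
    """Untrained model matching the tiny cohort."""
    cfg, rna, atac, _ = tiny_cohort
    types = sorted(set(rna.cell_meta["cell_type"]))
    return build_model(rna.n_features, atac.n_features,
                       chrom_layout_for(cfg), types, k=10, seed=7,
                       rna_hidden=(32, 16), atac_hidden=(16, 8, 4))


@pytest.fixture(scope="session")
def tiny_trained(tiny_cohort):
    """A briefly trained small model, shared by translation/attribution tests."""
    cfg, rna, atac, truth = tiny_cohort
    types = sorted(set(rna.cell_meta["cell_type"]))
    model = build_model(rna.n_features, atac.n_features,
                        chrom_layout_for(cfg), types, k=10, seed=7,
                        rna_hidden=(32, 16), atac_hidden=(16, 8, 4))
    model, history = train(model, rna, atac,
                           TrainConfig(seed=7, pretrain_epochs=15,
                                       adversarial_epochs=15, batch_size=32))
    return model, history


@pytest.fixture
def rng():
    return np.random.default_rng(0)
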