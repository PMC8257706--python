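import numpy as np
import pytest

from hybrid_ase import SimConfig, place_genes, simulate_genomes


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated genome + SNPs + genes shared across tests."""
    cfg = SimConfig(seed=11, n_chroms=2, chrom_length_bp=60_000, n_genes=8)
    gen_rng = cfg.rng()
    reference, snps = simulate_genomes(cfg, gen_rng)
    genes = place_genes(cfg, gen_rng)
    return cfg, reference, snps, genes
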