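import numpy as np
import pandas as pd
import pytest

from ldne import GenotypeMatrix, LDConfig, SimConfig, simulate, summarize_ld
from ldne.genotype_io import filter_sites


def make_matrix(dosages, ploidy=2, cM=None, chrom=None, missing=None):
    """Small GenotypeMatrix from a dense dosage array (individuals x sites)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    sites = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos_bp": np.arange(1, m + 1) * 1000,
        "pos_cM": cM if cM is not None else np.arange(m, dtype=float),
        "ref": ["A"] * m,
        "alt": ["C"] * m,
    })
    miss = np.zeros_like(dosages, dtype=bool) if missing is None else missing
    return GenotypeMatrix(dosages, miss, ploidy, sites)


@pytest.fixture(scope="session")
def panmictic_sim():
    """Equilibrium panmictic population, N = 300, moderate SNP density."""
    cfg = SimConfig(N=300, chromosomes=4, chrom_length_cM=100.0,
                    chrom_length_bp=10_000_000, mu=6.0e-9, sample_n=80,
                    seed=101, dtwf_generations=60)
    g, truth = simulate(cfg)
    return filter_sites(g, maf_min=0.01, call_rate_min=0.0), truth


@pytest.fixture(scope="session")
def panmictic_summary(panmictic_sim):
    g, _ = panmictic_sim
    return summarize_ld(g, LDConfig(seed=5))


@pytest.fixture(scope="session")
def island_sim():
    """Two-deme island metapopulation at migration-drift equilibrium."""
    cfg = SimConfig(s=2, N=400, m=0.001, chromosomes=4,
                    chrom_length_cM=100.0, chrom_length_bp=10_000_000,
                    mu=5.0e-9, sample_n=80, seed=202, dtwf_generations=60)
    g, truth = simulate(cfg)
    return filter_sites(g, maf_min=0.01, call_rate_min=0.0), truth


@pytest.fixture(scope="session")
def island_summary(island_sim):
    g, _ = island_sim
    return summarize_ld(g, LDConfig(seed=6))
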