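import numpy as np
import pytest

import hlafine as hf


@pytest.fixture(scope="session")
def small_pool():
    """A small two-gene haplotype pool with 5 LD blocks of 20 SNPs."""
    cfg = hf.PoolConfig(
        n_haplotypes=600,
        n_blocks=5,
        block_size=20,
        sharing_rate=0.9,
        hla_genes={
            "C": {"01:02": 0.3, "07:02": 0.5, "04:01": 0.2},
            "DQA1": {"01:02": 0.4, "03:01": 0.6},
        },
    )
    return hf.build_haplotype_pool(cfg, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_pool):
    """500 diploid individuals drawn from the small pool (noiseless)."""
    snp_G, allele_G, ancestry = hf.simulate_genotypes(small_pool, 500, seed=21)
    return snp_G, allele_G, ancestry


@pytest.fixture()
def tiny_aa_map():
    """The HLA-C p.11 Ala/Ser dichotomy plus one extra position."""
    return hf.AlleleAAMap(
        {
            "C": {
                "07:02": {11: "Ala", 45: "Gly"},
                "01:02": {11: "Ser", 45: "Gly"},
            }
        }
    )
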