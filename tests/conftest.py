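import numpy as np
import pandas as pd
import pytest

from methmr import simdata


@pytest.fixture(scope="session")
def small_pool():
    """Two independent 3-SNP blocks plus two singleton SNPs."""
    return simdata.make_haplotype_pool(
        n_snps=8, maf_low=0.2, maf_high=0.4, block_sizes=[3, 3, 1, 1],
        within_block_rho=0.8, pool_size=1000, seed=42,
    )


@pytest.fixture(scope="session")
def small_panel(small_pool):
    return simdata.draw_genotypes(small_pool, 400, seed=7)


def make_summary(snp_ids, betas, ses, *, pos=None, ea=None, oa=None, eaf=0.3, n=1000):
    """Summary-statistic table builder with self-consistent normal p-values."""
    from methmr.assoc import normal_p

    m = len(snp_ids)
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "1",
            "pos": pos if pos is not None else np.arange(m) * 10_000 + 1_000_000,
            "effect_allele": ea if ea is not None else ["A"] * m,
            "other_allele": oa if oa is not None else ["G"] * m,
            "beta": betas,
            "se": ses,
            "p": normal_p(betas, ses),
            "eaf": eaf,
            "n": n,
        }
    )


@pytest.fixture
def summary_builder():
    return make_summary
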