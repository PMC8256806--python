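import numpy as np
import pytest

from driftscan.genotype_io import MISSING, GenotypeDataset, SNPRecord


def make_snps(n, chrom="1", start=1, spacing=1000):
    return [
        SNPRecord(
            snp_id=f"s{chrom}_{j}", chrom=chrom, pos_bp=start + j * spacing, allele1="A", allele2="B"
        )
        for j in range(n)
    ]


def make_dataset(dosages, populations=None, chrom="1"):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    pops = populations or ["P1"] * n
    return GenotypeDataset(
        sample_ids=[f"ind{i}" for i in range(n)],
        populations=list(pops),
        snps=make_snps(m, chrom=chrom),
        dosages=dosages,
    )


@pytest.fixture
def toy_dataset():
    """3 samples x 2 SNPs, two populations, one missing call."""
    return make_dataset(
        [[0, 2], [1, 1], [2, MISSING]],
        populations=["P1", "P1", "P2"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dataset(rng, n_samples=7, n_snps=11, missing_rate=0.1, n_pops=2):
    dos = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    miss = rng.random((n_samples, n_snps)) < missing_rate
    dos[miss] = MISSING
    pops = [f"P{i % n_pops + 1}" for i in range(n_samples)]
    return make_dataset(dos, populations=pops)
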