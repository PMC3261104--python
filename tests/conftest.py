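import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from genesift import (
    GeneCatalog,
    GeneModel,
    SnpRecord,
    SyntheticSpec,
    generate,
)

settings.register_profile(
    "suite",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bundle():
    """Default planted synthetic study, shared across tests."""
    return generate(SyntheticSpec(rng_seed=7))


@pytest.fixture
def linear_catalog():
    """Six non-overlapping 10-kb genes spaced 100 kb apart on chr1."""
    genes = [
        GeneModel(f"G{i}", f"G{i}", "chr1", i * 100_000, i * 100_000 + 10_000)
        for i in range(1, 7)
    ]
    return GeneCatalog(genes)


def make_snp(snp_id, chrom, pos, p=1e-8):
    return SnpRecord(snp_id, chrom, pos, p)


@pytest.fixture
def random_layout():
    """Factory: random non-overlapping gene catalog plus random SNPs."""

    def _make(seed, n_genes=40, n_snps=30, n_chrom=2):
        rng = np.random.default_rng(seed)
        catalog = GeneCatalog()
        gi = 0
        for c in range(n_chrom):
            cursor = 0
            for _ in range(n_genes // n_chrom):
                cursor += int(rng.integers(1_000, 120_000))
                length = int(rng.integers(2_000, 60_000))
                gi += 1
                catalog.add(
                    GeneModel(f"G{gi:03d}", f"G{gi:03d}", f"chr{c+1}", cursor, cursor + length)
                )
                cursor += length
        span = cursor
        snps = [
            SnpRecord(
                f"rs{i}",
                f"chr{int(rng.integers(1, n_chrom + 1))}",
                int(rng.integers(0, span)),
                1e-8,
            )
            for i in range(n_snps)
        ]
        return catalog, snps

    return _make
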