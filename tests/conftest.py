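import numpy as np
import pandas as pd
import pytest

from asoc import SimConfig, simulate_study


def make_counts(rows):
    """Build a count table from (chrom, pos, snp_id, ref, alt, rc, ac, gt, dbsnp)."""
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "snp_id",
            "ref",
            "alt",
            "ref_count",
            "alt_count",
            "genotype",
            "in_dbsnp",
        ],
    )


@pytest.fixture
def toy_counts():
    """The five-row hand-checkable qualification-filter table.

    Row 1: DP=25, 20/5 autosomal het in dbSNP        -> pass
    Row 2: DP=20 but one allele seen once            -> low allele count
    Row 3: DP=19                                     -> low depth
    Row 4: DP=40, 2/38                               -> pass
    Row 5: homozygous genotype                       -> non-het
    """
    return make_counts(
        [
            ("chr1", 1000, "rs1", "A", "G", 20, 5, "0/1", True),
            ("chr1", 2000, "rs2", "C", "T", 19, 1, "0/1", True),
            ("chr1", 3000, "rs3", "G", "A", 10, 9, "0/1", True),
            ("chr1", 4000, "rs4", "T", "C", 2, 38, "0/1", True),
            ("chr1", 5000, "rs5", "A", "C", 30, 10, "1/1", True),
        ]
    )


@pytest.fixture(scope="session")
def study():
    """One fully seeded synthetic study reused by integration tests."""
    cfg = SimConfig(n_snps=20_000, pi_asoc=0.1, theta_asoc=0.75, rho=0.01, seed=11)
    return simulate_study(cfg)


def brute_force_overlap(a_start, a_end, b_start, b_end):
    """Half-open interval overlap by >= 1 bp."""
    return a_start < b_end and b_start < a_end


def rng_for(name: str) -> np.random.Generator:
    """Deterministic per-test RNG (stable across processes)."""
    import zlib

    return np.random.default_rng(zlib.crc32(name.encode()) % 2**31)
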