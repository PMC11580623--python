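import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "fixed", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("fixed")

from sdrscan.qc import GenotypeTable, SexFrame  # noqa: E402
from sdrscan.simulate import CohortConfig, simulate_cohort  # noqa: E402


@pytest.fixture(scope="session")
def noiseless_cohort():
    """24F/20M ZW cohort with no genotype error or missingness and a
    bounded-away-from-threshold allele-frequency floor."""
    return simulate_cohort(CohortConfig(
        seed=11, genotype_error_rate=0.0, missing_rate=0.0,
        n_autosomal_snps=2000, maf_dist=("beta", 0.8, 0.8, 0.20, 0.80)))


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default study conditions: 24F/20M, 0.5% genotype error,
    2% missingness, 20 planted ZW SNPs, 10,000 autosomal SNPs."""
    return simulate_cohort(CohortConfig(seed=7))


def make_table(codes, n_f, n_m, dp=30, gq=60, chrom="chr1", qual=100.0):
    """Small GenotypeTable from an explicit code matrix.

    Samples are F01.. then M01..; one row per site at positions 100, 200...
    """
    codes = np.asarray(codes, dtype=np.int8)
    n_sites = codes.shape[0]
    samples = [f"F{i:02d}" for i in range(1, n_f + 1)] + \
              [f"M{i:02d}" for i in range(1, n_m + 1)]
    assert codes.shape[1] == len(samples)
    sites = pd.DataFrame({
        "chrom": chrom, "pos": 100 * np.arange(1, n_sites + 1),
        "ref": "A", "alt": "G", "qual": qual})
    dp = np.broadcast_to(np.asarray(dp), codes.shape).copy()
    gq = np.broadcast_to(np.asarray(gq), codes.shape).copy()
    return GenotypeTable(samples=samples, sites=sites, codes=codes,
                         dp=dp.astype(int), gq=gq.astype(int))


def make_sexframe(n_f, n_m, depth=30.0):
    samples = [f"F{i:02d}" for i in range(1, n_f + 1)] + \
              [f"M{i:02d}" for i in range(1, n_m + 1)]
    return SexFrame(pd.DataFrame({
        "sample_id": samples,
        "sex": ["F"] * n_f + ["M"] * n_m,
        "genome_mean_depth": depth}))
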