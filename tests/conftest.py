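import numpy as np
import pytest

from eqtlhot import SimConfig, simulate_dataset
from eqtlhot.datatypes import ExpressionData, GeneInfo, GenotypeData, SnpInfo


@pytest.fixture(scope="session")
def small_cohort():
    """Default small cohort: 50 samples, 200 SNPs, 100 genes, haploid."""
    return simulate_dataset(SimConfig(seed=7))


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with one planted trans hotspot and one cis pair."""
    cfg = SimConfig(
        seed=11,
        n_samples=200,
        n_snps=120,
        n_genes=120,
        hotspot_spec=[(30, 40, 1.0)],
        cis_spec=[(5, 2, 1.2)],
    )
    return cfg, simulate_dataset(cfg)


@pytest.fixture
def tiny_genotypes():
    """Hand-built 4-sample, 2-SNP genotype set with one missing call."""
    snps = [
        SnpInfo(id="rs1", chrom="chr1", pos=100, ref_allele="A", alt_allele="G"),
        SnpInfo(id="rs2", chrom="chr1", pos=900, ref_allele="C", alt_allele="T"),
    ]
    dosage = np.array([[0.0, 2.0], [1.0, np.nan], [2.0, 0.0], [0.0, 1.0]])
    return GenotypeData(samples=["a", "b", "c", "d"], snps=snps, dosage=dosage, ploidy=2)


def make_expression(values, chrom="chrX", spacing=50_000):
    """Expression container with genes spread far apart on one chromosome."""
    values = np.asarray(values, dtype=float)
    n, G = values.shape
    genes = [
        GeneInfo(id=f"g{j}", chrom=chrom, start=(j + 1) * spacing, end=(j + 1) * spacing + 500)
        for j in range(G)
    ]
    return ExpressionData(samples=[f"s{i}" for i in range(n)], genes=genes, values=values)
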