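"""Synthetic eQTL cohort generator.

Emulates the structure of an organism-cross eQTL panel (haploid
segregants by default): independent biallelic SNPs laid out evenly over
a configurable number of chromosomes, expression built from planted cis
effects, planted trans hotspots (one SNP driving many distant genes),
low-rank shared-factor confounding, optional batch shifts, and Gaussian
noise. Effect sizes apply to the standardized dosage, so power is
MAF-independent and analytically checkable. Every draw flows from the
mandatory seed; a truth table records everything planted.

The confounder factors can optionally be correlated with randomly chosen
"anchor" SNPs (``confounder_geno_corr``). This models technical or batch
structure that is itself aligned with genotype — the regime in which a
plain per-SNP regression produces spurious trans hotspots while the
correlation-corrected test does not. With factors fully independent of
genotype, per-test p-values of the plain regression remain marginally
calibrated and, at desk-scale SNP counts, essentially never cross a
5e-5 threshold for many genes at once.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io
from .datatypes import ExpressionData, GeneInfo, GenotypeData, SnpInfo
from .exceptions import ConfigError

logger = logging.getLogger(__name__)

_SNP_SPACING = 1_000  # bp between adjacent simulated SNPs
_GENE_LEN = 500  # bp gene body length


@dataclass
class SimConfig:
    """Cohort layout and planted-effect specification.

    ``hotspot_spec`` entries are ``(snp_index, n_target_genes, effect)``;
    ``cis_spec`` entries are ``(snp_index, gene_index, effect)``. Effects
    multiply the standardized dosage.
    """

    seed: int
    n_samples: int = 50
    n_snps: int = 200
    n_genes: int = 100
    n_chromosomes: int = 4
    maf_range: tuple[float, float] = (0.1, 0.5)
    ploidy: int = 1
    hotspot_spec: list[tuple[int, int, float]] = field(default_factory=list)
    cis_spec: list[tuple[int, int, float]] = field(default_factory=list)
    n_confounder_factors: int = 0
    confounder_strength: float = 0.0
    confounder_geno_corr: float = 0.0
    batch_assignment: np.ndarray | None = None
    batch_effect_sd: float = 1.0
    noise_sd: float = 1.0
    cis_window: int = 10_000

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.ploidy not in (1, 2):
            raise ConfigError("ploidy must be 1 or 2")
        if not (0 <= self.confounder_geno_corr < 1):
            raise ConfigError("confounder_geno_corr must be in [0, 1)")
        if min(self.n_samples, self.n_snps, self.n_genes, self.n_chromosomes) < 1:
            raise ConfigError("all dimensions must be >= 1")
        for s, _, _ in self.hotspot_spec:
            if not 0 <= s < self.n_snps:
                raise ConfigError(f"hotspot snp_index {s} out of range")
        for s, g, _ in self.cis_spec:
            if not 0 <= s < self.n_snps or not 0 <= g < self.n_genes:
                raise ConfigError(f"cis pair ({s}, {g}) out of range")


@dataclass
class TruthTable:
    """What was planted: hotspot SNPs with their target gene index sets,
    cis pairs, confounder scores/loadings and anchor SNP indices."""

    hotspots: list[tuple[int, list[int], float]]
    cis_pairs: list[tuple[int, int, float]]
    confounder_scores: np.ndarray | None = None
    confounder_loadings: np.ndarray | None = None
    confounder_anchors: list[int] = field(default_factory=list)


def _chrom_sizes(total: int, n_chrom: int) -> list[int]:
    base = total // n_chrom
    rem = total % n_chrom
    return [base + (1 if c < rem else 0) for c in range(n_chrom)]


def simulate_genotypes(cfg: SimConfig) -> GenotypeData:
    """Draw dosages per SNP as Binomial(ploidy, maf) with
    maf ~ Uniform(maf_range); SNPs evenly spaced over the chromosomes."""
    rng = np.random.default_rng(cfg.seed)
    snps: list[SnpInfo] = []
    for c, size in enumerate(_chrom_sizes(cfg.n_snps, cfg.n_chromosomes)):
        for j in range(size):
            snps.append(
                SnpInfo(
                    id=f"snp{len(snps)}",
                    chrom=f"chr{c + 1}",
                    pos=(j + 1) * _SNP_SPACING,
                    ref_allele="A",
                    alt_allele="G",
                )
            )
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_snps)
    dosage = rng.binomial(cfg.ploidy, mafs, size=(cfg.n_samples, cfg.n_snps)).astype(float)
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    return GenotypeData(samples=samples, snps=snps, dosage=dosage, ploidy=cfg.ploidy)


def _gene_layout(cfg: SimConfig, snps: list[SnpInfo]) -> list[GeneInfo]:
    """Genes spread evenly over the same chromosomes as the SNPs."""
    chrom_extent: dict[str, int] = {}
    for s in snps:
        chrom_extent[s.chrom] = max(chrom_extent.get(s.chrom, 0), s.pos)
    chroms = list(chrom_extent)
    genes: list[GeneInfo] = []
    sizes = _chrom_sizes(cfg.n_genes, len(chroms))
    for c, size in zip(chroms, sizes):
        spacing = max(chrom_extent[c] // max(size, 1), _GENE_LEN + 100)
        for j in range(size):
            start = j * spacing + spacing // 2
            genes.append(
                GeneInfo(
                    id=f"gene{len(genes)}", chrom=c, start=max(start, 1),
                    end=max(start, 1) + _GENE_LEN,
                )
            )
    return genes


def _standardized(x: np.ndarray, what: str) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ConfigError(f"{what} is constant in the simulated cohort; choose another SNP")
    return (x - x.mean()) / sd


def simulate_expression(
    geno: GenotypeData, cfg: SimConfig
) -> tuple[ExpressionData, TruthTable]:
    """Build expression from planted effects + confounding + batch + noise.

    Gene positions are arranged so every cis pair satisfies the cis
    window and every hotspot target is in trans (targets are drawn only
    from genes outside the hotspot SNP's cis window).
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    n, G = cfg.n_samples, cfg.n_genes
    genes = _gene_layout(cfg, geno.snps)

    # relocate cis-pair genes next to their SNP (distance 0 => cis)
    for s_idx, g_idx, _ in cfg.cis_spec:
        snp = geno.snps[s_idx]
        start = max(snp.pos - _GENE_LEN // 2, 1)
        genes[g_idx] = GeneInfo(
            id=genes[g_idx].id, chrom=snp.chrom, start=start, end=start + _GENE_LEN
        )

    from .hotspot import classify_cis_trans

    E = np.zeros((n, G))
    cis_gene_idx = {g for _, g, _ in cfg.cis_spec}
    truth_hotspots: list[tuple[int, list[int], float]] = []
    for s_idx, n_targets, eff in cfg.hotspot_spec:
        snp = geno.snps[s_idx]
        z = _standardized(geno.dosage[:, s_idx], f"hotspot SNP {snp.id}")
        eligible = [
            j
            for j in range(G)
            if j not in cis_gene_idx
            and not classify_cis_trans(snp, genes[j], cfg.cis_window)
        ]
        if n_targets > len(eligible):
            raise ConfigError(
                f"hotspot at SNP {snp.id}: {n_targets} targets requested but only "
                f"{len(eligible)} trans genes available"
            )
        targets = sorted(rng.choice(eligible, size=n_targets, replace=False).tolist())
        for j in targets:
            E[:, j] += eff * z
        truth_hotspots.append((s_idx, targets, eff))

    for s_idx, g_idx, eff in cfg.cis_spec:
        z = _standardized(geno.dosage[:, s_idx], f"cis SNP {geno.snps[s_idx].id}")
        E[:, g_idx] += eff * z

    F = L = None
    anchors: list[int] = []
    k = cfg.n_confounder_factors
    if k > 0 and cfg.confounder_strength > 0:
        F = rng.standard_normal((n, k))
        rho = cfg.confounder_geno_corr
        if rho > 0:
            anchors = sorted(rng.choice(cfg.n_snps, size=k, replace=False).tolist())
            for j, a in enumerate(anchors):
                za = _standardized(geno.dosage[:, a], f"anchor SNP {geno.snps[a].id}")
                F[:, j] = rho * za + np.sqrt(1 - rho**2) * F[:, j]
        L = rng.standard_normal((G, k))
        E += cfg.confounder_strength * (F @ L.T) / np.sqrt(k)

    if cfg.batch_assignment is not None:
        batches = np.asarray(cfg.batch_assignment)
        if batches.shape[0] != n:
            raise ConfigError("batch_assignment length must equal n_samples")
        for b in np.unique(batches):
            shift = rng.normal(0.0, cfg.batch_effect_sd, size=G)
            E[batches == b] += shift

    E += rng.normal(0.0, cfg.noise_sd, size=(n, G))
    expr = ExpressionData(samples=list(geno.samples), genes=genes, values=E)
    truth = TruthTable(
        hotspots=truth_hotspots,
        cis_pairs=list(cfg.cis_spec),
        confounder_scores=F,
        confounder_loadings=L,
        confounder_anchors=anchors,
    )
    return expr, truth


def simulate_dataset(cfg: SimConfig) -> tuple[GenotypeData, ExpressionData, TruthTable]:
    """Genotypes and expression in one call."""
    geno = simulate_genotypes(cfg)
    expr, truth = simulate_expression(geno, cfg)
    return geno, expr, truth


# ---------------------------------------------------------------------------
# frozen study presets
# ---------------------------------------------------------------------------


def null_config(seed: int) -> SimConfig:
    """Global-null cohort for scan calibration: 100 samples, 200 SNPs,
    100 genes, no planted effects, no confounding."""
    return SimConfig(seed=seed, n_samples=100, n_snps=200, n_genes=100)


def planted_hotspot_config(seed: int) -> SimConfig:
    """One trans hotspot driving 50 of 200 genes at standardized effect
    1.0 in a 300-sample cohort (the recovery benchmark); the hotspot SNP
    sits mid-chromosome-1."""
    return SimConfig(
        seed=seed,
        n_samples=300,
        n_snps=200,
        n_genes=200,
        hotspot_spec=[(25, 50, 1.0)],
    )


def confounded_null_config(seed: int) -> SimConfig:
    """Shared-factor confounding with no genetic effects on expression.

    Three factors at strength 3 whose scores correlate 0.8 with randomly
    chosen anchor SNPs — batch/technical structure aligned with genotype,
    the regime that produces spurious trans hotspots under a plain
    per-SNP regression. Sized (n=80, 300 SNPs, 300 genes) so that the
    plain scan's failure mode is essentially deterministic while the
    corrected scan retains only moderate residual leakage.
    """
    return SimConfig(
        seed=seed,
        n_samples=80,
        n_snps=300,
        n_genes=300,
        n_confounder_factors=3,
        confounder_strength=3.0,
        confounder_geno_corr=0.8,
    )


def write_fixture_suite(
    geno: GenotypeData,
    expr: ExpressionData,
    truth: TruthTable,
    out_dir: str | os.PathLike,
) -> dict[str, Path]:
    """Serialize one cohort as PLINK + VCF + plain matrices + truth TSVs.

    The three genotype serializations re-read to identical dosage
    matrices (the format-equivalence property).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    data_io.write_plink_binary(geno, out / "genotypes")
    paths["plink_prefix"] = out / "genotypes"
    data_io.write_vcf(geno, out / "genotypes.vcf")
    paths["vcf"] = out / "genotypes.vcf"
    paths.update(data_io.write_plain_matrices(geno, expr, out))

    rows = [
        {"snp_index": s, "snp_id": geno.snps[s].id, "target_gene_ids":
         ",".join(expr.genes[j].id for j in targets), "effect": eff}
        for s, targets, eff in truth.hotspots
    ]
    pd.DataFrame(rows, columns=["snp_index", "snp_id", "target_gene_ids", "effect"]).to_csv(
        out / "truth_hotspots.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {"snp_index": s, "snp_id": geno.snps[s].id, "gene_index": g,
             "gene_id": expr.genes[g].id, "effect": eff}
            for s, g, eff in truth.cis_pairs
        ],
        columns=["snp_index", "snp_id", "gene_index", "gene_id", "effect"],
    ).to_csv(out / "truth_cis.tsv", sep="\t", index=False)
    paths["truth_hotspots"] = out / "truth_hotspots.tsv"
    paths["truth_cis"] = out / "truth_cis.tsv"
    logger.info("fixture suite written to %s", out)
    return paths
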