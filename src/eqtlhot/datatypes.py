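"""Core in-memory containers shared across the pipeline.

All genomic coordinates are 1-based and inclusive, matching the native
conventions of PLINK .bim and VCF. Chromosome names are opaque strings:
``"chrII"`` and ``"2"`` are distinct and are never normalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SnpInfo:
    """A single variant: identifier, position and the two alleles.

    ``dosage`` columns elsewhere count copies of ``alt_allele``.
    """

    id: str
    chrom: str
    pos: int  # 1-based bp
    ref_allele: str = "N"
    alt_allele: str = "N"

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("SNP id must be non-empty")
        if self.pos < 1:
            raise InputError(f"SNP {self.id}: position must be >= 1, got {self.pos}")

    def label(self) -> str:
        """Render as ``chrom:pos_ref/alt``, e.g. ``chrII:117298_A/G``."""
        return f"{self.chrom}:{self.pos}_{self.ref_allele}/{self.alt_allele}"


@dataclass(frozen=True)
class GeneInfo:
    """A gene body: identifier and 1-based inclusive [start, end] span."""

    id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("gene id must be non-empty")
        if self.start < 1 or self.end < self.start:
            raise InputError(
                f"gene {self.id}: invalid span [{self.start}, {self.end}]"
            )


def _check_unique(ids: list[str], kind: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise InputError(f"duplicate {kind} id: {dup!r}")


@dataclass
class GenotypeData:
    """Sample x SNP dosage matrix plus per-SNP metadata.

    ``dosage[i, j]`` counts alt-allele copies of SNP ``j`` in sample ``i``,
    a float in ``[0, ploidy]`` with ``NaN`` marking missing genotypes.
    """

    samples: list[str]
    snps: list[SnpInfo]
    dosage: np.ndarray  # (n_samples, n_snps) float, NaN = missing
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.snps)):
            raise InputError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        _check_unique([s.id for s in self.snps], "SNP")
        _check_unique(self.samples, "sample")
        if self.ploidy not in (1, 2):
            raise InputError(f"ploidy must be 1 or 2, got {self.ploidy}")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosage < 0) | (self.dosage > self.ploidy))
        if bad:
            raise InputError(f"{int(bad)} dosage entries outside [0, {self.ploidy}]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def imputed_dosage(self) -> np.ndarray:
        """Dosage with missing entries replaced by the per-SNP mean.

        SNPs that are entirely missing are filled with 0. Imputation is
        deterministic and logged; the original missingness stays available
        through :attr:`missing_mask`.
        """
        X = self.dosage.copy()
        miss = np.isnan(X)
        n_miss = int(miss.sum())
        if n_miss:
            col_mean = np.where(
                miss.all(axis=0), 0.0, np.nanmean(np.where(miss, np.nan, X), axis=0)
            )
            X[miss] = np.broadcast_to(col_mean, X.shape)[miss]
            logger.info("mean-imputed %d missing genotype calls", n_miss)
        return X


@dataclass
class ExpressionData:
    """Sample x gene expression matrix plus per-gene metadata."""

    samples: list[str]
    genes: list[GeneInfo]
    values: np.ndarray  # (n_samples, n_genes) float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.genes)):
            raise InputError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.genes)} genes"
            )
        _check_unique([g.id for g in self.genes], "gene")
        _check_unique(self.samples, "sample")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def drop_constant_genes(self) -> "ExpressionData":
        """Drop zero-variance gene columns, logging a warning per drop."""
        sd = self.values.std(axis=0)
        keep = sd > 0
        if keep.all():
            return self
        dropped = [g.id for g, k in zip(self.genes, keep) if not k]
        logger.warning(
            "dropping %d constant gene(s): %s", len(dropped), ", ".join(dropped[:10])
        )
        return ExpressionData(
            samples=list(self.samples),
            genes=[g for g, k in zip(self.genes, keep) if k],
            values=self.values[:, keep],
        )


@dataclass
class PvalueMatrix:
    """SNP x gene association p-values, the scan -> hotspot interchange object."""

    snps: list[SnpInfo]
    genes: list[GeneInfo]
    pvalues: np.ndarray  # (n_snps, n_genes) in [0, 1]
    annotated: bool = field(default=True)

    def __post_init__(self) -> None:
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        if self.pvalues.shape != (len(self.snps), len(self.genes)):
            raise InputError(
                f"p-value shape {self.pvalues.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.genes)} genes"
            )
        if self.pvalues.size and (
            np.nanmin(self.pvalues) < 0 or np.nanmax(self.pvalues) > 1
        ):
            raise InputError("p-values must lie in [0, 1]")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def align_samples(
    geno: GenotypeData, expr: ExpressionData
) -> tuple[GenotypeData, ExpressionData]:
    """Restrict both datasets to their common samples, in genotype order.

    Raises :class:`InputError` on an empty intersection; logs how many
    samples were dropped from either side.
    """
    common = [s for s in geno.samples if s in set(expr.samples)]
    if not common:
        raise InputError("genotype and expression share no sample ids")
    n_drop = (len(geno.samples) - len(common)) + (len(expr.samples) - len(common))
    if n_drop:
        logger.info("sample alignment dropped %d non-shared sample(s)", n_drop)
    g_idx = [geno.samples.index(s) for s in common]
    e_pos = {s: i for i, s in enumerate(expr.samples)}
    e_idx = [e_pos[s] for s in common]
    geno2 = GenotypeData(
        samples=common,
        snps=list(geno.snps),
        dosage=geno.dosage[g_idx, :],
        ploidy=geno.ploidy,
    )
    expr2 = ExpressionData(
        samples=common, genes=list(expr.genes), values=expr.values[e_idx, :]
    )
    return geno2, expr2
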