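"""Regulatory-hotspot calling from a SNP x gene p-value matrix.

Stages: eQTL thresholding (strict ``p < eqtl_threshold``), cis/trans
classification by genomic distance, a per-SNP binomial enrichment test
(each of the ``n`` genome-wide trans eQTLs falls on any of the ``m`` SNPs
with probability ``1/m`` under the null; the statistic is the binomial
survival probability ``P(X >= k_i)``), Bonferroni correction at
``alpha / m``, fixed-width genome bins with merging of adjacent
significant bins, and putative-regulator assignment (cis-eQTL target
genes of SNPs inside each hotspot region).

cis eQTLs are excluded symmetrically: from the genome-wide total ``n``
and from each per-SNP count ``k_i``, so the binomial null and the
observed counts draw from the same event set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatypes import GeneInfo, PvalueMatrix, SnpInfo
from .exceptions import EqtlHotError, InputError

logger = logging.getLogger(__name__)


@dataclass
class HotspotParams:
    """Thresholds of the hotspot analysis (defaults follow common eQTL practice:
    per-test 5e-5, 10-kb cis window, 20-kb bins, family-wise 0.05)."""

    eqtl_threshold: float = 5e-5
    cis_window: int = 10_000
    bin_width: int = 20_000
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.eqtl_threshold <= 1):
            raise InputError("eqtl_threshold must be in (0, 1]")
        if not (0 < self.alpha <= 1):
            raise InputError("alpha must be in (0, 1]")
        if self.cis_window <= 0 or self.bin_width <= 0:
            raise InputError("cis_window and bin_width must be positive")


@dataclass(frozen=True)
class EqtlCall:
    snp_index: int
    gene_index: int
    pvalue: float
    is_cis: bool


@dataclass(frozen=True)
class SnpHotspotStat:
    snp_index: int
    trans_count: int  # k_i
    binomial_p: float
    significant: bool


@dataclass(frozen=True)
class Bin:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    index_in_chrom: int


@dataclass
class HotspotCall:
    region: tuple[str, int, int]  # chrom, start, end (1-based inclusive)
    bins_merged: int
    peak_snp: SnpInfo
    total_trans_eqtls: int
    regulators: list[str] = field(default_factory=list)

    @property
    def peak_label(self) -> str:
        return self.peak_snp.label()


def classify_cis_trans(snp: SnpInfo, gene: GeneInfo, cis_window: int) -> bool:
    """True iff the pair is cis: same chromosome and the SNP lies within
    ``cis_window`` bp of the gene body (0 if inside; boundary inclusive)."""
    if snp.chrom != gene.chrom:
        return False
    if gene.start <= snp.pos <= gene.end:
        return True
    gap = gene.start - snp.pos if snp.pos < gene.start else snp.pos - gene.end
    return gap <= cis_window


def call_eqtls(pm: PvalueMatrix, params: HotspotParams) -> list[EqtlCall]:
    """All (snp, gene) pairs with ``p`` strictly below the threshold,
    tagged cis/trans."""
    if not pm.annotated:
        raise InputError("p-value matrix lacks genomic annotations")
    si, gi = np.nonzero(pm.pvalues < params.eqtl_threshold)
    calls = [
        EqtlCall(
            snp_index=int(i),
            gene_index=int(j),
            pvalue=float(pm.pvalues[i, j]),
            is_cis=classify_cis_trans(pm.snps[i], pm.genes[j], params.cis_window),
        )
        for i, j in zip(si, gi)
    ]
    n_cis = sum(c.is_cis for c in calls)
    logger.info("called %d eQTLs (%d cis, %d trans)", len(calls), n_cis, len(calls) - n_cis)
    return calls


def binomial_hotspot_test(
    trans_counts: np.ndarray | list[int], m: int, alpha: float
) -> list[SnpHotspotStat]:
    """Per-SNP binomial enrichment test.

    ``n`` = total trans eQTLs genome-wide; under the null each falls on
    any of the ``m`` SNPs with probability ``1/m``, so the p-value of SNP
    ``i`` with ``k_i`` trans eQTLs is ``P(X >= k_i)`` for
    ``X ~ Binomial(n, 1/m)`` (survival function at ``k_i - 1``).
    Significance is Bonferroni at ``alpha / m`` with a strict inequality.
    """
    counts = np.asarray(trans_counts, dtype=int)
    if m < 1:
        raise InputError("m must be >= 1")
    if (counts < 0).any():
        raise InputError("trans counts must be non-negative")
    n = int(counts.sum())
    if n == 0:
        logger.warning("no trans eQTLs: all binomial p-values are 1")
        pvals = np.ones(len(counts))
    else:
        pvals = stats.binom.sf(counts - 1, n, 1.0 / m)
    thresh = alpha / m
    return [
        SnpHotspotStat(
            snp_index=i,
            trans_count=int(k),
            binomial_p=float(p),
            significant=bool(p < thresh),
        )
        for i, (k, p) in enumerate(zip(counts, pvals))
    ]


def min_significant_count(n: int, m: int, alpha: float) -> int:
    """Smallest trans count whose binomial p-value clears ``alpha / m``
    (the dashed threshold line of the linkage track); ``n + 1`` if none."""
    if n == 0:
        return 1
    ks = np.arange(0, n + 2)
    p = stats.binom.sf(ks - 1, n, 1.0 / m)
    ok = np.nonzero(p < alpha / m)[0]
    return int(ks[ok[0]]) if len(ok) else n + 1


def define_bins(chrom_extents: dict[str, int], bin_width: int) -> list[Bin]:
    """Fixed-width bins ``[1, w], [w+1, 2w], ...`` per chromosome, last bin
    truncated at the extent; ordered by chromosome order of appearance."""
    bins: list[Bin] = []
    for chrom, extent in chrom_extents.items():
        if extent < 1:
            raise InputError(f"extent of {chrom} must be positive")
        n_bins = -(-extent // bin_width)  # ceiling
        for b in range(n_bins):
            bins.append(
                Bin(
                    chrom=chrom,
                    start=b * bin_width + 1,
                    end=min((b + 1) * bin_width, extent),
                    index_in_chrom=b,
                )
            )
    return bins


def merge_hotspot_bins(
    stats_list: list[SnpHotspotStat], bins: list[Bin], snps: list[SnpInfo]
) -> list[HotspotCall]:
    """Merge maximal runs of adjacent significant bins into hotspot calls.

    A bin is significant if it contains >= 1 Bonferroni-significant SNP;
    runs never cross chromosome boundaries. The peak SNP of a region is
    the significant SNP with the largest trans count (ties -> smallest
    position); the region's total is the sum over its significant SNPs.
    """
    by_chrom: dict[str, dict[int, Bin]] = {}
    for b in bins:
        by_chrom.setdefault(b.chrom, {})[b.index_in_chrom] = b
    # every non-terminal bin has the nominal width; terminal bins may be truncated
    width = max((b.end - b.start + 1 for b in bins), default=0)

    sig = [st for st in stats_list if st.significant]
    marked: dict[str, dict[int, list[SnpHotspotStat]]] = {}
    for st in sig:
        snp = snps[st.snp_index]
        chrom_bins = by_chrom.get(snp.chrom)
        idx = (snp.pos - 1) // max(width, 1) if chrom_bins else None
        if chrom_bins is None or idx not in chrom_bins:
            raise EqtlHotError(
                f"significant SNP {snp.id} at {snp.chrom}:{snp.pos} falls outside all bins"
            )
        marked.setdefault(snp.chrom, {}).setdefault(idx, []).append(st)

    calls: list[HotspotCall] = []
    chrom_order = list(dict.fromkeys(b.chrom for b in bins))
    for chrom in chrom_order:
        idxs = sorted(marked.get(chrom, {}))
        run: list[int] = []
        for i, idx in enumerate(idxs):
            run.append(idx)
            last = i == len(idxs) - 1 or idxs[i + 1] != idx + 1
            if last:
                members = [st for b in run for st in marked[chrom][b]]
                peak = min(
                    members, key=lambda st: (-st.trans_count, snps[st.snp_index].pos)
                )
                calls.append(
                    HotspotCall(
                        region=(chrom, by_chrom[chrom][run[0]].start, by_chrom[chrom][run[-1]].end),
                        bins_merged=len(run),
                        peak_snp=snps[peak.snp_index],
                        total_trans_eqtls=sum(st.trans_count for st in members),
                    )
                )
                run = []
    return calls


def assign_regulators(
    hotspot: HotspotCall,
    eqtls: list[EqtlCall],
    snps: list[SnpInfo],
    genes: list[GeneInfo],
) -> list[str]:
    """Putative regulators of a hotspot: unique gene ids that are cis
    targets of any SNP positioned inside the hotspot region, in genomic
    order (chromosome order of appearance in the gene table, then start).
    May be empty."""
    chrom, start, end = hotspot.region
    hits: set[int] = set()
    for c in eqtls:
        if not c.is_cis:
            continue
        snp = snps[c.snp_index]
        if snp.chrom == chrom and start <= snp.pos <= end:
            hits.add(c.gene_index)
    chrom_rank: dict[str, int] = {}
    for g in genes:
        chrom_rank.setdefault(g.chrom, len(chrom_rank))
    ordered = sorted(hits, key=lambda j: (chrom_rank[genes[j].chrom], genes[j].start))
    return [genes[j].id for j in ordered]


def run_hotspot_analysis(
    pm: PvalueMatrix, params: HotspotParams | None = None
) -> tuple[list[SnpHotspotStat], list[HotspotCall], dict]:
    """Full hotspot pipeline on a p-value matrix.

    Returns the per-SNP statistics, the merged hotspot calls (with
    regulators attached), and a summary dict with the genome-wide trans
    eQTL count ``n``, SNP count ``m``, Bonferroni threshold, bin count and
    one report row per hotspot.
    """
    params = params or HotspotParams()
    eqtls = call_eqtls(pm, params)
    m = pm.n_snps
    trans_counts = np.zeros(m, dtype=int)
    for c in eqtls:
        if not c.is_cis:
            trans_counts[c.snp_index] += 1
    stats_list = binomial_hotspot_test(trans_counts, m, params.alpha)

    extents: dict[str, int] = {}
    for s in pm.snps:
        extents[s.chrom] = max(extents.get(s.chrom, 0), s.pos)
    for g in pm.genes:
        extents[g.chrom] = max(extents.get(g.chrom, 0), g.end)
    bins = define_bins(extents, params.bin_width)
    calls = merge_hotspot_bins(stats_list, bins, pm.snps)
    for call in calls:
        call.regulators = assign_regulators(call, eqtls, pm.snps, pm.genes)
    calls.sort(key=lambda c: (list(extents).index(c.region[0]), c.region[1]))

    n_trans = int(trans_counts.sum())
    summary = {
        "n_eqtls": len(eqtls),
        "n_cis_eqtls": len(eqtls) - n_trans,
        "n_trans_eqtls": n_trans,
        "m_snps": m,
        "bonferroni_threshold": params.alpha / m,
        "n_bins": len(bins),
        "n_hotspots": len(calls),
        "hotspots": [
            {
                "index": i + 1,
                "location": c.peak_label,
                "region": f"{c.region[0]}:{c.region[1]}-{c.region[2]}",
                "bins_merged": c.bins_merged,
                "trans_eqtl_count": c.total_trans_eqtls,
                "binomial_p": next(
                    st.binomial_p
                    for st in stats_list
                    if pm.snps[st.snp_index].id == c.peak_snp.id
                ),
                "regulators": ", ".join(c.regulators),
            }
            for i, c in enumerate(calls)
        ],
    }
    logger.info(
        "hotspot analysis: n=%d trans eQTLs over m=%d SNPs -> %d hotspot(s)",
        n_trans, m, len(calls),
    )
    return stats_list, calls, summary


def write_hotspot_report(summary: dict, path) -> None:
    """Write the per-hotspot table as TSV (index, location, region,
    bins_merged, trans_eqtl_count, binomial_p, regulators)."""
    import pandas as pd

    cols = ["index", "location", "region", "bins_merged", "trans_eqtl_count", "binomial_p", "regulators"]
    pd.DataFrame(summary["hotspots"], columns=cols).to_csv(path, sep="\t", index=False)
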