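"""Diagnostic plots: the genome-wide eQTL map (SNP position x gene
position of every significant association) and the per-SNP linkage track
(trans-eQTL counts or mean -log10 p along the genome, with the hotspot
significance threshold as a dashed line).

Every plot function returns its data layer as a DataFrame alongside the
figure, so tests and downstream tools can assert on coordinates rather
than pixels. Files are written in both PNG and SVG.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .datatypes import GeneInfo, PvalueMatrix, SnpInfo
from .exceptions import InputError
from .hotspot import HotspotCall, SnpHotspotStat, min_significant_count

logger = logging.getLogger(__name__)


class GenomeLayout:
    """Maps (chrom, pos) to a single strictly monotone genome-wide axis.

    Chromosome order is the order of first appearance in the SNP table
    (genes append any chromosomes of their own afterwards); no
    natural-sort assumption is made on names.
    """

    def __init__(self, chrom_extents: dict[str, int]):
        self.chroms = list(chrom_extents)
        self.extents = dict(chrom_extents)
        self.offsets: dict[str, int] = {}
        off = 0
        for c in self.chroms:
            self.offsets[c] = off
            off += self.extents[c]
        self.total = off

    @classmethod
    def from_features(
        cls, snps: list[SnpInfo], genes: list[GeneInfo] | None = None
    ) -> "GenomeLayout":
        extents: dict[str, int] = {}
        for s in snps:
            extents[s.chrom] = max(extents.get(s.chrom, 0), s.pos)
        for g in genes or []:
            extents[g.chrom] = max(extents.get(g.chrom, 0), g.end)
        return cls(extents)

    def coord(self, chrom: str, pos: int) -> int:
        if chrom not in self.offsets:
            raise InputError(f"unknown chromosome {chrom!r}")
        return self.offsets[chrom] + pos

    def boundaries(self) -> list[int]:
        """Genome-axis coordinates of chromosome starts (for gridlines)."""
        return [self.offsets[c] for c in self.chroms]


def _save_both(fig, out_path: str | os.PathLike) -> list[Path]:
    base = Path(out_path)
    if base.suffix.lower() in (".png", ".svg"):
        base = base.with_suffix("")
    base.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for ext in (".png", ".svg"):
        p = base.with_suffix(ext)
        fig.savefig(p, dpi=120)
        paths.append(p)
    plt.close(fig)
    return paths


def plot_eqtl_map(
    pm: PvalueMatrix,
    threshold: float,
    out_path: str | os.PathLike,
    figsize: tuple[float, float] = (7.0, 7.0),
    color: str = "#1f4e9c",
) -> tuple[pd.DataFrame, list[Path]]:
    """Scatter every (SNP, gene) pair with ``p < threshold`` at (genome-x
    of the SNP, genome-y of the gene start); cis signals fall on the
    diagonal, trans hotspots show as vertical bands.

    Returns the point layer (snp_id, gene_id, x, y, pvalue) and the
    written file paths.
    """
    if not pm.annotated:
        raise InputError("p-value matrix lacks genomic annotations")
    if not (0 < threshold <= 1):
        raise InputError("threshold must be in (0, 1]")
    layout = GenomeLayout.from_features(pm.snps, pm.genes)
    si, gi = np.nonzero(pm.pvalues < threshold)
    points = pd.DataFrame(
        {
            "snp_id": [pm.snps[i].id for i in si],
            "gene_id": [pm.genes[j].id for j in gi],
            "x": [layout.coord(pm.snps[i].chrom, pm.snps[i].pos) for i in si],
            "y": [layout.coord(pm.genes[j].chrom, pm.genes[j].start) for j in gi],
            "pvalue": pm.pvalues[si, gi] if len(si) else np.array([]),
        }
    )
    fig, ax = plt.subplots(figsize=figsize)
    ax.scatter(points["x"], points["y"], s=6, c=color, alpha=0.7, linewidths=0)
    for b in layout.boundaries()[1:]:
        ax.axvline(b, color="0.85", lw=0.6, zorder=0)
        ax.axhline(b, color="0.85", lw=0.6, zorder=0)
    ax.set_xlim(0, layout.total)
    ax.set_ylim(0, layout.total)
    ax.set_xlabel("SNP position (genome-wide)")
    ax.set_ylabel("gene position (genome-wide)")
    ax.set_title(f"eQTL map (p < {threshold:g})")
    paths = _save_both(fig, out_path)
    logger.info("eQTL map with %d points -> %s", len(points), paths[0])
    return points, paths


def plot_linkage_track(
    snps: list[SnpInfo],
    values: np.ndarray,
    out_path: str | os.PathLike,
    threshold_line: float | None = None,
    hotspots: list[HotspotCall] | None = None,
    ylabel: str = "trans-eQTL count",
    figsize: tuple[float, float] = (9.0, 3.5),
    color: str = "#1f4e9c",
) -> tuple[pd.DataFrame, list[Path]]:
    """Per-SNP track along the genome axis with an optional dashed
    threshold line and hotspot index annotations above the peaks.

    Returns the track layer (snp_id, x, value) and the written paths.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(snps):
        raise InputError("one value per SNP required")
    layout = GenomeLayout.from_features(snps)
    xs = np.array([layout.coord(s.chrom, s.pos) for s in snps])
    track = pd.DataFrame({"snp_id": [s.id for s in snps], "x": xs, "value": values})
    fig, ax = plt.subplots(figsize=figsize)
    ax.vlines(xs, 0, values, color=color, lw=0.8)
    if threshold_line is not None:
        ax.axhline(threshold_line, color="red", ls="--", lw=1.0)
    for b in layout.boundaries()[1:]:
        ax.axvline(b, color="0.85", lw=0.6, zorder=0)
    if hotspots:
        pos = {s.id: x for s, x in zip(snps, xs)}
        top = max(values.max() if len(values) else 1.0, 1.0)
        for i, h in enumerate(hotspots, start=1):
            x = pos.get(h.peak_snp.id, layout.coord(h.region[0], h.region[1]))
            ax.annotate(
                str(i), (x, top * 1.02), ha="center", fontsize=8, color="black"
            )
    ax.set_xlim(0, layout.total)
    ax.set_xlabel("genome position")
    ax.set_ylabel(ylabel)
    paths = _save_both(fig, out_path)
    return track, paths


def trans_count_track(stats_list: list[SnpHotspotStat]) -> np.ndarray:
    """Per-SNP trans-eQTL counts in SNP order."""
    return np.array([st.trans_count for st in stats_list], dtype=float)


def mean_neglog10_track(pm: PvalueMatrix, floor: float = 1e-300) -> np.ndarray:
    """Per-SNP average of -log10 p over genes (the alternative y-axis of
    the linkage plot; ~0.434 per SNP under a uniform null)."""
    return (-np.log10(np.maximum(pm.pvalues, floor))).mean(axis=1)


def hotspot_threshold_line(n_trans: int, m: int, alpha: float) -> float:
    """Y-position of the dashed significance line on the count track: the
    smallest trans count that is Bonferroni-significant."""
    return float(min_significant_count(n_trans, m, alpha))
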