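"""Readers and writers for the three genotype input formats and for
tab-delimited p-value matrices and annotation tables.

Conventions
-----------
* PLINK binary: ``dosage`` counts copies of the **A1** allele (the first
  allele column of the .bim), matching PLINK's minor-allele-first dialect;
  ``SnpInfo.ref_allele`` is A2 and ``alt_allele`` is A1. Fixtures written
  by this package use A1 = the VCF ALT allele, so the three serializations
  of one cohort decode to identical dosage matrices.
* VCF: ``dosage`` counts ALT alleles in GT (``0/1`` -> 1, ``1/1`` -> 2,
  haploid ``1`` -> 1, ``./.`` or ``.`` -> missing).
* Plain matrices: tab-delimited, feature rows x sample columns, first
  column feature ids, header row sample ids; annotations are keyed by
  feature id (SNPs: id/chrom/pos/ref/alt, genes: id/chrom/start/end).
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionData, GeneInfo, GenotypeData, PvalueMatrix, SnpInfo
from .exceptions import FormatError, InputError

logger = logging.getLogger(__name__)

_BED_MAGIC = (0x6C, 0x1B)
# 2-bit PLINK genotype code -> copies of A1: 00 -> 2, 01 -> missing, 10 -> 1, 11 -> 0
_BED_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


# ---------------------------------------------------------------------------
# binary PLINK
# ---------------------------------------------------------------------------


def read_plink_binary(prefix: str | os.PathLike, ploidy: int = 2) -> GenotypeData:
    """Read a binary PLINK fileset ``prefix``.bed/.bim/.fam.

    The .bed must be in SNP-major mode (third byte 0x01). Sample ids come
    from .fam column 2 (IID); SNP metadata from the .bim, with
    ``alt_allele`` = A1 (the counted allele) and ``ref_allele`` = A2.
    """
    prefix = Path(prefix)
    paths = {ext: prefix.with_suffix(f".{ext}") for ext in ("bed", "bim", "fam")}
    for ext, p in paths.items():
        if not p.exists():
            raise InputError(f"missing PLINK file: {p}")

    fam = pd.read_csv(paths["fam"], sep=r"\s+", header=None, dtype=str)
    if fam.shape[1] < 2:
        raise FormatError(f"{paths['fam']}: expected >= 2 columns")
    samples = fam.iloc[:, 1].tolist()

    bim = pd.read_csv(
        paths["bim"],
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    snps = [
        SnpInfo(id=r.id, chrom=r.chrom, pos=int(r.pos), ref_allele=r.a2, alt_allele=r.a1)
        for r in bim.itertuples()
    ]

    raw = np.fromfile(paths["bed"], dtype=np.uint8)
    if len(raw) < 3 or raw[0] != _BED_MAGIC[0] or raw[1] != _BED_MAGIC[1]:
        raise FormatError(f"{paths['bed']}: bad magic bytes (not a PLINK .bed file)")
    if raw[2] != 0x01:
        raise FormatError(f"{paths['bed']}: not in SNP-major mode")
    n_samples, n_snps = len(samples), len(snps)
    bytes_per_snp = (n_samples + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_snp * n_snps:
        raise FormatError(
            f"{paths['bed']}: {len(body)} data bytes, expected "
            f"{bytes_per_snp * n_snps} for {n_samples} samples x {n_snps} SNPs"
        )
    # unpack 2-bit codes, low bits first within each byte
    mat = body.reshape(n_snps, bytes_per_snp)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (mat[:, :, None] >> shifts) & 0b11  # (snps, bytes, 4)
    codes = codes.reshape(n_snps, bytes_per_snp * 4)[:, :n_samples]
    dosage = _BED_CODE_TO_DOSAGE[codes].T.copy()  # (samples, snps)
    return GenotypeData(samples=samples, snps=snps, dosage=dosage, ploidy=ploidy)


def write_plink_binary(geno: GenotypeData, prefix: str | os.PathLike) -> None:
    """Write ``geno`` as a binary PLINK fileset (SNP-major .bed).

    Haploid cohorts (ploidy 1) are encoded with the heterozygote code for
    dosage 1 so that the round trip is exact; PLINK tools would instead use
    homozygote codes, but the .bed container itself is agnostic.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in geno.samples:
            fh.write(f"{s} {s} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for s in geno.snps:
            fh.write(f"{s.chrom}\t{s.id}\t0\t{s.pos}\t{s.alt_allele}\t{s.ref_allele}\n")

    n_samples = geno.n_samples
    bytes_per_snp = (n_samples + 3) // 4
    # dosage -> 2-bit code: 0 -> 11, 1 -> 10, 2 -> 00, NaN -> 01
    dosage = geno.dosage.T  # (snps, samples)
    codes = np.full(dosage.shape, 0b01, dtype=np.uint8)
    codes[dosage == 0] = 0b11
    codes[dosage == 1] = 0b10
    codes[dosage == 2] = 0b00
    pad = bytes_per_snp * 4 - n_samples
    if pad:
        codes = np.pad(codes, ((0, 0), (0, pad)), constant_values=0b11)
    codes = codes.reshape(geno.n_snps, bytes_per_snp, 4)
    packed = (
        codes[:, :, 0]
        | (codes[:, :, 1] << 2)
        | (codes[:, :, 2] << 4)
        | (codes[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(bytes([_BED_MAGIC[0], _BED_MAGIC[1], 0x01]))
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str | os.PathLike, strict_biallelic: bool = True) -> GenotypeData:
    """Read GT dosages from a VCF 4.x file (plain or bgzipped).

    Multiallelic records raise :class:`FormatError` in strict mode and are
    skipped (with a warning) otherwise.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise InputError(f"missing VCF file: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on garbage
        raise FormatError(f"{path}: not a readable VCF ({exc})") from exc
    samples = list(vcf.samples)
    snps: list[SnpInfo] = []
    cols: list[np.ndarray] = []
    max_dose = 0.0
    for v in vcf:
        if len(v.ALT) != 1:
            msg = f"multiallelic record at {v.CHROM}:{v.POS} ({v.REF}->{v.ALT})"
            if strict_biallelic:
                raise FormatError(msg)
            logger.warning("skipping %s", msg)
            continue
        gts = v.genotypes  # per sample: [a1, a2, phased] or [a, phased]
        if gts is None:
            raise FormatError(f"{path}: record {v.CHROM}:{v.POS} has no GT field")
        dose = np.empty(len(samples))
        for i, g in enumerate(gts):
            alleles = g[:-1]
            if any(a < 0 for a in alleles):
                dose[i] = np.nan
            else:
                dose[i] = float(sum(alleles))
        max_dose = max(max_dose, np.nanmax(dose) if len(dose) else 0.0)
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        snps.append(
            SnpInfo(id=vid, chrom=v.CHROM, pos=v.POS, ref_allele=v.REF, alt_allele=v.ALT[0])
        )
        cols.append(dose)
    dosage = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0))
    )
    ploidy = 1 if max_dose <= 1 else 2
    return GenotypeData(samples=samples, snps=snps, dosage=dosage, ploidy=ploidy)


def write_vcf(geno: GenotypeData, path: str | os.PathLike) -> None:
    """Write ``geno`` as a minimal plain-text VCF 4.2 with GT only."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    chroms: list[str] = []
    max_pos: dict[str, int] = {}
    for s in geno.snps:
        if s.chrom not in max_pos:
            chroms.append(s.chrom)
        max_pos[s.chrom] = max(max_pos.get(s.chrom, 0), s.pos)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=eqtlhot\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c},length={max_pos[c] + 1000}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        for j, s in enumerate(geno.snps):
            if geno.ploidy == 1:
                gts = [
                    "." if np.isnan(d) else str(int(d)) for d in geno.dosage[:, j]
                ]
            else:
                conv = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
                gts = [
                    "./." if np.isnan(d) else conv[d] for d in geno.dosage[:, j]
                ]
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.id}\t{s.ref_allele}\t{s.alt_allele}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# plain tab-delimited matrices + annotations
# ---------------------------------------------------------------------------


def _read_feature_matrix(path: Path, kind: str) -> pd.DataFrame:
    if not path.exists():
        raise InputError(f"missing {kind} matrix: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    for ci, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            ri = int(np.nonzero(bad.to_numpy())[0][0])
            raise FormatError(
                f"{path}: non-numeric cell at row {df.index[ri]!r} "
                f"(line {ri + 2}), column {col!r} (column {ci + 2})"
            )
        df[col] = coerced
    return df


def read_snp_annotation(path: str | os.PathLike) -> dict[str, SnpInfo]:
    """Read a SNP annotation table (columns: id, chrom, pos[, ref, alt])."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"missing SNP annotation: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    for col in ("id", "chrom", "pos"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    out = {}
    for r in df.itertuples():
        out[r.id] = SnpInfo(
            id=r.id,
            chrom=r.chrom,
            pos=int(r.pos),
            ref_allele=getattr(r, "ref", "N"),
            alt_allele=getattr(r, "alt", "N"),
        )
    return out


def read_gene_annotation(path: str | os.PathLike) -> dict[str, GeneInfo]:
    """Read a gene annotation table (columns: id, chrom, start, end)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"missing gene annotation: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    for col in ("id", "chrom", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return {
        r.id: GeneInfo(id=r.id, chrom=r.chrom, start=int(r.start), end=int(r.end))
        for r in df.itertuples()
    }


def read_plain_matrices(
    genotype_path: str | os.PathLike,
    expression_path: str | os.PathLike,
    snp_annot_path: str | os.PathLike,
    gene_annot_path: str | os.PathLike,
    ploidy: int = 2,
) -> tuple[GenotypeData, ExpressionData]:
    """Read the plain tab-delimited dialect (feature rows x sample columns).

    Sample columns are aligned to the intersection of the two matrices'
    headers, keeping genotype-file order; the number of dropped samples is
    logged. Features absent from their annotation table raise
    :class:`InputError` naming the id.
    """
    gdf = _read_feature_matrix(Path(genotype_path), "genotype")
    edf = _read_feature_matrix(Path(expression_path), "expression")
    snp_annot = read_snp_annotation(snp_annot_path)
    gene_annot = read_gene_annotation(gene_annot_path)

    for sid in gdf.index:
        if sid not in snp_annot:
            raise InputError(f"SNP {sid!r} not present in annotation {snp_annot_path}")
    for gid in edf.index:
        if gid not in gene_annot:
            raise InputError(f"gene {gid!r} not present in annotation {gene_annot_path}")

    common = [s for s in gdf.columns if s in set(edf.columns)]
    if not common:
        raise InputError("genotype and expression matrices share no sample columns")
    dropped = (len(gdf.columns) - len(common)) + (len(edf.columns) - len(common))
    if dropped:
        logger.info("plain-matrix alignment dropped %d sample column(s)", dropped)

    geno = GenotypeData(
        samples=common,
        snps=[snp_annot[sid] for sid in gdf.index],
        dosage=gdf[common].to_numpy(dtype=float).T,
        ploidy=ploidy,
    )
    expr = ExpressionData(
        samples=common,
        genes=[gene_annot[gid] for gid in edf.index],
        values=edf[common].to_numpy(dtype=float).T,
    )
    return geno, expr


def write_plain_matrices(
    geno: GenotypeData, expr: ExpressionData, out_dir: str | os.PathLike
) -> dict[str, Path]:
    """Write a cohort in the plain dialect; returns the path of each file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotype": out / "genotype_matrix.tsv",
        "expression": out / "expression_matrix.tsv",
        "snp_annot": out / "snp_annotation.tsv",
        "gene_annot": out / "gene_annotation.tsv",
    }
    pd.DataFrame(
        geno.dosage.T, index=[s.id for s in geno.snps], columns=geno.samples
    ).to_csv(paths["genotype"], sep="\t", index_label="snp_id")
    pd.DataFrame(
        expr.values.T, index=[g.id for g in expr.genes], columns=expr.samples
    ).to_csv(paths["expression"], sep="\t", index_label="gene_id")
    pd.DataFrame(
        [
            {"id": s.id, "chrom": s.chrom, "pos": s.pos, "ref": s.ref_allele, "alt": s.alt_allele}
            for s in geno.snps
        ]
    ).to_csv(paths["snp_annot"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"id": g.id, "chrom": g.chrom, "start": g.start, "end": g.end}
            for g in expr.genes
        ]
    ).to_csv(paths["gene_annot"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# p-value matrix
# ---------------------------------------------------------------------------


def write_pvalue_matrix(pm: PvalueMatrix, path: str | os.PathLike) -> None:
    """Write SNP rows x gene columns, full-precision scientific notation."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        pm.pvalues, index=[s.id for s in pm.snps], columns=[g.id for g in pm.genes]
    ).to_csv(path, sep="\t", index_label="snp_id", float_format="%.17e")


def read_pvalue_matrix(
    path: str | os.PathLike,
    snps: dict[str, SnpInfo] | None = None,
    genes: dict[str, GeneInfo] | None = None,
) -> PvalueMatrix:
    """Read a p-value matrix written by :func:`write_pvalue_matrix`.

    When annotation mappings are supplied, every row/column id must resolve
    and the result carries full genomic metadata (``annotated=True``);
    without them placeholder metadata is attached and the matrix can only
    be used for operations that ignore positions.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"missing p-value matrix: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "snp_id":
        raise FormatError(f"{path}: malformed header (first column must be 'snp_id')")
    vals = df.to_numpy(dtype=float)
    if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
        raise InputError(f"{path}: p-values outside [0, 1]")
    annotated = snps is not None and genes is not None
    if annotated:
        for sid in df.index:
            if sid not in snps:  # type: ignore[operator]
                raise InputError(f"SNP {sid!r} missing from annotation")
        for gid in df.columns:
            if gid not in genes:  # type: ignore[operator]
                raise InputError(f"gene {gid!r} missing from annotation")
        snp_list = [snps[sid] for sid in df.index]  # type: ignore[index]
        gene_list = [genes[gid] for gid in df.columns]  # type: ignore[index]
    else:
        snp_list = [SnpInfo(id=str(sid), chrom="?", pos=1) for sid in df.index]
        gene_list = [GeneInfo(id=str(gid), chrom="?", start=1, end=1) for gid in df.columns]
    return PvalueMatrix(snps=snp_list, genes=gene_list, pvalues=vals, annotated=annotated)
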