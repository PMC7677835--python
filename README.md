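# eqtlhot

Trans-eQTL **regulatory hotspot** detection: a library and command-line
tool for finding genetic loci whose variants are associated with the
expression of unusually many distant genes.

Expression QTL (eQTL) panels — e.g. a yeast cross with ~1000 haploid
segregants typed at tens of thousands of SNPs and assayed for thousands
of transcripts — often show "hotspot" loci linked to hundreds of genes
in *trans*. Many such hotspots are artifacts: shared non-genetic
structure among samples (batches, culture conditions, technical drift)
correlates whole expression profiles with each other, and any variant
that happens to align with that structure appears to regulate hundreds
of genes at once. `eqtlhot` addresses this with an intersample-correlation
corrected association scan followed by a binomial enrichment test per
SNP.

## Method

**Association scan.** For each gene *y* and SNP dosage *x*, the plain
(`ols`) scan fits *y = a + b·x* and reports the two-sided p-value of the
*t* statistic for *b* (df = *n* − 2). The corrected (`emended`) scan is
an EMMAX-style mixed model: the sample correlation matrix *K* is
estimated from the expression matrix itself (genes standardized,
*K* = *EEᵀ*/*G*, unit diagonal, clipped to PSD), each gene's
residual-to-structured variance ratio δ is fitted once by REML under
*V* = σ²(*K* + δ*I*), and every SNP is then tested by generalized least
squares under that *V*. The scan runs in deterministic parallel chunks
over SNPs: output is bit-identical for any worker count or chunk size.

**Hotspot test.** eQTLs are the (SNP, gene) pairs with *p* < 5×10⁻⁵
(strict); pairs within 10 kb on the same chromosome are *cis*, the rest
*trans*. With *n* trans eQTLs genome-wide over *m* SNPs, each SNP's
trans count *kᵢ* is referred to Binomial(*n*, 1/*m*): its p-value is
P(X ≥ *kᵢ*), Bonferroni-significant when below 0.05/*m*. Significant
SNPs are mapped into 20-kb genome bins; adjacent significant bins merge
into one hotspot region, reported with its peak SNP
(`chrom:pos_ref/alt`), total trans-eQTL count and putative regulators —
the *cis*-eQTL target genes of SNPs inside the region.

All thresholds (5×10⁻⁵, 10 kb, 20 kb, 0.05) are defaults and can be
changed via `HotspotParams` or CLI flags.

## Worked example

The built-in simulator generates a full synthetic cohort (PLINK
bed/bim/fam + VCF + plain matrices + a truth table), here with one
hotspot SNP driving 50 genes in trans and one cis effect:

```bash
eqtlhot simulate --out-dir demo/fixtures --seed 42 \
    --n-samples 300 --n-snps 200 --n-genes 200 \
    --hotspot 25:50:1.0 --cis 26:3:1.2

eqtlhot scan --format plink --genotypes demo/fixtures/genotypes \
    --expression demo/fixtures/expression_matrix.tsv \
    --gene-annot demo/fixtures/gene_annotation.tsv \
    --method ols --workers 2 --ploidy 1 --out-dir demo/scan

eqtlhot hotspots --pvalues demo/scan/pvalues.tsv \
    --snp-annot demo/fixtures/snp_annotation.tsv \
    --gene-annot demo/fixtures/gene_annotation.tsv \
    --out-dir demo/hotspots
```

which prints `1 hotspot(s)` and writes `demo/hotspots/hotspots.tsv`:

```
index  location         region            bins_merged  trans_eqtl_count  binomial_p              regulators
1      chr1:26000_A/G   chr1:20001-40000  1            50                1.1662065757533937e-112  gene3
```

Reading the row: of 53 eQTL calls (52 trans, 1 cis), all 50 planted
trans targets concentrate on the planted SNP at chr1:26000; under the
null of *n* = 52 trans eQTLs spread uniformly over *m* = 200 SNPs, a
count of 50 has binomial survival probability ≈ 10⁻¹¹², far below the
Bonferroni bar of 0.05/200 = 2.5×10⁻⁴, so its 20-kb bin is called a
hotspot, and the cis-eQTL gene inside the region (`gene3`) is reported
as the putative regulator. The output directory also contains the
genome-wide eQTL map and the per-SNP linkage track (PNG + SVG) with the
significance threshold drawn as a dashed line.

`eqtlhot hotspots` also accepts any user-supplied SNP × gene p-value
table in the same TSV layout.

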