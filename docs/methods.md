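# Methods

## The statistical model

### Association scan

For gene expression vector *y* (length *n* samples) and SNP dosage *x*
(alt-allele copies, 0–1 haploid or 0–2 diploid, missing calls
mean-imputed per SNP), both scan methods test the slope in
*y = a + b·x*.

* **`ols`** — ordinary least squares; exact *t* test with *n* − 2 df.
* **`emended`** — a two-stage mixed model in the EMMAX tradition:

  1. *Sample correlation.* Genes are standardized to mean 0, variance 1
     across samples; *K*raw = *EEᵀ*/*G*; *K* is *K*raw rescaled to unit
     diagonal, with negative eigenvalues clipped to zero and the
     diagonal re-normalized. *K* captures whatever makes whole samples
     resemble each other — batch structure, shared technical factors,
     relatedness — without needing those factors to be named.
  2. *Per-gene variance components.* Under
     *V* = σ²(*K* + δ*I*), δ (the ratio of independent residual variance
     to structured variance) is estimated once per gene by restricted
     maximum likelihood on the spectrum of *SKS* (*S* the centering
     projection, which adjusts for the intercept). The REML profile is
     evaluated on an 81-point log grid over [10⁻⁵, 10⁵] and refined by
     bounded scalar minimization in log δ (xatol 10⁻¹⁰), making the
     estimate deterministic. A flat profile (range < 10⁻⁸ relative),
     which occurs exactly when *K* carries no information against *I*
     (e.g. *K* = *I*), flags the gene "unstructured" and the scan falls
     back to OLS for it.
  3. *GLS test.* With δ fixed, every SNP is tested by generalized least
     squares under *V* = *K* + δ*I*, implemented by rotating into *K*'s
     eigenbasis and weighting by 1/(*sᵢ* + δ) — algebraically identical
     to Cholesky whitening (verified against that oracle to ~10⁻¹⁴).
     The statistic is the slope *t* ratio with *n* − 2 df, an exact test
     under OLS and the standard approximation under GLS with estimated
     δ. Constant SNPs get *p* = 1.

Per-gene (rather than per-SNP-per-gene) δ estimation is what makes a
42k-SNP × 5.7k-gene scan tractable; the resulting p-values are
score-style approximations, standard for this model class.

### Determinism and parallelism

SNPs are partitioned into contiguous chunks dispatched to joblib
workers and reassembled by chunk index. Three implementation rules make
the output bit-identical for every worker count *and* chunk size: all
basis rotations (*UᵀX*, *UᵀY*) happen once in the parent before
chunking; per-column reductions inside chunks use einsum rather than
BLAS gemv (whose accumulation order varies with operand width); and
BLAS thread pools are pinned to one thread inside chunk computation.

### Hotspot detection

Let *m* be the number of SNPs scanned and call each (SNP, gene) pair
with *p* strictly below the eQTL threshold an eQTL; a pair is *cis*
when SNP and gene are on the same chromosome and the SNP lies within
the cis window of the gene body (distance 0 inside the body; the
boundary is inclusive), otherwise *trans*. cis eQTLs are excluded
symmetrically from both the genome-wide total *n* and the per-SNP
counts *kᵢ*, so the binomial null and the observed counts draw from the
same event set. The per-SNP p-value is P(X ≥ *kᵢ*) for
X ~ Binomial(*n*, 1/*m*), evaluated by the survival function at
*kᵢ* − 1; significance is Bonferroni at α/*m*, strict inequality at
both thresholds. Significant SNPs are mapped into fixed-width bins
([1, w], [w+1, 2w], … per chromosome, last bin truncated at the data
extent); maximal runs of adjacent significant bins merge into one
hotspot, never across chromosomes. The peak SNP is the significant SNP
with the largest trans count (ties: smallest position, since a report
needs one representative row). Regulators are the unique cis-eQTL
target genes of SNPs positioned inside the merged region, in genomic
order; a hotspot with no cis gene is retained with an empty list.

Chromosome extents are inferred from the data maxima (the largest SNP
position or gene end per chromosome) rather than from a reference
genome, so bin counts depend on the input.

### Defaults and units

| parameter | default | meaning |
|---|---|---|
| `eqtl_threshold` | 5×10⁻⁵ | per-pair eQTL call threshold (strict `<`) |
| `cis_window` | 10 000 bp | SNP-to-gene-body distance for cis |
| `bin_width` | 20 000 bp | genome bin width for merging/reporting |
| `alpha` | 0.05 | family-wise level, Bonferroni-divided by *m* |

## The synthetic-data generator

`simulate` produces cohorts shaped like an organism-cross eQTL panel:
haploid dosages by default (diploid supported), independent biallelic
SNPs with MAF ~ Uniform(0.1, 0.5), evenly spaced at 1 kb over a
configurable number of chromosomes; genes spread evenly over the same
chromosomes. Expression is a sum of planted cis effects, planted
hotspot effects (one SNP, many trans targets), a low-rank confounder
term, optional batch shifts, and Gaussian noise (sd 1). Effects
multiply the *standardized* dosage, so power is MAF-independent: a
standardized effect β against noise sd 1 gives per-target noncentrality
≈ β√n (β = 1, n = 300 → *t* ≈ 17, hence essentially certain recovery at
5×10⁻⁵). Cis-pair genes are relocated next to their SNP; hotspot
targets are drawn only from genes outside the SNP's cis window. All
randomness flows from the mandatory seed.

**What it does not emulate:** linkage disequilibrium or recombination
maps (SNPs are independent), count-based RNA-seq noise, epistasis, or
polygenic backgrounds. Passing tests therefore demonstrate the
statistical machinery under clean conditions, not robustness to LD
structure or heavy-tailed expression noise.

### The confounded-null scenario

The confounder term is Λ·F/√k scaled by `confounder_strength`, with
per-sample factor scores F and N(0,1) loadings. Factor scores can be
partially aligned with randomly chosen "anchor" SNPs
(`confounder_geno_corr` = correlation ρ between a factor and the
anchor's standardized dosage). This matters because with factors fully
independent of genotype, per-test OLS p-values remain marginally
calibrated; at desk-scale SNP counts the expected maximum
SNP-confounder correlation (z ≈ √(2 ln m) ≈ 3.7 for a few hundred SNPs)
sits below the z ≈ 4.1 needed to cross 5×10⁻⁵, so spurious hotspots
essentially never form. Real spurious hotspots arise when technical or
batch structure is itself aligned with genotype (samples processed in
family or plate groups); the anchor mechanism models that regime
directly. The confounded-null preset uses three factors at strength 3,
ρ = 0.8, in an 80-sample, 300-SNP, 300-gene cohort: there the plain
scan's failure mode (the anchor SNP appearing to regulate tens to
hundreds of genes) occurs essentially every replicate, while the
corrected scan suppresses most of it. This sizing came from an explicit
operating-characteristics analysis of the design, not from matching any
particular dataset.

### Residual leakage of the corrected scan

The correction is real but not complete. *K* is estimated from the same
finite expression matrix, so its top eigenvectors miss the true factor
span by a small angle; the unexplained sliver of a genotype-aligned
factor lands in *K*'s near-null bulk directions, which the GLS weights
1/(*sᵢ* + δ) actually *up*-weight. Both the anchor dosage and
high-loading genes retain that same sliver, so a strongly
genotype-aligned factor (ρ√n ≈ 7 in the preset) can still leave a
significant residual association in a fraction of replicates. The
contrast with OLS remains large (roughly 3× fewer spurious hotspots per
replicate and a reliably smaller replicate count in head-to-head runs),
which is the property the pipeline claims. Mitigations such as
including top expression PCs as fixed covariates, or estimating *K*
leaving out the tested chromosome, are deliberately out of scope.

A converse limitation: a *genuine* hotspot whose targets are a large
fraction of all genes is itself a low-rank expression factor, so the
corrected scan partially absorbs it into *K* and loses power for it
(visible in small cohorts where one SNP drives 30% of genes). This is
intrinsic to expression-derived covariance. The planted-recovery
benchmark therefore exercises the pipeline with the OLS scan, which its
no-confounding design makes exact.

## Benchmark problem sizes

Chosen to keep each block well-powered while remaining desk-scale:
binomial oracle on 200 random (n ≤ 5000, m ≤ 50 000) triples, with the
oracle computed by exact rational pmf summation (truncation error
< 10⁻²⁵); GLS-vs-whitening on 50 random problems with n ≤ 100; null
calibration on a 100 × 200 × 100 cohort (20 000 p-values: binomial sd
of the 0.05 exceedance fraction ≈ 0.0015, typical KS ≈ 0.01); hotspot
family-wise error on 100 replicates of 1000 × 100 uniform matrices
(expected ~5 trans calls per replicate; the probability that ≥2 of them
collide on one SNP — the only way a null hotspot forms — is ≈ 1%);
planted recovery over 20 seeds at n = 300 with 50 targets of 200 genes;
the confounding contrast over 10 seeds of the preset above.

## Numerical notes and degenerate inputs

* Negative eigenvalues of *K*raw (guaranteed when genes < samples) are
  clipped, then the diagonal re-normalized; REML spectra are clipped at
  zero and δ ≥ 10⁻⁵ keeps all weights finite.
* Constant genes are dropped with a warning (also after covariate
  residualization); constant SNPs score *p* = 1; a scan with < 4
  samples, no genes, or no SNPs is refused.
* *n* = 0 trans eQTLs yields all binomial p-values 1 with a warning.
* Missing dosages are mean-imputed per SNP immediately before testing;
  missingness remains available on the genotype container.
* Haploid cohorts are written to PLINK .bed using the heterozygote code
  for dosage 1, so all three serializations of one cohort decode to the
  identical dosage matrix; PLINK's own tools would use homozygote codes
  for haploids, which a consumer of our fixtures should know.
* p-value TSVs are written at 17 significant digits; round trips are
  lossless to < 10⁻¹² relative error.
* Chromosome names are opaque strings; ordering everywhere is order of
  first appearance in the SNP table (genes append theirs after), with
  no natural-sort assumptions.
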