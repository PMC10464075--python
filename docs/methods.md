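# Methods

## Growth response surface

Weight gain rate over a culture interval is
`WGR (%) = (Wt − W0)/W0 × 100`; negative values (weight loss at high
temperature) are valid. The response surface is the full second-order
polynomial in shell diameter `D` and temperature `T` with terms
`(1, D, T, DT, D², T²)`, fitted by ordinary least squares
(`statsmodels.OLS`); the model object carries the six coefficients, R²,
the overall F statistic and its p-value. Fitting accepts raw per-tank
records or per-(D, T)-cell means (`aggregate_cells=True`); the drivers
fit raw records.

Derived quantities assume concavity in `T` (β5 < 0):

- optimal temperature at fixed diameter: the closed-form stationary point
  `T_opt = (β2 + β3·D)/(−2·β5)`; the implementation asserts agreement
  with a numeric maximizer in tests;
- maximum WGR: the surface value at `T_opt`;
- growth-limit temperature: the larger real root of `WGR(D, T) = 0` by
  the quadratic formula, required to exceed `T_opt`; raises when the
  surface never reaches zero from a positive peak.

Reported values are rounded to 1 decimal for temperatures and 2 decimals
for WGR percentages. The per-diameter optimum is deliberately the
stationary point in `T` at fixed `D`, not a joint (D, T) optimum.

**Known discrepancy.** The sea-urchin study that motivates the default
coefficients reported per-diameter optimal temperatures of 16.1 / 15.4 /
13.6 °C for 2 / 4 / 6 cm animals, but the stationary points of its own
published equation are 15.14 / 15.24 / 15.35 °C. The source of the 2 cm
and 6 cm values is not reconstructible from the published coefficients
(plausibly a GUI optimizer on an unrounded internal model), so this
package does not attempt to reproduce them: it computes stationary points
and exposes the comparison as `growth.printed_optimum_discrepancy()`,
which the pipeline writes and logs on every run.

## Count engine

All three differential analyses (methylation sites, gene-level
methylation sums, RNA-seq) share one engine rather than three separate
tools, so contracts and calibration are tested once.

**Normalization.** Median-of-ratios size factors against the per-feature
geometric-mean reference, computed over features with all-positive
counts. When fewer than 50 such features exist in a realistically sized
matrix, upper-quartile scaling (quartiles rescaled to geometric mean 1)
is used instead, which tolerates sparse matrices. Size factors are a
relative scale: statements like "scaling a sample by c scales its factor
by c" hold as ratios between samples.

**Dispersion.** A single common NB dispersion φ (variance = μ + φμ²) is
estimated by method of moments from within-group means and variances of
normalized counts: pooling features, `φ = Σ(v − m·mean(1/s)) / Σ m²`,
clamped at zero. With three samples per group, per-feature dispersion
estimates would be dominated by noise; a common φ is the deliberate
simplification, and simulation tests verify recovery (φ=0.2 estimated
within [0.1, 0.3] at 2,000 features) and type-I calibration.

**Exact test.** Two-group comparison conditions on the integer total of
the two group sums. Each group sum is modelled as NB with mean
proportional to its summed size factors and dispersion
`φ·Σs_j²/(Σs_j)²` (exactly φ/n for equal factors), which matches the
mean and variance of the sum of the per-sample NB counts; the sum is not
exactly NB when size factors differ, an approximation shared with
classic exact-test implementations. The two-sided p doubles the smaller
tail of the conditional split distribution, capped at 1. φ = 0
degenerates to the exact binomial/Poisson split. For large totals the
split is enumerated over a ±12-sd window around the conditional mean
(excluded mass < 1e−20). The fold change is
`log2((mean normalized treatment + 0.5)/(mean normalized control + 0.5))`;
the 0.5 pseudocount affects reporting only, never the test.

**Multiple testing.** Benjamini–Hochberg step-up, implemented directly
and cross-checked against `statsmodels.stats.multitest` on random
vectors. Site-level and gene-level methylation screens use raw p < 0.05
(with FDR available via a flag); expression uses q < 0.05. All screens
additionally require |log2FC| > 1.

## Annotation and metagene profiles

Coordinates are 0-based half-open internally; GFF3 (1-based closed) is
converted on parse via gffutils, BED12 blocks are expanded directly. Per
gene, strand-aware regions are: promoter = 2 kb upstream of the TSS
(clipped at chromosome edges), gene body = the gene span (exons plus
derived introns), downstream = 2 kb past the TTS. Site labels follow the
priority promoter > exon > intron > downstream > intergenic, while every
covering gene is recorded with its own element so gene-level aggregation
can filter by scope. "Whole-gene" aggregation scope means the gene body;
promoter scope means promoter sites only. A site inside two genes'
regions contributes to both genes' sums.

Metagene profiles use 20 upstream bins of 100 bp, 60 proportionally
scaled gene-body bins, and 20 downstream bins of 100 bp, strand-aware
(upstream is always 5′). Genes shorter than the number of body bins are
skipped with a warning. Profile mass equals the summed signal of covered
sites when gene windows do not overlap; overlapping windows each count a
shared site once.

## Conjoint analysis

"Promoter DMG" means the gene-level methylation screen run on
promoter-scope sums — chosen because the conjoint question is about
promoter methylation; whole-gene scope remains available. The quadrant
label comes from the fold-change sign pair, the association (positive /
negative) from their product; a zero log2FC cannot pass the |log2FC| > 1
screens, so ties are asserted impossible rather than handled. Per-gene
Pearson correlation between promoter methylation and FPKM across the six
samples is attached as supplementary evidence; genes with zero variance
are flagged `r_defined=False` rather than dropped.

## Enrichment and qPCR

Term enrichment: upper-tail hypergeometric p per term (scipy), BH q over
all terms with any universe overlap (so the min-gene filter commutes
with testing), ranked by −log10(p) with term-id tie-break. The "more
than two genes" screening rule is read strictly (k > 2) with k ≥ min
available via `strict=False`. The universe defaults to the genes present
in the expression matrix.

qPCR: primer efficiency `E = (10^(−1/slope) − 1)×100` with the 90–105 %
acceptance window; relative quantification by 2^−ΔΔCt with replicate Ct
values averaged before the delta steps and replicate SDs propagated in
quadrature on the log2 scale. Efficiency-corrected (Pfaffl)
quantification is out of scope.

## Synthetic data

The generators emulate the study design the analysis assumes: two groups
(control vs high temperature) of three pooled samples; ~20,000 CG and
~1,800 CWG sites (the ~11:1 context ratio of the real site catalogue at
1/34 scale) at mean depth 10 with NB dispersion 0.2; 2,000
non-overlapping gene models (1–8 exons, ~1–20 kb) on ten 4 Mb
chromosomes; per-sample library-scale multipliers (log-normal, sd 0.15);
planted promoter-methylation shifts of |log2FC| = 2 covering ~10 % of
promoter sites, gene-wise with random sign; planted expression shifts of
|log2FC| = 2 in ~10 % of genes; and 8 positively plus 7 negatively
methylation-coupled genes whose expression shift sign is tied to their
CG promoter-methylation shift (the coupled-set sizes mirror the scale of
a published CG quadrant map). Coupling acts on the NB mean, keeping
count marginals valid. The growth generator draws per-tank WGR from the
published surface plus Gaussian noise (sd 0.3 % WGR) and back-converts
to weight pairs. All generators are pure functions of an explicit seed,
and a `TruthManifest` (per-site and per-gene effects, coupled genes,
true β) is serialized next to the data.

What the synthetic data does **not** emulate — and hence what passing
tests do not show about real data: genomic sequence context (sites are
placed uniformly, not at enzyme recognition motifs), spatial correlation
of methylation along chromosomes, per-feature dispersion heterogeneity,
GC/length biases in counts, isoform structure, and any real GO/KEGG
structure (the term map is random). Recovery rates measured here are
therefore upper bounds for comparably sized real designs.

## Numerical choices and degenerate inputs

- Gene-level methylation sums are rounded to the nearest integer before
  the exact test. Because of this re-rounding, rescaling a single
  sample's raw depths (which normalization absorbs up to one common
  constant) can move an isolated borderline gene across the significance
  threshold; fold changes are preserved.
- All-zero count matrices, single-group designs, non-concave surfaces,
  zero-variance correlations, and selections outside the enrichment
  universe raise typed errors with the offending quantity named.
- Genes with zero counts in all samples are excluded before expression
  testing (they cannot move and would inflate the BH denominator).
- The pipeline summary asserts up + down = total for every differential
  block before writing.

## Problem sizes

The default synthetic study (2,000 genes, 21,800 sites, 3 vs 3) runs the
full pipeline in under a minute on one core; the test suite's
calibration and recovery checks use the same sizes, with smaller
configurations (200 genes, 2,200 sites) for structural and end-to-end
checks.

## Known limitations

- The NB engine uses a common dispersion and an exact conditional test;
  it will not numerically replicate DESeq/edgeR results (per-feature
  shrinkage, different test statistics), and no covariate designs are
  supported.
- Site-catalogue-scale results of the motivating study (e.g. its DMS and
  DEG totals) depend on its raw sequencing data and unpublished genome
  and are intentionally out of scope; the synthetic study verifies
  calibration and recovery instead.
- Transcript-level isoforms, UTR/CDS subdivision, and GO DAG propagation
  are not modelled.
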