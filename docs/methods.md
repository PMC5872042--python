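# Methods

This note documents the models and procedures `loadnet` implements, the
choices made where the methodology is genuinely open, and what the
synthetic validation does and does not demonstrate.

## Synthetic cohort generator

The generator emulates a small post-mortem case/control brain cohort of
the kind held under controlled access: ~60 unrelated subjects with a
~2:1 case/control split, bulk expression over a few thousand
transcripts, nine clinical covariates (six neuropathology metrics —
CDR, Braak, NP1, PLQ_Mn, NTr_Sum, NPr_Sum — plus pH, post-mortem
interval and age), and biallelic SNV genotypes.

**Expression.** Per-sample latent module factors `f_m ~ N(0,1)`
(centered to exact zero mean). Gene g in module m has log2-scale value
`baseline_g + loading_g · f_m + ε`, `ε ~ N(0, noise_sd)`; background
genes are baseline + noise only. Values are exponentiated (base 2) so
the stored matrix is non-negative and right-skewed, and the QC log2
transform approximately restores Gaussianity (making the transform's
SD-reduction demonstrable). Defaults: 2,000 genes, modules of
100/80/60/50, loading 1.0 ± 0.2, noise SD 0.5, baselines
`N(3, 1)` on the log2 scale.

**Traits.** Each trait is a linear combination of the module factors
plus `N(0, 0.5)` noise. By default the six neuropathology metrics load
+1 on the first factor (the concordant disease block), pH loads −0.5 on
it, NP1 splits 0.4/0.8 between the first and second factors, age loads
0.8 on the second factor, and post-mortem interval is pure noise. This
reproduces the familiar clinical geometry: a dominant neuropathology
axis (PC1), with NP1 deviating toward age on PC2, and pH
anti-correlated with disease burden. The generating literature reports
no effect sizes for the module→trait links; these values were chosen
once for testability (clear block structure, non-degenerate PC2) rather
than fitted to any dataset.

**Case/control labels.** Drawn per sample with
`P(case) = logistic(logit(2/3) + 2.0 · f_1)`, tying disease status to
the first module factor so class-based enrichment has signal while
preserving the ~40/20 split in expectation. An untied mode
(`class_link=False`) gives null labels.

**Genotypes.** Dosages `Binomial(2, maf)` per variant with
`maf ~ U(0.05, 0.5)`, 5% missingness (genotypes only — expression is
complete, mirroring pipelines that filter variants rather than samples
for missingness), and metadata (chrom/pos/rsID-style ids/ref/alt).
Ten planted eQTLs of +0.8 log2 units per alt allele are applied
multiplicatively (`raw ×= 2^(β·dosage)`) using the pre-missingness
dosages. Effects are planted in *first-module* genes: background genes
would be removed by the connectivity filter before the scan, and the
clinical covariates proxy the first module factor, so covariate
adjustment strips the dominant co-expression variance and exposes the
genotype effect — the standard rationale for covariate-adjusted eQTL
scanning. No LD structure or population stratification is simulated.

One seed governs everything; each sub-generator draws from a fixed,
documented stream, so a bundle is byte-reproducible.

**What the generator does not emulate:** count-specific noise
(overdispersion, library size), batch effects, correlated background
(real transcriptomes have pervasive weak correlation), LD, and
non-linear trait scales (CDR is generated as continuous, not ordinal).
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated generating model, not performance on real
tissue data.

## Three-tier QC

1. **Power transform**: `v → log2(v + pseudocount)`, pseudocount 1.
   Re-transforming a transformed matrix is an error.
2. **Entropy filter**: per gene, samples are binned into `n_bins`
   (default 16) equal-width bins over the gene's observed range;
   `H = −Σ p_i log2 p_i` in bits; genes with `H ≥ threshold` are kept
   (ties inclusive). A constant gene occupies one bin and scores 0.
   The binning scheme is the simplest under which a bit-threshold near
   the 4-bit ceiling of 16 bins is meaningful; both the bin count and
   the threshold (default 3.97 bits) are configurable.
3. **Connectivity filter**: soft degree
   `k_i = Σ_{j≠i} |cor(x_i,x_j)|^β` (Pearson); genes with
   `k_i ≥ k_min` are kept (default 45). β defaults to the soft power
   chosen for the network stage and is overridable.

Stage order is fixed; each stage's output genes are a subset of its
input, with counts tracked in a `QcReport`.

**Synthetic-scale profile.** The stock thresholds target large
(~50,000-transcript) panels with heavy-tailed occupancy. At 60 samples
of near-Gaussian data the entropy ceiling is ≈3.5 bits and soft degrees
peak near 13, so `synthetic_scale_config()` sets entropy 3.0 bits,
β = 6 and `k_min = 5` for runs on the default bundle; this keeps all
planted modules (smallest-module degrees ≈ 8) while removing the
uncorrelated background (degrees ≈ 0.15). The same profile pins the
network's soft power to 6: a few planted near-cliques cannot satisfy a
scale-free degree fit, so chasing one is not meaningful there.

## Co-expression network

Unsigned adjacency `a_ij = |cor(x_i,x_j)|^β` (zero diagonal). The
unsigned form matches the association-oriented use of the network; a
signed variant is not implemented. β is chosen as the smallest
candidate whose degree distribution achieves scale-free model fit
R² ≥ 0.8 (log10 frequency vs log10 degree over 10 equal-width degree
bins); if none qualifies the best-fitting candidate is used with a
warning.

TOM as above, with `tom_ii = 1`; the denominator vanishes only when
`min(k) = 0` and `a_ij = 1`, where the overlap is defined as 1.
Modules come from average-linkage hierarchical clustering on `1 − TOM`
cut at height 0.99 (static cut — reproducible and fully specified;
dynamic tree cutting is out of scope); clusters below `min_size`
(default 30) are relabeled 0 ("grey"). Surviving modules are renamed
1..K by decreasing size with deterministic tie-breaks.

Eigengenes: member genes standardized (zero mean, unit variance,
ddof = 1); the eigengene is the first principal component of the
samples × genes submatrix, rescaled to unit variance, with sign fixed
so it correlates non-negatively with the mean member profile (PCs are
sign-ambiguous; a fixed convention makes runs comparable). The
explained-variance fraction is reported per module.

## Trait association

Clinical concordance: pairwise-complete Pearson correlation matrix
(constant traits yield flagged NaNs, never silent zeros) and PCA via
eigendecomposition of the trait correlation matrix (standardized
internally; eigenvalues sum to the trait count; deterministic loading
signs).

The screen correlates every gene (or eigengene) with each clinical
trait. Per association: `r`, `t = r√(n−2)/√(1−r²)` with a two-sided
Student p, Fisher statistic `z = √(n−3)·atanh(r)`, and weighted
quantities `cor_w = w·r`, `z_w = w·z`, `p_w = 2·Φ(−|z_w|)` with
`w = scale × |trait loading on clinical PC2|`, scale 0.5. The weighted
p as implemented — scaling the Fisher z by the PC-coefficient weight
and taking a normal tail — is this package's construction: the
screening function it emulates is under-specified in the literature,
and this form preserves the documented "0.5 × PC2 coefficient" scaling
while remaining a proper tail probability. Down-weighted traits
(small PC2 coefficient) therefore yield conservative weighted p-values
by design.

Associations outside mean ± 3 SD of the z statistics are trimmed (the
trim is applied to z; perfect correlations, with infinite z, always
trim). Bonferroni (α = 0.01) and BH corrections accept an external test
count m; `paper_mode_m` sets m = subjects × transcripts, reproducing a
correction convention quoted against observation counts rather than
test counts. The per-gene report table carries the conventional columns
GENE, P.WEIGHTED (lowest corrected weighted p), FDR, COR.WEIGHTED,
#OF TRAITS (traits with uncorrected weighted p ≤ 0.05).

Functional annotation is a flat two-column TSV (gene, term); keyword
filtering is case-insensitive substring matching over a gene's terms;
term over-representation is the hypergeometric upper tail on the
analyzed background.

## eQTL

Variant QC applies call rate ≥ 0.8, MAF ≥ 0.02 and HWE exact p ≥ 1e−5
in that order, attributing each excluded variant to the first filter it
fails (order affects attribution, hence the per-filter counts). The HWE
test is the exact conditional test: enumeration of the heterozygote-
count distribution given allele counts via the standard stable
recurrence, two-sided by probability mass.

The scan is ordinary least squares of each gene's log2 expression on
[intercept, dosage, covariates], complete-case per variant (samples
missing that variant's call are dropped; no imputation), additive 0/1/2
coding. The per-variant core is a vectorized normal-equations solve
across all genes (validated against a reference OLS implementation to
1e−10); p-values are Student t with n − rank degrees of freedom.
Records at `p ≤ p_report` (default 1e−5) are kept; Bonferroni m
defaults to the number of tests performed, with a `paper_mode` that
uses subjects × variants. All-pairs (trans) scanning is the default; a
cis window is not implemented.

Covariates default to the nine clinical covariates (`"clinical"`),
matching the documented workflow even though several of them are also
association outcomes; a `"none"` mode runs unadjusted. Neither is
claimed to be the "right" causal adjustment — the choice is exposed.

QQ diagnostics report observed vs expected −log10 p order statistics
(expected `−log10((i−0.5)/n)`) and the genomic inflation factor
λ = median observed χ² / null median.

## GSEA

Ranking metric: `log2(mean_case / mean_control)` on the raw abundance
scale, class means floored at 1% of the smallest positive matrix value
so the ratio stays defined (a necessity the classic description leaves
open; configurable). Ties break lexicographically by gene id, making
the ranking strict and deterministic.

ES: walking the ranked list, hits add `|metric|^p / Σ_hits |metric|^p`
(exponent p = 1, the standard weighted form), misses subtract
`1/(N − |S|)`; ES is the maximum-magnitude deviation. The running sum
returns to zero only for p = 0.

Null: class labels are permuted (seeded) and the metric, ranking and ES
recomputed per permutation — phenotype permutation preserves gene–gene
correlation, so strongly co-expressed sets correctly receive wide
nulls. `NES = ES / mean |same-sign permuted ES|` (the sign-matched
form; a literal `all`-permutations mode is available via
`nes_null="all"`), nominal p is the add-one-corrected fraction of
same-sign permuted ES at least as extreme. FDR q compares each observed
NES against the pooled permuted NES distribution
(q = same-sign tail fraction in the pool / same-sign tail fraction
among observed NES, capped at 1), with q-value-style monotonicity: the
running minimum is carried from the least extreme set upward within
each sign. Enrichment runs on the full abundance matrix rather than the
network-QC'd subset — it is an independent validation pass, and
restricting the universe to module genes would distort set sizes.

GMT sets are intersected with the analyzed genes and dropped outside
[5, 500] members, with a report.

## Pipeline

The CLI (`simulate | qc | network | associate | eqtl | gsea | run-all`)
is a thin layer over the model classes. Every run writes the effective
configuration and a manifest (per-stage counts, wall time, version).
Configuration is YAML with defaults for every parameter and strict
rejection of unknown keys. Execution is single-process and in-memory;
the default problem sizes (≤ 5,000 genes × 60 samples) run in seconds.

## Validation scope and problem sizes

The test suite and `scripts/acceptance.py` use: brute-force oracle
comparisons on ≤ 20-element instances (TOM, adjacency, connectivity,
OLS, hypergeometric tail, GSEA running sum; tolerance 1e−10 or
tighter); analytic fixed points (uniform 16-bin entropy = 4 bits,
Bonferroni arithmetic, monomorphic HWE p = 1, NES ratios); null
calibration at 2,000 replicates (rejection at α = 0.05 inside the
binomial 99% CI); planted-effect recovery (eQTL β = 0.8 at n = 200
over 100 replicates, module ARI and eigengene–factor correlation on the
default bundle); constructed filter fixtures (six-variant VCF with
per-filter attribution 2/2/1; twenty-gene annotation map with twelve
keyword matches); and a 1,000-permutation enrichment run on the default
bundle. These sizes were chosen so the entire validation executes in
well under a minute on one CPU while keeping Monte-Carlo error small
relative to every asserted margin.

## Known limitations

- Entropy thresholds in bits are only comparable across datasets with
  the same bin count and similar occupancy shapes; the 3.97-bit default
  presumes a large heavy-tailed panel.
- The weighted association p-value is a package-defined construction
  (see above), not a canonical statistic.
- Static tree cut only; closely spaced modules that a dynamic cut would
  separate may merge or shed members.
- The HWE test assumes autosomal biallelic genotypes; no X-chromosome
  handling.
- GSEA provides no gene-level leading-edge report and no gene-set
  (as opposed to phenotype) permutation mode.
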