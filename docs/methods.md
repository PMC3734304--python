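# Methods

## Problem setting

A single target gene's expression, measured by RNA-seq in a small cohort
(tens of cases, a handful of controls), is tested for association against
every variant inside a symmetric cis window around an anchor position. The
package implements the full desk pipeline from raw counts and genotypes to
adjusted per-variant p-values, together with a case/control expression
contrast and a co-expression screen.

## Normalization

Size factors are median-of-ratios: `s_j = median_i counts(i,j) / geomean_i`,
the median taken over genes with strictly positive counts in every sample
(genes with any zero are excluded — the classic convention; a zero count
would otherwise contribute a zero ratio and drag medians down). Normalized
expression is `counts(i,j)/s_j`, with no log or variance-stabilizing
transform: the directional test is rank-based and indifferent to monotone
transforms, and the linear model defaults to the normalized scale (a
`log_expression` flag switches it to `log1p` of normalized values for users
who prefer multiplicative-error regression).

Two facts worth knowing about this estimator:

- Size factors are identified only up to a common constant. Multiplying one
  sample's column by `c` multiplies its factor by `c` *relative to the
  others*; all factors also absorb `c^(1/n)` because the geometric-mean
  pseudo-reference contains the scaled sample. Tests state equivariance in
  ratio form for this reason.
- DESeq2 (and pydeseq2) take the median on the log scale. For an odd number
  of qualifying genes the two definitions coincide exactly; for an even
  number they differ microscopically (geometric vs arithmetic mean of the
  two middle ratios). The ratio-scale median is used here.

## The two association tests

**Linear.** OLS of expression on additive dosage, complete-case over
non-missing genotypes; Wald t on the slope, two-sided p from t(n−2).
Requires ≥ 3 samples and ≥ 2 distinct dosage values. A perfect fit (zero
residual variance, nonzero slope) reports p = 0 with a degeneracy flag
rather than a division error.

**Directional.** The tie-corrected Jonckheere–Terpstra statistic
`T = Σ_{k<l} U_kl` over dosage-ordered groups, with `U_kl` the
Mann–Whitney count giving ties weight ½. The per-pair probabilistic index
`U_kl/(n_k n_l)` is reported in each record's group summary. The null is
the permutation distribution of expression across samples with group sizes
fixed:

- *Exact enumeration* over all distinct assignments of samples to groups
  whenever the multinomial count `n!/(n₀!n₁!n₂!)` is at most the enumeration
  cap (default 200,000). One-sided p-values are then exact proportions.
- *Monte-Carlo* otherwise, with `B` permutations (default 10,000; minimum
  100 enforced) and the add-one estimator `(b+1)/(B+1)`, which cannot return
  zero and is valid as a permutation p-value. The Monte-Carlo engine
  precomputes the n×n pairwise comparison matrix once per variant and
  evaluates all permutations as masked bilinear forms (three matrix products
  per group pair), which is what makes thousand-permutation scans over
  hundreds of variants cheap.

The reported two-sided p is `min(1, 2·min(p_inc, p_dec))`, with the
direction set by the smaller tail; a `side` option gives the pre-specified
one-sided versions. Doubling is slightly conservative for asymmetric
discrete nulls but keeps the two tails interpretable and symmetric.

Comparisons of permuted statistics use an absolute tolerance of 1e-9; T is
always a multiple of ½ so this only guards against float summation order.

**Untestable variants.** Variants with fewer than two genotype groups of at
least `min_group_n` samples (default 2) — monomorphic or nearly so — are
skipped with a logged reason and counted in the scan result, not errored, so
scans over real windows complete.

**Reproducibility.** One master seed; each variant derives a child seed from
(seed, CRC32(variant id)), so per-variant p-values are independent of scan
order and stable under window changes.

## Multiplicity and α selection

`bh_adjust` implements the step-up definition directly and accepts a family
size `m` larger than the supplied vector (needed when adjusting a subset of
a tested family); the unsupplied tests are treated as occupying the worst
ranks, the conservative completion. `alpha_scan` counts observed rejections
at each α on a grid (default step 0.001, range (0, 0.1]; α = 0 is excluded
because its null expectation is zero), divides by `α·m`, and reports the
smallest α attaining the maximal ratio (conservative tie-break). The ratio
is observed/expected, so a maximum means *enrichment* of significant results
over the null expectation. When no p-value falls at or below any grid α,
`alpha_star` is None rather than a fabricated optimum.

## Case/control contrast and co-expression

The group comparison defaults to the Wilcoxon rank-sum test (exact for
small untied samples via scipy), robust for a 15-control arm; Welch's t is
available for users who trust normality on the normalized scale. The
co-expression screen computes Pearson r of every gene against the target
over complete pairs, p from `t = r·√((n−2)/(1−r²))` with n−2 df (a
permutation option exists for small n), BH and Bonferroni over the screened
family, and a joint threshold class: positive if `r > r_min` *and*
`p < p_max` (defaults 0.30 and 0.05), negative mirrored, else none. A
stricter reporting tier (`strict_r`, e.g. 0.50) reclassifies without
dropping rows. Constant gene vectors yield an undefined r and are flagged,
excluded from classing and corrections.

## Synthetic cohorts

The generator states a fixed world chosen to mirror the target study design:
84 cases + 15 controls; 468 variants placed uniformly (sorted, unique) over
a 2 Mb window centred on the anchor; Hardy–Weinberg dosages
`Binomial(2, maf)` with per-variant MAF drawn from U(0.05, 0.5); 200 genes
with log-uniform baseline means in [50, 1000] (typical bulk RNA-seq
mean-count range for moderately expressed genes; the range is a package
choice, stated once here); negative-binomial counts with dispersion
φ = 0.1 (variance `μ + φμ²`); per-sample depth factors lognormal(0, 0.25);
a multiplicative case effect of 0.7 on the target gene's mean (a 30%
decrease in cases); planted cis effects as additive shifts β on the
log-mean per alt allele. Variants are independent by default; an optional
Gaussian-copula block mode (block size, ρ) adds LD-like correlation for
robustness experiments.

What the generator does **not** emulate: family/pedigree structure (the
motivating cohorts include related individuals; neither the original
analysis nor this package corrects for it), realistic LD decay, GC/length
biases, batch effects, or disease-dependent genotype frequencies (case
status is assigned independently of genotype — the phenotype under test is
expression, not disease). A green simulation-based test therefore
establishes calibration and power *under this stated world*, not under
arbitrary real-data pathologies.

## Numerical and design choices

- The directional test's exact published form was never released by its
  original authors; the tie-corrected JT statistic with a permutation null
  and doubled one-sided tails is the closest published relative and is
  exactly testable by enumeration, which is why it was chosen.
- Dosage counts alt alleles as written in the file (not minor alleles):
  reproducible from the input alone; direction labels make orientation
  explicit.
- Window boundaries are inclusive at both ends; the anchor position is a
  required input.
- Missing genotypes are handled per variant by complete-case dropping.
- Decimal output always uses dots; result tables serialize floats with
  `repr` and re-read with round-trip parsing, so write→read is lossless.
- Simulation-heavy test budgets: the type-I calibration runs at its stated
  scale (2,000 null cohorts, B = 1,000); the 200-replicate × 468-variant
  power/recovery check uses B = 300 Monte-Carlo permutations per variant,
  enough to rank a β = 1.0 effect first while keeping the suite inside a
  CI-scale time budget.

## Known limitations

- No covariate adjustment (age, ancestry PCs) and no mixed-model
  relatedness correction; with familial samples the permutation null
  assumes exchangeability that relatedness violates.
- The two-sided-by-doubling permutation p can exceed the attainable minimum
  for very small groups; exact enumeration reports the attainable floor.
- BH with `m > len(p)` is conservative by construction.
- The co-expression p-values use the t approximation, which is anti-
  conservative for heavy-tailed expression at small n; use the permutation
  option there.
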