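# Methods

This note documents the statistical models behind `endoseq`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Count model and preprocessing

Counts are modelled as negative binomial with gene-specific dispersion,
Var(K) = μ + αμ². All preprocessing derives from that assumption.

**Globin removal.** Whole-blood libraries can be dominated by hemoglobin
transcripts; the packaged default list (HBA1/2, HBB, HBD, HBE1, HBG1/2,
HBM, HBQ1, HBZ) is removed before any estimation. The list is
configuration, not code, because globin depletion protocols differ between
labs. Removal precedes size-factor estimation so that library-size
estimates describe the informative part of the library; the order is
recorded in provenance and the functions can be called in either order.

**Size factors.** Median-of-ratios: for sample j,
s_j = median over reference genes of k_gj / geomean_g(k), where reference
genes are those with a nonzero count in every sample, then rescaled to
geometric mean 1. The median makes the estimator robust to the minority of
genes that are genuinely differential; it fails (with an explicit error) if
no gene is expressed everywhere, since a pseudo-reference would then be
needed.

**Dispersion.** Per-gene method-of-moments on normalized counts,
α_g = max(0, (s² − m)/m²); the pooled value used by the VST is the median
of the positive α_g, floored at 1e-4. The floor keeps the transform defined
for near-Poisson data; at α = 1e-4 the transform is within numerical noise
of 2√x. Method-of-moments is noisy per gene at n ≈ 30 but the *pooled*
median is stable, and per-gene values enter only the Wald standard errors,
where their noise is tolerable (verified by null calibration).

**Variance-stabilizing transform.** The closed form
g(x) = (2/√α)·asinh(√(αx)) is the exact VST of the NB variance function
with constant α: monotone, g(0) = 0, ≈ 2√x for αx ≪ 1 and ≈ (1/√α)·log x +
const for αx ≫ 1. A spline-fitted, trend-aware VST (as DESeq2 fits) adapts
to a mean-dispersion trend; the closed form was chosen because it is fully
specified, desk-testable against its limits, and satisfies the same
contract (monotone, asymptotically logarithmic, variance within binned
abundance classes stable to < 2× over two decades of mean, verified by
simulation).

**Batch adjustment.** Parametric empirical-Bayes location/scale
adjustment, the ComBat model: standardize each gene against its
batch-weighted grand mean and pooled variance, estimate per-batch per-gene
location γ̂ and scale δ̂², shrink them toward cross-gene priors (normal for
γ, inverse-gamma for δ² via moment matching, solved by the standard
iterative posterior-mode update), adjust, and restore the gene scale. A
single-batch matrix is returned unchanged; singleton batches are an error
because a scale cannot be estimated from one sample.

*A note on idempotency.* EB shrinkage deliberately removes only the
estimated batch effect net of its own sampling noise; the residual left by
the shrunk correction is second-order but not zero, so applying the
adjustment twice is a contraction rather than an exact fixed point. The
test suite asserts that the second application changes values by < 5% of
the first application's change (and < 0.02 RMS absolute) on balanced
designs with gene-specific batch shifts (drawn N(2, 1) at 50 samples per
batch — the adjustment's own generative regime). Exact idempotency would
require un-shrunk standardization, which discards the EB robustness that
motivates the method.

## Clustering and endotype assignment

Samples are clustered by average-linkage agglomeration on Euclidean
distances between variance-stabilized profiles. Average linkage is
monotone (no height inversions — asserted on every tree) and the
implementation is checked gene-for-gene against a brute-force O(n³)
re-implementation. Samples are sorted lexicographically before linkage so
results are invariant to input column order.

The tree is cut into k = 3 flat clusters by default (two major endotypes
plus an "other" group); k is configurable because validation cohorts can
show a different number of outliers. A k-cut was chosen over a height
threshold because it makes the "two major + remainder" contract explicit
and deterministic; ties in cluster size break by lower mean within-cluster
cophenetic distance, then by lexicographically first member.

A/B orientation is decided by anchor genes rather than cluster size (the
major clusters can be nearly equal, 13 vs 14): the cluster with higher mean
stabilized expression of a neutrophil-degranulation marker set (default
S100A8, S100A9, FCGR3B, CSF3R, MMP9, shipped as configuration) is labeled
A. Swapping the anchor set for a B-directed set flips the labels, which the
tests assert as a symmetry.

Concordance between assignments reports (i) the agreement fraction
maximized over the two matchings of {A, B} with "other" fixed, and (ii)
the adjusted Rand index of the full three-label partition, which is
permutation-invariant by construction.

## Differential expression

An explicit NB Wald test replaces a full GLM fit: group means of
size-factor-normalized counts with a 0.5 pseudocount (a standard
continuity correction that bounds fold changes), log2FC = log2((μ̂_A+½)/(μ̂_B+½)),
and a delta-method standard error using Var(x̄) = μ·mean(1/s)/n + αμ²/n per
group with the per-gene α_g. Two-sided normal p-values are BH-adjusted.
"Other" samples are excluded — the contrast is strictly between the major
endotypes. Genes with zero counts in both groups report log2FC = 0, p = 1.

This is a deliberately transparent contract substitute for a DESeq2-style
analysis (no dispersion shrinkage, no independent filtering, no LFC
shrinkage); the DE thresholds (|FC| ≥ 1.5, q ≤ 0.05) are applied to the raw
fold-change estimate. Calibration is verified empirically: permutation-null
p-values are uniform (KS < 0.05 at ~2000 genes, 13 vs 14 samples) and the
q ≤ 0.05 null call rate stays ≤ 0.07.

## Signature selection

Four conjunctive filters (order-independent), then a ranking:

1. significant DE (q < 0.05, |FC| > 1.5) — the discovery thresholds;
2. |FC| ≥ 2 between cluster means of normalized counts (pseudocount ½,
   matching the DE convention);
3. within-cluster variance of stabilized values in the lowest 50% in *both*
   clusters, quantiles taken over all genes in the matrix per cluster;
4. mean normalized count ≥ 100 across the A/B samples.

Survivors are ranked by divergence = |mean_A − mean_B| / pooled
within-cluster SD — a signal-to-noise score that jointly encodes "maximally
divergent between endotypes" and "reliable in individual samples" — and
the top k = 20 are returned (ties break lexicographically; fewer than k
survivors produce a warning, zero an error naming the most restrictive
filter). No up-A/up-B balance is imposed. Validation re-clusters a cohort
on the signature genes alone (average linkage, 2-cluster cut) and scores
concordance against a reference assignment restricted to A/B samples.

## Gene-set tests

**ORA** — upper-tail hypergeometric overlap of a query list with each set,
both intersected with an explicit universe, BH across sets. The universe is
a required argument: results are meaningless without a stated background.

**Fisher overlap** — 2×2 cross-classification of the universe by
membership in two lists; two-sided p by the probability-mass rule; sample
cross-product odds ratio with Haldane's ½ correction only when a cell is
zero. Checked against exhaustive enumeration of all tables with fixed
margins for universes ≤ 40.

**Rotation test (ROAST-style)** — per-gene moderated z for the A-vs-B
contrast: data are projected onto an orthonormal basis of the complement of
the intercept; the effect along the unit contrast direction is divided by a
moderated SD whose per-gene variance is shrunk toward the cross-gene mean
with a prior weight of 4 pseudo-genes (a fixed, lightweight stand-in for an
estimated EB hyperparameter, recorded in output). The set statistic is the
mean z over set genes; the null replaces the contrast direction with B
random unit vectors in the residual space (equivalent in distribution to
rotating the data, and simpler); p = (1 + #{|rotation| ≥ |observed|})/(B+1),
so min p = 1/(B+1). Under Gaussian exchangeability the test is exact, and
the measured null rejection at 0.05 over 500 replicates falls in
[0.03, 0.07]. Published ROAST variants (msq, floor, mixed alternatives) are
reduced to this single two-sided mean-z form, which is what a single
directional signature requires.

**Competitive test (CAMERA-style)** — the mean moderated z of set genes is
compared with the non-set mean by a two-sample z-test whose set-side
variance is inflated by VIF = 1 + (m−1)ρ̄, ρ̄ being the mean pairwise
correlation of set-gene residuals after removing the contrast, floored so
VIF ≥ 1. With ρ̄ = 0 the test reduces exactly to the unadjusted comparison;
with planted ρ = 0.5 the VIF keeps the null rejection ≤ 0.08 where the
unadjusted test exceeds 0.2.

## Marker ratios

Ratios of stabilized values (numerator + ε)/(denominator + ε) with
ε = 0.01 guarding empty denominators; default pairs TBX21:GATA3 (Th1:Th2),
FOXP3:CD3E (Treg share) and GATA3:CD3E (Th2 share), with all seven marker
levels reported alongside. Whether "ratio" should be a quotient or a
difference of stabilized (≈ logarithmic) values is ambiguous; the quotient
is the default and the difference is available via `mode="difference"`.
Group comparisons use a hand-written Wilcoxon rank-sum: exact enumeration
of rank placements when the pooled sample is ≤ 12 and tie-free (matching
full enumeration by construction and scipy's exact method in tests),
otherwise a normal approximation with tie-corrected variance and ±0.5
continuity correction.

## Synthetic cohorts

The generator emulates the data regime the analysis assumes:

| parameter | default | rationale |
|---|---|---|
| genes | 2000 | desk-scale stand-in for a filtered transcriptome |
| samples | 13 A / 14 B / 3 other | the discovery cohort's structure |
| batches | 2, balanced, log-SD 0.15 | moderate sequencing-date effect |
| DE fraction | 10% | sizeable but minority signal |
| |log2FC| | U(1, 3) | straddles the 1.5× and 2× analysis thresholds |
| dispersion α | U(0.05, 0.5) | typical bulk RNA-seq overdispersion |
| baseline μ | LogNormal(ln 150, 1.0) | expressed-gene depth in ~20M-read libraries |
| library size | LogNormal σ = 0.3 | realistic depth variation |
| globin block | 5 genes, 20% of reads | whole-blood hemoglobin dominance |
| gene sets | 20 sets, 20–100 genes, 5 DE-enriched (50%) | ORA/rotation targets |

Counts are drawn as K ~ NB(s_j · b_{batch,g} · μ_g · 2^{β_g·[group=A]}, α_g);
the "other" group gets an independent 150-gene shifted profile so it
separates from both endotypes. Named marker genes are planted with fixed
effects (GATA3, FOXP3, CD4 higher in B; TBX21 higher in A) and the anchor
block 1.5 log2-units higher in A, mirroring the neutrophil-high phenotype.
Clinical covariates condition on group: activity scores are rounded
truncated normals (A: N(21, 7); B: N(14, 5); other: N(21, 8) — group means
from the packaged cohort, the "other" spread widened for a 3-patient
group), and categorical frequencies follow the discovery cohort's observed
proportions. A second cohort can be drawn from the same truth object
(same gene-level parameters, fresh sampling), which is how cross-cohort
signature validation is tested. All randomness flows from one seed.

What the generator does *not* emulate: mean-dependent dispersion trends,
count outliers, GC/length biases, correlated co-expression modules outside
planted sets, confounded batch/group designs, or any single-cell structure.
Passing recovery tests therefore demonstrates internal consistency of the
pipeline under its own model, not robustness to those real-data
pathologies.

## Numerical and design notes

- Dispersion floor 1e-4; VST requires pooled α > 0.
- Degenerate genes (zero variance) get α_g = 0 and are handled throughout.
- The linkage step sorts samples by identifier; all downstream tie-breaks
  (cluster ranking, signature ordering) are lexicographic, so every result
  is a pure function of the inputs.
- Problem sizes in the test-suite simulations (200-gene × 16-sample null
  matrices for calibration at 500 replicates and B = 999 rotations;
  2000 × 30 recovery cohorts) were chosen as the smallest sizes at which
  the asymptotic approximations under test are expected to hold.
- The packaged clinical tables are covered by SHA-256 checksums so silent
  edits fail loudly.

## Known limitations

- The Wald test with moment dispersions is slightly underpowered relative
  to a shrinkage-based GLM at n ≲ 10 per group and is not recommended below
  that.
- ComBat-style adjustment without a protected design matrix can absorb
  group signal if batch and group are strongly confounded; the generator
  balances batches across groups, and confounded designs are the user's
  responsibility.
- Genome-scale results from real cohorts (exact DE counts, pathway tables,
  specific signature gene identities) depend on the data and tool versions
  that produced them; this package reproduces the *procedures* and verifies
  them on planted-truth simulations, not those specific numbers.
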