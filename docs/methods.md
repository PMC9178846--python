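# Methods

This note documents the statistical models, conventions and numerical
choices behind `heterosiskit`, and what the synthetic-data tests do and
do not demonstrate about real data.

## Study design assumed

The package operates on *triplets*: a female parent, a male parent and
their F1 hybrid, each with replicated bulk RNA-seq gene-level counts
(three biological replicates per genotype is the canonical design) and
optionally sampled at multiple timepoints (e.g. 21 and 24 days after
sowing). Phenotypes (fresh/dry weight, leaf area, leaf length/width) are
replicate tables per genotype. Upstream read processing (QC, alignment,
counting) is out of scope; the entry point is the count matrix.

## Expression bookkeeping

* **Size factors** are classical median-of-ratios: the reference for
  each gene is its geometric mean across samples, restricted to genes
  detected in every sample; a sample's factor is the median ratio to
  that reference. Because the reference itself absorbs a common
  `c^(1/n)` when one library is scaled by `c`, equivariance holds on
  the ratio scale (factor ratios scale exactly by `c`), which is the
  form our tests assert.
* **TPM**: `1e6 · (c_g/L_g) / Σ_h (c_h/L_h)` using annotated gene
  lengths; no effective-length/fragment-length correction is applied
  because no fragment model is assumed. All-zero samples yield all-zero
  TPM rather than an error.
* **Expressed-gene filter**: a gene is expressed if, in at least one
  (cross, role, timepoint) replicate group, the summed counts are
  strictly greater than 30. The grouping is a documented convention:
  the per-group "any" rule keeps genes expressed in only one genotype,
  which the dominance classes require. The filter is monotone in the
  counts.
* **Sample correlation** is Pearson on TPM of expressed genes, without
  a log transform (the quantity named by the protocol it follows).
  Zero-variance samples produce NaN entries as an explicit
  "undefined" flag.
* **qPCR**: relative expression by `2^-ΔΔCT` against a reference gene
  and a calibrator sample; the calibrator is exactly 1 by construction.

## Differential expression

A deliberately transparent two-group negative-binomial Wald test, with
an import path for tables produced by external DE tools:

* **Normalization**: counts divided by their size factors.
* **Dispersion**: per-gene pooled method of moments,
  `α = max(1e-8, (s² − m)/m²)`, with within-group variances pooled by
  degrees of freedom and the mean replicate-weighted across groups.
  Under-dispersed genes clamp to the floor. No shrinkage across genes.
* **Effect size**: `log2FC = log2((m_a + ½)/(m_b + ½))` on normalized
  group means; the 0.5 pseudo-count keeps estimates finite with zeros.
* **Standard error**: delta method from the NB variance of a group
  mean, `Var(m_g) = (m_g + αm_g²)/n_g`, propagated through the log.
* **Reference distribution**: the Wald statistic is compared to a
  Student t on `n_a + n_b − 2` degrees of freedom rather than a normal.
  The standard error is a plug-in estimate from few replicates, and in
  null simulations the t reference holds the 0.05-level rejection rate
  at 0.050–0.052 where the normal reference reaches 0.066 (n = 10 per
  group) and 0.085 (n = 5). Genes with zero counts in both groups are
  reported untestable (`p = 1`, `log2FC = 0`).
* **Multiple testing**: Benjamini–Hochberg step-up with monotone
  enforcement, stable ties, and NaN p-values propagated (with a warning
  count) rather than silently dropped.
* **Calling**: `up`/`down` require `q < 0.05` **and** `|log2FC| > 1`,
  both strict; everything else is `ns`.

No GLM covariates, outlier replacement or independent filtering are
implemented; exact numeric parity with any particular external DE tool
is a non-goal.

## Inheritance classification

The three contrasts per triplet (H vs F, H vs M, F vs M) are reduced to
sign codes (+1 higher, −1 lower, 0 not significant). The 27 patterns
partition exactly into 1 no-change pattern, 12 consistent classes and
14 inconsistent residual patterns:

| category | classes | pattern |
|---|---|---|
| additive | I, XII | hybrid strictly between differing parents |
| ELD-M | II, XI | hybrid = male parent, parents differ |
| ELD-F | IV, IX | hybrid = female parent, parents differ |
| OD | V, VI, VIII | hybrid above both parents (by s_FM sign) |
| UD | III, VII, X | hybrid below both parents (by s_FM sign) |

Parental ELD is {II, XI, IV, IX}; II and IV are the high-parent bins
(dominance toward the significantly higher parent). The 14 residual
patterns are reported as `AMB` rather than forced into a nearest class:
patterns such as "parents differ but the hybrid is distinguishable from
neither" carry real information about power and should stay visible.
Additivity requires significance against **both** parents; hybrids
between the parents but separable from only one are `AMB`.

A structural consequence of the published calling thresholds is worth
stating: a gene whose hybrid mean sits exactly at the mid-parent of an
f-fold parent pair has a true fold change of `2f/(f+1) < 2` against the
nearer parent, so it can never pass `|log2FC| > 1` on that side and is
classified as dominance toward that parent instead. Exact additivity is
therefore systematically under-called under these thresholds — by any
implementation using them — which is consistent with additive genes
being a small minority in this kind of survey.

## Phenotype heterosis

`MP = (P_f + P_m)/2`, `MPH = (F1 − MP)/MP × 100%`,
`HPH = (F1 − HP)/HP × 100%` with HP the better parent. Percentages are
reported on the printed scale (83.77, not 0.8377). Significance of the
hybrid against MP uses an unpaired two-sample t-test of hybrid
replicates against *mid-parent pseudo-samples* formed by
replicate-index pairing of the parents; index pairing is a deterministic
documented convention (no pairing rule is implied by the design).
Student's equal-variance test is the default, matching common
statistical-software defaults for "unpaired t-test"; a Welch flag is
provided. Stars: * p<0.05, ** p<0.01, *** p<0.001.

The leaf length/width contribution treats leaf area as ∝ length ×
width, so the log area gain over the mid-parent decomposes additively:
`contribution_L = Δlog L / (Δlog L + Δlog W) × 100`. This decomposition
is a declared convention of this package; contributions sum to 100 when
both gains are positive and are NA when the total log gain is zero.

## Co-expression networks

Input is log2(TPM + 1) of the union of DEGs across contrasts (log
transform chosen for variance stabilization; documented here because it
is a choice, not a given).

* **Soft threshold**: smallest power β in 1..20 whose scale-free fit
  reaches R² ≥ 0.8, else the argmax. The fit regresses log10 bin
  frequency on log10 mean connectivity over 10 linear bins and is set
  to 0 for non-decaying (positive-slope) fits.
* **Adjacency**: unsigned `|cor|^β` by default (signedness is not
  dictated by the protocol emulated; a signed option
  `((1+cor)/2)^β` exists).
* **TOM**: `TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)`
  with connectivity excluding the diagonal, computed as a single matrix
  product; verified elementwise against a brute-force double loop.
* **Modules**: average-linkage clustering on 1 − TOM, cut statically at
  0.99 × the maximum merge height; clusters below 30 genes become
  unassigned (module 0); modules whose eigengenes correlate above 0.75
  are merged iteratively (most-correlated pair first). A static cut
  plus eigengene merging is simpler and fully specified, in preference
  to a dynamic tree cut whose parameters would be unconstrained here;
  recovering any particular published module count is explicitly not a
  goal.
* **Eigengenes**: unit-norm first principal component of the module's
  gene-standardized profiles, oriented to correlate positively with the
  module's mean profile. Single-gene modules use the standardized
  profile itself.
* **Module–trait correlation**: Pearson r with a two-sided Student p on
  n − 2 df, for any trait vector aligned to the expression samples (the
  pipeline uses each sample's genotype-mean trait value).
* **Hub genes**: KME = correlation with the own-module eigengene;
  hub ⇔ KME > 0.90 and p < 10⁻⁶, both strict, with the KME p-value
  taken as the same n − 2 df correlation test.

## Synthetic data

The count simulator plants one of 13 truth labels per gene and derives
genotype means deterministically (baseline log-normal with σ = 0.5
around a configurable mean; "different" means separated by
`effect_fold`, default 4; additive truth at the exact mid-parent;
transgressive truth at fold × max or min/fold). Counts are
gamma–Poisson (NB) with `Var = μ + αμ²`, per-sample log-normal(0, 0.1)
depth multipliers, and a single integer seed for bit-reproducibility.
Default proportions mirror the composition this kind of survey reports:
40% unchanged, ~85% of classified genes in the four parental-ELD bins
(~58% of those toward the higher parent), additive and transgressive
genes rare. The phenotype simulator draws normal replicates with a
configurable coefficient of variation around parent means and around
`MP × (1 + MPH/100)`, so the generative MPH is recovered exactly at
cv = 0.

What the simulations do **not** emulate: batch effects, isoform
structure, correlated genes outside planted modules, GC/length biases,
outlier replicates, or real biological effect-size distributions.
Passing planted-truth tests therefore demonstrates correctness of the
statistical machinery under its own model, not performance on real
libraries.

## Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen to make the
statistical assertions sharp while staying light: 5,000 genes × 5
replicates for planted-truth recovery (~1e6 counts per sample), 10,000
genes × 10 replicates for the null calibration, 2 × 50-gene blocks over
20 samples for module recovery (10 seeds), 2,000 phenotype replicates
for Monte-Carlo heterosis estimates. Every stochastic step is driven by
an explicit integer seed; the acceptance script derives independent
sub-streams from a single `--seed` via `numpy.random.SeedSequence`.

## Known limitations

* The NB test is per-gene two-group only; designs with covariates need
  an external tool (whose tables can be imported).
* Dispersion is estimated per gene without information sharing, which
  is noisy at 3 replicates; calibration relies on the t reference.
* The static tree cut can split one very large homogeneous module
  before merging rejoins it; pathological TOM landscapes may need a
  manually chosen `cut_height_fraction`.
* The expressed-gene filter and classification operate per
  cross/timepoint; no multi-cross joint modelling is attempted.
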