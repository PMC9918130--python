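# Methods

`plsrank` implements a candidate-gene prioritization workflow for a
three-group bulk RNA-seq design: an intact control group (C), a group
sampled after a sustained intervention (A20, e.g. 20 days of daily
agonistic interactions), and the same intervention followed by a
withdrawal period (AD, e.g. 14 days of fighting deprivation), with
n = 6 animals per group. The pipeline starts from a genes × samples
FPKM matrix; read trimming, alignment and quantification are upstream
of its scope.

## Analysis scale and preprocessing

All inference operates on `log2(FPKM + c)` with pseudocount `c = 1` by
default (configurable). FPKM is already within-sample normalized, so
the only further normalization is per-gene: each gene row is centered
and scaled to unit sample variance (n − 1 denominator). "Centered,
normalized and scaled" is deliberately implemented as this single
z-scoring step; no additional between-sample normalization is applied.
Zero-variance genes cannot be standardized and are dropped with a
logged report; an all-constant matrix is an error rather than an empty
result.

## Sample ordination (PCoA)

Sample structure is summarized by classical principal coordinate
analysis of the Euclidean distances between samples on the processed
scale: Gower double-centering of the squared distance matrix,
`B = -1/2 · J D² J`, followed by a symmetric eigendecomposition.
Coordinates are eigenvectors scaled by the square root of their
eigenvalues, restricted to numerically positive eigenvalues (cutoff
`1e-10 · λ₁`), so pairwise coordinate distances reproduce the input
distances to machine precision. On Euclidean input PCoA is equivalent
to PCA of the samples up to axis sign; the test suite asserts both this
equivalence and agreement with scikit-bio's independent implementation.
Axes are deterministically oriented so the first sample's coordinate is
non-negative.

## Differential expression

The three pairwise contrasts (C_A20, C_AD, A20_AD) are tested per gene
with Welch's unequal-variance two-sample t-test on the log2 scale,
adjusted per contrast by Benjamini–Hochberg (contrasts are corrected
separately, never jointly; default α = 0.05). The engine is pluggable
(`call_degs(..., test_fn=...)`) because FPKM-era pipelines differ in
this choice and the upstream tool chain that motivated this package did
not document its engine. Two caveats, both asserted by the tests:

* **Calibration.** At n = 6 per group the Welch–Satterthwaite df
  approximation is slightly conservative: the measured raw type-I error
  at nominal 0.05 is ≈ 0.046 under the generator's equal-variance null.
  This is a property of the chosen engine, not a defect of the
  implementation; the pooled t-test would be exact under equal
  variances but is not robust to variance heterogeneity.
* **Fold changes.** Reported `log2FC` is the log2 ratio of raw
  arithmetic group means of FPKM, with no pseudocount — this exactly
  reproduces reference worked examples recomputed from printed group
  means. If a group mean is zero, the configured pseudocount is added
  to both means and the row is flagged (`fc_pseudocount_used`).

## PLS-DA and Axis-1 correlation ranking

The discriminant step relates two blocks over the same samples: the
processed expression block X (restricted to the two contrasted groups
and column-centered per gene over those samples) and a column-centered
dummy block Y coding group membership. Axis 1 is the unit-norm gene
weight vector from the first singular triple of the cross-covariance
XᵀY — equivalently one NIPALS component; Axis 2 comes from the deflated
X block, making successive score vectors orthogonal. With only two
classes the dummy block has rank 1, so either indicator column yields
the same axis (tested). When the cross-covariance is numerically zero
(no group effect) the axis is flagged unstable rather than reported as
meaningful.

Orientation is fixed by the convention that the control group's mean
Axis-1 score is positive. Consequently a gene *down* in the
experimental group correlates positively with Axis 1 and an
up-regulated gene correlates negatively; ranking and candidate
selection therefore use |r|.

Per-gene Pearson correlations with the Axis-1 scores are binned at
width 0.1 (`1.00–0.90`, `0.89–0.80`, …, `0.09–0.00`). Bins are
lower-closed, with the top bin closed on both ends, so a correlation at
exactly 0.90 lands in the top bin — consistent with reporting
candidates as "r > |0.90|" at two-decimal print precision. Candidate
selection uses the inclusive comparison |r| ≥ threshold (default 0.90),
sorted by |r| descending with alphabetical tie-break, optionally
intersected with annotation flags (neurogenesis membership,
transcription-factor status, behavior terms) and with a DEG list, since
the published candidate tables are DEG-restricted.

PLS-DA consumes the processed gene matrix directly rather than PCoA
coordinates: per-gene Axis-1 correlations are only well defined in gene
space. The ordination is a companion visualization/QC step, not a
PLS input.

## Trajectory classification

Each gene's dynamics across C → A20 → AD are reduced to the
significance flags and fold-change signs of the three contrasts and
mapped through an ordered decision table (persistent → partial
normalization → deprivation-emergent → gradual-emergent → restored →
unclassified; see `plsrank.trajectory` for the exact rules). Ordered
evaluation makes the table total and mutually exclusive by
construction; the tests enumerate every flag/direction/magnitude
combination. "Did not restore" is operationalized as A20_AD
non-significant — the stricter of the two plausible readings, with the
partial-normalization rule catching the overlap. An exact-zero fold
change agrees with either direction.

## Coexpression screening

The critical correlation is analytic: `r* = t / sqrt(t² + df)` with `t`
the two-tailed Student-t critical value at level α and `df = n − 2`.
With the 12 samples of a two-group comparison (df = 10) and α = 0.001,
`r* = 0.823`. Correlations are computed on `log2(FPKM + 1)` across
those 12 samples (Pearson r is invariant to the per-gene z-scoring, so
this matches the processed scale); the threshold comparison is
inclusive (≥). Partners of a key gene are ranked by |r| with
alphabetical tie-break; `top_k` truncates reporting only, never the
flag computation. Behavior terms of the key gene(s) are propagated to
flagged partners as hypotheses, with terms the partner already carries
marked "known" instead.

## Over-representation

A database-independent stand-in for pathway enrichment: upper-tail
hypergeometric `P(X ≥ k)` of the query/set overlap, one-sided
(enrichment only), sets intersected with the universe before testing,
BH across sets, significance at FDR < 0.05. The universe defaults to
the expressed genes of the experiment, not the genome. The tests pin
the implementation to exhaustive combinatorial enumeration on universes
≤ 25. Reproducing any specific database's FDR values is explicitly out
of scope — curated pathway collections are version-dependent inputs,
supplied as GMT.

## The synthetic-data generator

No public expression matrix accompanies the motivating study, so the
generator emulates its statistical structure and emits ground truth for
every downstream stage:

* **Expression model.** Log-normal FPKM: per-gene baseline log2 means
  `Normal(4.5, 1.5)` (typical FPKM ≈ 3–80, matching the worked
  examples' scale) and within-group noise `Normal(0, 0.1)` on the log2
  scale. The analysis operates entirely on log2 FPKM, so count-level
  (negative-binomial) simulation would add machinery without exercising
  anything the pipeline computes. The default within-group SD of 0.1 is
  a free parameter chosen so that effects of |log2FC| ≈ 0.3–0.4 are
  confidently detectable at n = 6 — the published tables' implied
  per-gene SDs are, if anything, smaller (≈ 0.06).
* **Planted effects.** A `deg_fraction` of genes (default 0.1,
  emulating ~2k DEGs in a ~10⁴-gene transcriptome) receives a signed
  effect δ with |δ| drawn from `effect_size_range` (default
  [0.2, 0.6], bracketing the printed fold-change magnitudes) and a
  trajectory class drawn from `trajectory_mix` (default 0.4 persistent,
  0.2 partial normalization, 0.1 deprivation-emergent, 0.1
  gradual-emergent, 0.2 restored — persistent dynamics dominating, as
  in the motivating data where 24 of 31 withdrawal-stage DEGs had not
  restored). Classes are planted as explicit (A20, AD) mean-shift
  pairs: persistent (δ, δ); partial normalization (δ, δ/2);
  deprivation-emergent (0, δ); restored (δ, 0). The gradual-emergent
  class is planted as two equal steps of 1.5 × noise SD each,
  *regardless of δ*: by definition its per-step changes are
  individually sub-threshold while the cumulative change is detectable,
  so its magnitude is intrinsically tied to the noise level — planting
  it at (δ/2, δ) would make the intermediate step significant for any
  clearly detectable δ and the class unrecoverable by its own
  definition. This threshold coupling also caps its recovery rate near
  50%; the default mix absorbs that.
* **Coexpression block.** A hub-and-spokes latent factor: the first
  block gene carries the factor with loading 1, the remaining
  `coexpr_block_size − 1` genes at `coexpr_loading` (default 0.9), so
  hub–spoke correlations equal the loading and spoke–spoke correlations
  its square. Mean shifts and the factor are additive, so a block gene
  can also be a planted DEG.
* **Annotations.** Neurogenesis membership is assigned at
  `neurogenesis_fraction` (default 0.04 ≈ a 397-gene curated list at
  10⁴-gene scale), transcription-factor flags at 0.1, and behavior
  terms to neurogenesis genes at 0.15 per term. The packaged
  `data/curated_annotation.tsv` is different in kind: a static curated
  snapshot of ~40 real mouse genes used in worked examples.
* **Determinism.** One integer seed drives a single `numpy`
  `default_rng` stream; identical configs give bit-identical matrices.

What the generator does *not* emulate: gene–gene correlation outside
the planted block, library-size or GC biases, count noise at low
expression, and outlier samples. Passing recovery tests therefore
demonstrate correctness of the inference machinery under the model's
assumptions, not robustness to real-data pathologies.

## Problem sizes and numerical choices

The recovery experiments use 50 replicates of 800–1000-gene matrices
(planted fraction 0.1), the coexpression null 10⁵ independent pairs,
and the DEG null 200 replicates of 250 genes — sizes at which the
Monte-Carlo standard errors are well below the margins being asserted.
Tolerances: row standardization and score orthogonality to 1e-8–1e-9;
PCoA distance preservation to 1e-6 (measured ~1e-13); PLS-DA
oracle-agreement to 1e-3 radians (measured ~2e-6). Ties in ranked
tables break alphabetically; degenerate inputs (zero-variance genes,
zero group means, empty truth tables) are handled explicitly as
described above.

## Known limitations

* The Welch stand-in's mild conservativeness at n = 6 (above); any
  engine reproducing a specific upstream tool's q-values would have to
  be plugged in via `test_fn`.
* A candidate screen at |r| ≥ 0.90 with n = 6 + 6 has limited per-gene
  power near |log2FC| = 0.4 at within-group SD 0.1: the probability of
  passing rises from ≈ 0.63 at δ = 0.4 to ≈ 0.99 at δ = 0.6, so a
  uniform-[0.4, 0.6] planting yields ≈ 0.86–0.89 pooled recovery, not
  ≳ 0.95. This is a power fact about the design, visible in the
  acceptance report, not a tunable of the implementation.
* Gene identity is by case-sensitive symbol; no synonym or ortholog
  resolution.
* Multi-class (three-group) PLS-DA, sparse/regularized PLS, VIP
  scores, partial correlations and network inference are out of scope.
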