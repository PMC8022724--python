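# Methods

`phenolink` quantifies how the similarity of phenotypic profiles — each
mutant strain's vector of fitness z-scores across growth conditions —
predicts shared gene function, and how much of that signal survives
converting quantitative scores to qualitative calls. This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic data does and does not establish.

## Fitness matrices and imputation

The primary input is a strains × conditions matrix of fitness scores scaled
to a standard normal distribution within each condition (negative =
decreased fitness). Missing measurements are replaced by the population mean
before any pairwise computation. "Population" is read as *per condition* by
default: since columns are standardized, the condition mean (≈ 0) is the
natural population, and per-condition imputation preserves each column mean
exactly. A `scope="global"` variant uses the grand mean. Pipeline order is
impute-then-filter: imputation precedes any condition or strain exclusion.

## Profile-similarity metrics

* **|PCC|** — absolute Pearson product-moment correlation. Sensitive to
  shared outliers by construction.
* **|SRCC|** — absolute Pearson correlation of average ranks; invariant
  under strictly monotone transforms.
* **MI, discrete** — plug-in estimate
  `MI = Σ p̂(x,y) ln[p̂(x,y)/(p̂(x)p̂(y))]` over empirical joint
  frequencies, in nats. Zero-probability cells contribute 0.
* **MI, continuous** — each profile is coded into equal-frequency bins
  (default `⌊√(n/5)⌋`, minimum 2) by ordinal rank, then the discrete plug-in
  estimator is applied. This replaces the kernel-density estimator that
  R's `mpmi::cminjk()` provides: the binned plug-in is dependency-light,
  exactly testable against closed-form entropies, and rank-invariant. The
  bin count is a parameter.

The plug-in estimator is biased upward on independent data by approximately
`(K−1)²/(2n)` nats for K bins (Miller–Madow). At the auto bin count this
null floor is non-negligible (≈ 0.09 at n = 5000, K = 31) and is a
deterministic property of the estimator, not corrected for: rankings, not
absolute MI values, drive every downstream analysis, and the bias is
constant across pairs of equal length. Tests pin the null floor to its
analytic value.

Zero-variance profiles raise an error rather than propagating NaN, so
degenerate strains surface early. Pairs are emitted once, ordered
`gene_a < gene_b` lexicographically; ranking ties break by pair id, making
every output deterministic.

## FDR discretization, stress collapsing, n-bin grading

Because scores are standard-normal z-scores within condition, each cell gets
a two-sided p-value `2·Φ(−|z|)`; Benjamini–Hochberg step-up at α = 0.05
*within each condition* defines significant phenotypes (the published
analysis states a 5% per-condition FDR without naming the procedure; BH is
the default and the procedure is isolated behind one function). Significant
cells become `sign(z)`, everything else 0 — the ternary matrix.

Concentration series: each stress groups the conditions probing one
treatment at several doses. Collapsing keeps, per (strain, stress), the call
of the condition with maximal |z| ("most significant concentration"); ties
break to the first condition in column order. A nonzero collapsed call
therefore always equals some member condition's call — sign is never
invented.

n-bin grading (odd n ≥ 3): non-significant cells stay in the center bin;
each condition's significant tail of each sign is split into `(n−1)/2`
equal-frequency sub-bins of |z|, more extreme → larger magnitude. Sub-bins
are assigned from *average* ranks so exactly tied scores (e.g. an overwritten
auxotroph block) share a sub-bin; splitting ties by storage order would
inject row-order noise. `n = 3` reproduces the ternary matrix cell-for-cell.

## Wang semantic similarity

GO biological-process terms form a DAG with typed child→parent edges. For a
term A, every ancestor t gets an S-value by dynamic programming in
topological order, `S_A(A) = 1`,
`S_A(t) = max over children t′ of t within A's ancestor DAG of
w(t′→t)·S_A(t′)`, with relation weights `w_is_a = 0.8`, `w_part_of = 0.6`
(the constants the standard GOSemSim implementation uses; configurable).
Term similarity is `Σ_shared (S_a(t)+S_b(t)) / (SV(a)+SV(b))`. Gene
similarity combines term similarities by best-match average (BMA): the mean
of every row and column maximum of the term-pair similarity matrix. BMA is
an assumption — the combine rule is not stated in the source analyses — and
is pluggable. Annotations are used as given (no ancestor propagation):
ancestry already enters through the S-values. Cross-namespace comparison is
an error. Genes without terms raise an error; callers restrict to annotated
genes, mirroring analyses limited to the annotated fraction of a strain
collection.

Only `is_a` and `part_of` edges are read from OBO files; other relationship
types are logged and skipped, matching the two weighted relations above.

## Evaluation

Co-annotation: a gene pair is positive if it shares ≥ 1 term in any
(`union`) or every (`intersection`) annotation set; unannotated genes yield
negative pairs. Precision at rank n is TP(n)/n over the similarity-ranked
pair list (dense ranks after deterministic tie-breaking). Precision-recall
uses the top-k window (default k = 5000) with the recall denominator the
positives *within that window*, so recall reaches 1 at k; a flag switches to
global positives. A window with zero positives returns flagged zeros rather
than erroring, so batch runs complete.

Negative controls: a uniformly permuted ranking of all pairs (its expected
precision is the co-annotation base rate at every rank) and a uniform
without-replacement sample of pairs. Group permutation test: observed mean
pairwise similarity of a gene group versus `n_perm` (default 1000) random
same-size groups; `p = (# null means strictly greater)/n_perm`, ties
counting for the null (they have measure zero for continuous similarity).
The one-sided Mann–Whitney U test ("co-annotated greater" by convention)
uses an exact distribution for small tie-free samples and the tie-corrected
normal approximation otherwise. Box summaries use linear-interpolation
(type-7) quantiles and 1.5·IQR whiskers; MI distributions may be
log10-transformed after adding 10⁻⁶ to eliminate zeros, with
above-cutoff fractions always computed on raw values.

## Synthetic data: the stated world

The generator emulates a genome-scale chemical-genomics screen at desk
scale. Defaults: 400 strains × 40 stresses × 3 concentrations = 120
conditions; 12 disjoint modules of 4–8 genes; within-module correlation
ρ = 0.8; signal fraction 0.75; 30 auxotrophs; 10 minimal-media conditions;
auxotroph score −6; missing rate 0.17%. The full-scale geometry
(≈ 4000 × 324, 114 stresses) is a supported configuration.

* **Module signal.** On a module's responsive conditions (a
  `signal_fraction` of the non-minimal columns), member scores are
  `√ρ·z + √(1−ρ)·ε` with a shared per-condition latent z, giving expected
  within-module Pearson correlation ρ there and ≈ `signal_fraction·ρ`
  overall. Columns are re-standardized (population sd) afterwards, so
  marginals stay standard normal. Consequence: planted cells are *not*
  enriched for FDR significance — the ternary matrix is sparse and its
  functional signal modest, which the evaluation criteria accommodate by
  comparing against permuted controls rather than absolute precision.
  `signal_fraction = 0.75` keeps the planted correlation (≈ 0.6) well above
  the extreme null correlation at 120 conditions (≈ 0.4 across 79,800
  pairs); responsive conditions are drawn from non-minimal columns so the
  auxotroph block is the only minimal-media signal.
* **Attenuation caveat.** If one module is a large fraction of all strains,
  column re-standardization absorbs part of the shared latent and the
  realized correlation drops below ρ; recovery of ρ holds when modules are
  small relative to the population, as in any realistic screen.
* **Auxotroph block.** Selected strains get the auxotroph score on every
  minimal-media condition, *overwriting* the background so the outlier
  magnitude is guaranteed. Strains are picked round-robin across modules
  first, then from background: auxotroph pairs are then mostly
  non-co-annotated, reproducing the artifact in which unrelated
  biosynthetic-gene mutants correlate strongly through shared minimal-media
  outliers.
* **Annotation sets** assign each module one term covering a random
  `coverage` fraction of members, independently per set — emulating how
  pathway, complex, and operon annotations partially disagree.
* **Toy GO** is a complete branching-tree DAG with edges typed `part_of`
  with a given probability; each module's genes share one leaf and ≈ 66% of
  background genes get a random leaf (the annotated fraction seen in real
  strain collections).
* **Missing values**: exactly `round(rate·cells)` positions, uniform without
  replacement.
* **Determinism**: each generation stage draws from its own stream spawned
  from the master seed, so stages regenerate independently; identical
  config + seed reproduces bit-identical data.

What a green end-to-end test establishes: the *relative* behavior of the
metrics (outlier sensitivity of |PCC|, robustness of rank/MI metrics,
signal retention after discretization, calibration of the permutation
machinery) on data with planted truth. What it does not establish: absolute
precision levels of the published analysis, which depend on the external
screen and specific database releases; replicate correlation structure
within a stress (replicates are independent here, a neutral default since
no dependence is specified); plate effects or the normalization that
produced the original z-scores.

## Known limitations

* The continuous-MI estimator differs from the kernel estimator used in the
  original analysis; estimates are comparable as rankings, not as values.
* Condition replicates within a stress are statistically independent in the
  generator.
* The pipeline assumes scores are already standard-normal per condition; it
  does not re-derive scores from raw colony sizes.
* `group_permutation_test` resamples gene sets, not profiles' condition
  structure; with very small universes the null is granular.
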