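# Methods

This note documents the statistical procedures implemented in `goadf`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Resampling design

Samples are partitioned by a stratified outer 5-fold split (per-class
seeded shuffle, round-robin block assignment; remainders go to the
earliest blocks, so within-class block sizes differ by at most one). Each
outer-training set is partitioned again into stratified inner 4-folds.
A *feature-selection set* is one (repeat, outer fold, inner fold) cell:
three inner blocks select features and grow the tree, the held-out inner
block (*feature evaluation*) scores it, and the held-out outer block
(*internal test*) is touched only by the final top tree. Both levels are
re-randomized on every repeat; repeat r draws its streams from
`SeedSequence(seed, spawn_key=(r,))` so any repeat is reproducible in
isolation. Stratification is imposed because unbalanced cohorts (e.g.
101 cases vs 19 controls) would otherwise produce near-empty control
blocks that break the two-sample statistics downstream.

## Differential expression (SAM)

For feature i, `d_i = (x̄_case − x̄_ctrl)/(s_i + s0)` with the pooled
standard error `s_i = sqrt((1/n1 + 1/n2)·(SS1 + SS2)/(n1 + n2 − 2))`. The
fudge constant `s0` stabilizes low-variance features; it is chosen from
the percentiles of `s` (0–100, step 5) as the value minimizing the
coefficient of variation of `|d|` across features, and can be overridden.
Significance is a two-sided permutation test on class labels: when the
number of distinct case assignments `C(n, n1)` does not exceed `n_perm`
every assignment is enumerated and `p = #{|d*| ≥ |d|}/n_assignments`
(identity included, so p > 0); otherwise `n_perm` shuffles are sampled
with `p = (1 + #{|d*| ≥ |d|})/(n_perm + 1)`. Tie comparisons use a 1e−9
relative slack because `|d*|` and `|d|` travel different arithmetic
paths. Default `n_perm = 500`, threshold `P < 0.05`; a q-value/FDR layer
is deliberately out of scope since the method thresholds on P.

## Co-expression sets and key members

Differentially expressed features are linked whenever their Pearson
correlation exceeds `r > 0.6` (signed by default; an absolute-value mode
exists) with two-sided `P < 0.05` from the t-transform on n − 2 degrees of
freedom. Co-expression sets are the connected components of this graph —
"co-expressed" is read as transitive linkage, not cliquehood — and
singletons are allowed. Within each set, key members are those passing a
two-sample t-test at `P < 0.01`; Welch's form is the default (serum
cohorts are typically unbalanced and heteroscedastic), Student's pooled
form is available. A set may contribute zero, one, or several key members;
a feature-selection set with no key members yields an explicit empty tree
record that simply fails QC later.

## Tree growth

Trees are plain binary CART: at every node the (feature, threshold) pair
maximizing the Gini impurity decrease is found by exhaustive search over
midpoints of consecutive sorted distinct values (entropy impurity is
selectable). Conventions fixed for determinism: left branch `< threshold`,
right branch `≥ threshold`; impurity-decrease ties break to the lowest
feature index, then the lowest threshold; leaf labels are the majority
class with ties to the control class. There is no pruning.

Stopping: a node becomes a leaf when pure, smaller than
`min_samples_split`, or when no admissible split (both children
≥ `min_leaf`) improves impurity. `build_tree` defaults to
`min_leaf = 2, min_samples_split = 4` (growth essentially to purity, the
right default for tiny worked examples), but the **pipeline** default is
`min_samples_split = 20`, the classic CART/rpart stopping value. The
reason is structural: with ~100 training samples and moderately
overlapping classes, purity growth produces 8–11 leaves from ~5
informative miRNAs, so almost every tree must reuse a feature and the
duplicate-feature QC stage would empty the forest. Stopping at 20-sample
nodes yields the intended regime — signatures of 3–6 distinct miRNAs with
roughly a quarter to a half of trees passing the structural filter.

Prediction returns both the leaf's class label and its training
case-proportion as a continuous score; the score is what makes ROC
analysis of a hard-labelled tree possible. This leaf-proportion scoring is
a documented design choice (see Limitations).

## Decision forest and quality control

The forest pools every non-empty tree. `freq[m]` counts the trees whose
signature contains miRNA m; the *forest mean frequency* is the mean of
`freq` over all distinct miRNAs appearing anywhere in the forest, and a
tree's *mean frequency* is the mean of `freq` over its own signature —
this reading makes the two quantities commensurable. The QC funnel is
applied in a fixed order, each stage reported:

1. drop trees with a duplicated feature or fewer than 3 signature miRNAs;
2. keep trees whose **minimum** single-miRNA AUC on the feature-evaluation
   block exceeds 0.7 (the strictest reading of "single AUC > 0.7";
   a mean-AUC mode is available);
3. keep trees whose mean signature frequency strictly exceeds the forest
   mean (this stage can be disabled — with a strict `>`, a degenerate
   forest in which all frequencies are equal would discard every tree);
4. keep trees with accuracy, sensitivity and specificity each > 0.5.

## Entropy-weight ranking

Factors are standardized over trees within each factor,
`p_ij = x_ij/Σ_i x_ij` (indices read as: normalize over trees i, weight by
factor j). Each factor's dispersion is its normalized Shannon entropy
`E_j = −(1/log₂ n) Σ_i p_ij log₂ p_ij` with `0·log 0 := 0`, so `E_j ∈
[0, 1]`; weights are `W_j = (1 − E_j)/(k − Σ_j E_j)`, non-negative and
summing to one, with constant factors receiving weight zero. The score is
`ST_i = Σ_j p_ij W_j`, ranked descending with ties broken by tree id.
Two audit modes exist and are **not** defaults: a "literal" entropy
(`Σ p log₂ p`, unsigned and unnormalized — it yields negative entropies
and weights outside [0, 1]) and raw-x scoring (`Σ_j x_ij W_j`, which mixes
incommensurate scales such as frequency counts with AUC proportions; the
standardization step exists precisely to avoid this).

## Label-shuffle significance

Labels are shuffled (feature and sample counts unchanged) and the entire
pipeline is rerun per shuffle. Each shuffle contributes one null draw of
the top tree's ST, signature mean frequency and synergistic AUC; a shuffle
whose forest does not survive QC contributes −∞ (it certainly did not
beat the observed tree). Empirical
`p = (1 + #{null ≥ observed})/(n_shuffles + 1)`, using `≥` in the tail and
+1 smoothing, so p ∈ (0, 1]. The default `n_shuffles = 1000` is a
compute/precision compromise; at least 100 is recommended, and the
implementation warns below that. Because each shuffle applies the exact
observed-data pipeline, the p-value is valid by exchangeability even
though ST is standardized within each run.

## Evaluation

AUC is the Mann–Whitney rank statistic with 0.5 per tied pair, case class
positive, and **no score flipping** — sub-0.5 AUCs are reported as-is.
Confidence intervals, when requested, use stratified percentile bootstrap
(default 2,000 resamples, seeded). Confusion metrics follow the standard
definitions; F-measure is defined as 0 (with a warning) when there are no
positive predictions. Comparator methods (SAM and t-test panels scored by
a Fisher linear discriminant, a single CART, a Fisher discriminant and a
k = 5 nearest-neighbour posterior on the top t-test panel) reconstruct
the customary usage of each selector for benchmarking; singular
within-class scatter in the discriminant is ridge-regularized.

External cohorts are evaluated with split values frozen by default; a
`refit` flag regrows thresholds on the external cohort (restricted to the
original signature) and logs that it did so.

## Synthetic data

The generator produces unit-variance Gaussian intensities: equicorrelated
modules (`x = √ρ·g + √(1−ρ)·ε`, pairwise correlation ρ within a block,
zero across), independent N(0, 1) elsewhere, and planted markers whose
case mean is shifted by δ within-class standard deviations — one marker
per module by default, so a recovered panel must combine markers across
distinct co-expression blocks. Defaults (500 features, 80/80 samples,
four ρ = 0.7 modules of five features, four markers at δ = 1.5) are a
scaled-down analogue of a serum microarray cohort with a few thousand
probes. Deliberately **not** emulated: microarray background/batch
artifacts, heavy-tailed or count-like intensity distributions,
normalization effects, correlated marker effect sizes. Passing tests on
this generator therefore demonstrate algorithmic correctness and
end-to-end recovery under a clean Gaussian co-expression model, not
robustness to real microarray noise.

## Problem sizes used by the test suite and acceptance script

End-to-end checks run at reduced depth chosen as sensible desk-scale
experiment sizes: recovery experiments use 10 resampling repeats (200
feature-selection sets) with 250 SAM permutations per set (at δ = 1.5 the
differential-expression calls sit far from the 0.05 threshold, so the
halved permutation count does not change selection); the shuffle-null
calibration uses single-repeat pipelines; the acceptance script uses 10
repeats, the default 500 SAM permutations and a 30-shuffle null.

## Numerical choices

Impurity-decrease acceptance and tie comparisons use a 1e−12 floor;
permutation tie counting uses 1e−9 relative slack; correlation values are
clipped away from ±1 before the t-transform; sums of squares computed via
the `E[x²] − n·x̄²` identity are floored at zero; `float_precision=
"round_trip"` parsing keeps read→write→read cycles bit-identical.
Degenerate inputs are handled explicitly: zero-variance features give
d = 0 (never significant) and are kept as clustering singletons;
single-class nodes or selection sets yield single-leaf trees / empty
records that fail QC rather than raising mid-pipeline; an all-zero factor
column is dropped from the factor matrix with a warning; a lone QC
survivor is reported without an ST (entropy needs at least two trees).

## Known limitations

* **Synergy vs strong single markers.** A CART panel emits only a handful
  of distinct leaf-proportion scores, so its ROC curve is coarse. When
  individual markers are already strong (δ = 1.5 gives a theoretical
  single AUC ≈ 0.86, and the best of four on a small evaluation block
  concentrates near 0.95), the panel's synergistic AUC statistically
  matches, but does not reliably exceed, the best single marker: across
  20 seeded recovery runs the mean synergistic-minus-best-single margin
  on the feature-evaluation block is ≈ −0.006, with the panel winning
  about half the runs. The synergy advantage materializes when single
  markers are individually weak — the regime the method targets — and a
  smoother score (e.g. within-leaf interpolation) would be needed to
  claim it against strong singles.
* ST values are standardized within a run and are not comparable across
  runs with different numbers of surviving trees; only ranks and
  shuffle-null p-values transfer.
* The pipeline is serial; 100 repeats × 500 permutations on a
  2,500-feature cohort is minutes-to-hours territory on one CPU.
  Vectorized SAM keeps each feature-selection set at tens of
  milliseconds.
* Expression values are used as supplied: no normalization or log
  transform is applied by default (an explicit `log2` flag exists),
  and missing values are handled by dropping features (default) or
  median imputation, never model-based imputation.
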