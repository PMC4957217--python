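# Methods

## Feature model

A protein is represented by its g-gap dipeptide composition: the frequencies
of the 400 ordered residue pairs at positions (i, i+g+1). The feature index
is fixed as eps = 20·a + b with residues coded alphabetically
(A=0 … Y=19), i.e. AA, AC, …, YY row-major; exports embed the gap in the
column name (`WL.g6`) so matrices from different gaps cannot be mixed
silently.

**Denominator.** The default normalizer is L − g − 1, the number of g-gap
pairs actually present, which makes each vector an exact probability
distribution (sum = 1, checked to 1e-12 in tests). A `denominator="length"`
switch divides by L instead, for compatibility with formulations that
normalize by protein length; vectors then sum to (L−g−1)/L < 1. All
downstream statistics accept either, but the distribution reading is the
default because F-scores and SVM kernels behave better on commensurate rows.

**Validation.** Only the 20 standard amino acids are accepted. Ambiguity
codes (B, J, Z, X), selenocysteine/pyrrolysine (U, O), stops and gaps make
the composition undefined, so they are rejected, skipped, or stripped
according to an explicit input policy; stripping that empties a sequence
drops it with a logged count. Sequences shorter than g + 2 have no g-gap
pairs and raise a length error naming the record (or are skipped per g
during a sweep).

## Feature scoring

Each feature is scored with the classical two-group one-way ANOVA F:
between-group mean square (1 degree of freedom for two groups) over pooled
within-group mean square (m_p + m_n − 2 degrees of freedom). For two groups
this equals the square of the pooled-variance t statistic, which the test
suite asserts against scipy at 1e-9 relative tolerance. At least two samples
per class are required, otherwise the within-group variance is undefined.

Degenerate features follow two conventions. A feature constant across all
samples carries no information and gets F = 0 (the 0/0 case). A feature with
zero within-group but positive between-group variance separates the classes
perfectly; it gets F = +inf and ranks above every finite value, with ties
among such sentinels broken by |x̄_p − x̄_n| descending and then by
dipeptide name. Finite ties are broken by ascending dipeptide name, so
rankings are deterministic and seed-free.

The signed normalized score is sgn(x̄_p − x̄_n) · (F − F_min)/(F_max − F_min)
with F_min/F_max taken over the finite scores; sentinels map to ±1. The
top-ranked feature therefore always has magnitude exactly 1 and the
lowest-F feature maps to 0. If every feature has the identical F the
normalization is undefined and an explicit error suggests checking for
signal. The 20 × 20 arrangement of these scores (first residue by row,
second by column) is the preference matrix; its numeric export is
sign-explicit (+ = positive-class enriched) because color conventions for
such heat maps vary between publications, and the plotting helper exposes a
`flip_colors` switch rather than guessing. The per-residue summary is the
mean signed score over a residue's row plus its column (mean, not max, so a
single extreme pair cannot dominate the marginal).

## Classifier and evaluation

The classifier is an RBF-kernel SVM (scikit-learn's SVC). C and γ are
chosen by grid search over the canonical exponential grid C ∈ 2^{−5, −3, …, 15},
γ ∈ 2^{−15, −13, …, 3}, scored by cross-validated overall accuracy with all
grid points sharing one seeded fold split; ties resolve toward smaller C,
then smaller γ. Compositions already live on a common [0, 1] scale, so no
feature scaling is applied, no class weighting is used (imbalance is
handled only through OA optimization), and the decision threshold is the
SVM's native sign.

Cross-validation is stratified k-fold (default k = 5) with seeded
shuffling; confusion counts are pooled over folds before Sn, Sp and OA are
computed, so OA is exactly the N⁺/N⁻-weighted mean of Sn and Sp. The
jackknife variant is leave-one-out and therefore deterministic and
seed-independent. Trained models persist with a format version, the gap,
the feature subset and (C, γ); loading refuses other versions.

## Incremental feature selection

IFS evaluates every prefix of the F-ranking (sizes 1..400). Two choices
matter:

- **Folds are fixed once per (g, seed)** and reused for all 400 prefix
  evaluations, so the curve reflects feature-set changes only, not
  fold-resampling noise.
- **Hyperparameters:** by default (C, γ) is re-optimized at each step on a
  coarse 3 × 3 grid (C ∈ {2⁻¹, 2³, 2⁷}, γ ∈ {2⁻⁷, 2⁻³, 2¹}); the `fixed`
  mode (CLI `--fast`) grid-searches once on the full 400-feature set and
  reuses that point for all prefixes. The fixed mode is roughly an order of
  magnitude faster and is what the heavier end-to-end tests use; on
  strongly separable data the two agree on the optimum.

The optimal subset is the smallest prefix attaining the maximal OA
(parsimony tie-break). In a g-sweep, ties across gaps resolve toward
smaller g, then smaller subset size. The `top_k_model` analysis entry point
shares the fold construction and hyperparameter policy with IFS, so its
report coincides with the curve point at size k under the same seed.

## Synthetic data

The generator emulates a curated two-class protein benchmark: by default 53
positive and 136 negative sequences with lengths uniform on [100, 500] and
residues i.i.d. uniform over the 20 amino acids (a 20-vector of background
frequencies can be supplied). Class signal is planted by positional pair
injection: for each planted pair (a, b) assigned to a class, every valid
start position i of that class's sequences is independently overwritten
with probability `effect` so that positions (i, i+g*+1) read (a, b).
Injection places the signal exactly at gap g* by construction — only the
marginal single-residue enrichment leaks to other gaps — which is why it is
preferred over frequency rejection-sampling. A spec whose total injected
frequency would exceed 1 in either class is rejected as infeasible. The
default planted pairs use residues characteristic of lipid-binding helical
proteins (L, F, I, W enriched in positives; C, E, K, P in negatives).

With effect = 0 the classes are exchangeable and the generator is a
calibration null: across 200 replicates at 100 samples per class, the
fraction of features with ANOVA p < 0.05 measures the F-machinery's type-I
error (observed ≈ 0.049, asserted within 0.05 ± 0.01). What the generator
does **not** emulate: realistic amino-acid background frequencies (uniform
by default to keep the null clean), length–class correlations, homology
structure, or any evolutionary model. Passing recovery tests therefore show
the pipeline finds planted compositional signal at the right gap; they do
not certify performance on real proteomes, where signal is weaker and
correlated with phylogeny.

## Problem sizes in the test suite

Unit tests use small planted datasets (10–100 sequences per class) chosen
so the full 400-point IFS curves and g-sweeps run quickly while remaining
clearly separable at effect sizes 0.03–0.06. The end-to-end recovery check
uses 100 sequences per class, lengths 120–400, 20 planted pairs at g* = 6
with effect 0.03, a reduced g-sweep {0, 3, 6, 9}, and fixed-mode IFS; the
calibration check uses 200 null replicates at 100 per class. These sizes
are the package's own desk-scale defaults for self-verification.

## Known limitations

- The F-score treats features marginally; compositional correlation between
  the 400 frequencies (they sum to 1) is ignored, as is standard for this
  filter-style selection.
- The default (non-nested) protocol reuses the same cross-validation folds
  for hyperparameter search and reporting, which can be optimistically
  biased; IFS likewise selects the subset size on the same folds it
  reports. This matches the common practice the pipeline reproduces; a
  nested protocol would require an outer loop the package does not
  currently implement.
- Perfect-separation sentinel features (F = +inf) arise easily at small
  sample sizes; their ±1 signed scores compress the finite scores' scale in
  the heat map.
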