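# Methods

## Model overview

`omicforest` classifies samples described by several per-modality numeric
feature tables (methylation-like, expression-like, copy-number-like) into
C ordered classes.  Each modality gets its own weighted deep forest —
multi-grained scanning followed by a cascade of forest layers — and the
per-modality probability outputs are combined by accuracy-weighted
decision-level fusion.  The model assumes tabular numeric features with a
fixed column order (windows are contiguous feature slices, so feature
order matters to scanning), complete rows after load-time filtering, and
at least a handful of samples per class.

## Input filtering

Loaders accept delimited text with a header row and a sample-id column.
NA tokens (empty, `NA`, `NaN`, `null`, case-insensitive) are recognized;
columns more than 50% missing are dropped first, then any column still
containing a missing value.  The order of the two rules is fixed so
filtered column counts are reproducible.  Samples are never imputed; they
are only removed when multi-modal alignment finds them missing from some
modality.

## Feature selection

L1-penalized (lasso) embedded selection, either with an explicit budget z
on the coefficient L1 norm (squared-error loss on the class codes) or to
an exact retained count.  For exact counts the default loss is
one-vs-rest L1 logistic regression — the natural embedded selector for a
multinomial label — with the selected set being the union of nonzero
coefficients over classes; the squared-loss variant remains available via
`loss="squared"`.  Because no penalty value maps a priori to a desired
count, the penalty strength is bisected (up to 50 steps on a log grid)
until the count lands within ±2 of the target, then the set is trimmed or
extended by coefficient magnitude (a weak-penalty reference fit ranks the
features the working penalty zeroed).  Features are standardized
internally by default; the flag is exposed because raw-scale selection is
sometimes wanted for bounded beta values.  Tables with at most 50 columns
skip selection entirely — the copy-number case, where the raw column
count is already below any sensible target.

## HUM and the forest weights α

The two scanning forests are weighted by their HUM — the hypervolume
under the ROC manifold, the C-class generalization of AUC.  We use the
argmax-concordance estimator: a one-per-class tuple of samples counts as
concordant when every member's own-class score is its row maximum (ties
toward the lowest class index).  Because concordance is a per-row
property, the fraction of concordant tuples over the full enumeration
factorizes exactly into the product of within-class top-1 accuracies,
which the implementation computes in O(nC); enumeration-based subsampling
is therefore unnecessary at any sample size.  The estimator is
parameter-free, equals 1 for a perfect classifier and (1/C)^C in
expectation for label-free scores.  A rank-order (Scurfield-style)
variant would also be defensible; it is noted as an extension, not
implemented.

HUM₁ and HUM₂ are measured on each forest's out-of-bag class
probabilities over the window instances.  Out-of-bag estimates were
chosen over a further data split because the scanning stage already
multiplies a small cohort into many window instances and a dedicated
split would shrink the effective training set; instances never out of bag
(possible with few trees) receive a uniform probability row.  The weights
are α₁ = HUM₁/(HUM₁+HUM₂), α₂ = 1 − α₁; both zero degrades to (½, ½) with
a warning.

## Scanning and the window weights β

Windows of length L at stride S (default 1) yield V = ⌊(M−L)/S⌋ + 1
positions; a ragged tail when S does not divide M−L is discarded.
Default window lengths are ⌈M/4⌉, ⌈M/2⌉, ⌈3M/4⌉ — (100, 200, 300) for
M = 400 — adapting automatically to small tables.  Window instances
inherit their parent sample's label (the standard deep-forest
convention).  A sample's scan vector per window is
concat(RF-vec·α₁, cRF-vec·α₂), length 2·V·C.

The sorting-optimization statistic rates each window: per sample, sort
the α-weighted scan vector descending and average the top
max(1, ⌊2VC/C⌋) entries — confidence concentrated near 1 signals a
discriminative window.  The α-weighted (not β-weighted) vector is used
because the window rating logically precedes the window weighting.
Averaging over training samples gives W_t, and β_t = W_t/ΣW.  The
transform multiplies each window's vectors by β_t *before* the cascade
consumes them; scaling before concatenation is an interpretation choice
(the alternative — rescaling inside the cascade — would be equivalent up
to where the constant lands) and is fixed here for determinism.  Forcing
α = (½, ½) and uniform β recovers the standard unweighted scanner output
times the constant 0.5/T, which the test suite verifies elementwise.

## Cascade

Each layer holds two random forests and two completely random forests
(random split feature, random threshold, grown to purity — realized as
extremely randomized trees with one candidate feature per split).  Layer
1 consumes the shortest window's vector; layer k ≥ 2 consumes the
previous layer's 4·C augmented vector concatenated with window
((k−2) mod T) + 1 in ascending-length order, so the granularities cycle
as the cascade deepens (1806 → 1818 → 1218 → 618 in the 400-dim worked
example).  Augmented vectors used to train the next layer come from
k-fold cross-fitting within the layer (default k = 3, reduced when a
class is smaller than k); validation and test samples use the full-data
fits.  Growth stops at the first layer whose validation accuracy fails to
exceed the running best by more than `stop_tol` (default 0, patience one
layer); the model is truncated to the best depth.  A `fixed_depth` mode
grows an exact number of layers without validation — used when refitting
at a depth already chosen by inner CV.  A `max_depth` cap (default 10)
bounds runtime on adversarial inputs.  Prediction averages the last
layer's four probability vectors; argmax ties break toward the lowest
class index everywhere in the package.

## Fusion γ and nested cross-validation

The evaluation protocol is nested CV: stratified outer folds (default 10)
for the error estimate, inner folds (default 10) within each outer
training set for everything tunable.  Per modality and inner fold,
feature selection is refit on the inner training split only, the scanner
and cascade are fit with early stopping on the inner validation fold, and
the validation accuracy is recorded.  The median of the inner best depths
fixes the cascade depth for a refit on the full outer training set — the
refit gets more data and needs no further split, at the cost of trusting
the inner-CV depth choice; this resolves the genuine ambiguity of which
split should drive early stopping in a nested design, and the inner
validation fold (never the outer test fold) is likewise what γ is
measured on, so no test information leaks into the weights.
γ_p = acc_p/Σacc normalizes the inner-CV accuracies; the fused model is
applied exactly once per outer fold.  Fold assignment deals each
shuffled class round-robin across folds, so fold class proportions match
the cohort's within one sample and classes smaller than the fold count
degrade gracefully with a warning.  Outer-test ids are asserted disjoint
from every inner fit.

Reported metrics: accuracy, macro precision/recall/F1 (macro because the
target cohorts are imbalanced and a majority class would otherwise
dominate), macro one-vs-rest AUC (the multi-class ROC averaging is a
documented choice), and HUM.

## Synthetic data

The generator emulates a three-modality staging cohort: default class
sizes (31, 49, 8) — a 1/5-scale version of a 155/243/41 stage I/II/III
split, the fourth stage being too rare to model — and default widths
(340, 320, 39).  A per-sample latent stage factor z = class code +
N(0, 0.25²) drives all modalities: informative features (defaults 25, 25,
8 per modality, ~7–20% of columns) add effect_size · noise_sd · s_j · z
to N(0, noise_sd²) noise, where the loading signs s_j are correlated
across modalities with probability controlled by `cross_modality_rho`
(default 0.5, a shared-but-not-identical signal).  The latent jitter sd
0.25 makes adjacent classes separable in principle (per-boundary Bayes
error ≈ Φ(−2) ≈ 2.3%), so a strong planted effect is genuinely learnable,
while the ordinal structure keeps the selection and HUM stages
meaningfully ranked.  Default effect_size 1.0 gives a moderate,
staging-like signal.  Value transforms: methylation columns are squashed
to (0,1) by a logistic map of their z-scores; expression columns get a
per-gene N(6, 2²) baseline (log-TPM-like); CNV columns are z-scored,
scaled, rounded and clipped to integers in [−2, 2].

What the generator does *not* model: methylation beta-value bimodality,
batch effects, count overdispersion, copy-number segment structure, or
feature-feature correlation beyond the shared latent factor.  Passing
tests therefore demonstrate that the pipeline recovers a planted
low-dimensional ordinal signal under realistic shapes and ranges — not
that it reproduces performance on any real cohort.

## Problem sizes used by the checks

The architecture-dimension checks run on 12 samples with 5-tree forests —
the measured dimensions are structural and independent of sample count.
The planted-signal nested-CV check runs at desk scale: 60 samples per
class, modality widths (100, 100, 39), outer 5 / inner 3 folds, 50 trees
per forest.  The permutation-null check uses a balanced 20-per-class
design at widths (40, 40, 20) with outer 3 / inner 2, where any
label-independent classifier has expected accuracy exactly 1/3.  Tree
counts of 300 (the recommended production setting) behave the same way;
the smaller counts keep the full suite in the minutes range.

## Numerical and degenerate-input choices

Single master seed fans out via a keyed hash to every forest, fold
shuffle and subsample, so refits are bit-identical.  Weight
normalizations (α, β, γ) are exact up to 1e-12 and checked on every fit.
All-zero window abilities fall back to uniform β with a warning; all-zero
modality accuracies are an error (there is no sensible fusion).  Argmax
ties break toward the lowest class index.  Columns with zero variance are
tolerated everywhere except an all-constant selection input, which is an
error.

## Known limitations

Scanning assumes feature order carries locality; on unordered omics
columns the windows are arbitrary slices, which matches the method being
implemented but means β mostly reflects window *length* rather than
position-specific structure.  The cascade refit after inner CV trusts the
median inner depth; a pathological split could choose a depth the full
outer-train set would not.  HUM on very small classes is coarse (top-1
accuracies in steps of 1/n_c).  Runtime grows linearly in windows ×
trees × instances; very wide tables should be feature-selected before
scanning.
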