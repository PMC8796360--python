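# Methods

This note records the models implemented in `pairclass`, the generative
model behind the synthetic cohorts, the numerical conventions, and the
design choices that were genuinely open.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

Expression matrices are genes × samples on a raw per-sample scale
(log2(TPM + 1), log2 array intensities).  No between-sample normalization
is performed anywhere.  Within-sample ranks use average ranks for ties.
Gene-pair rules are strict: `expr(A) > expr(B)` is TRUE, exact equality is
FALSE — deterministic and consistent with reading "A above B".  When both
orientations of a pair are candidates, the orientation is canonicalized
(lexicographic for neutral enumeration; toward the target class for
voters), since flipping a rule complements its value and leaves the delta
score unchanged.

Prediction output is uniform across families: per-class scores, the argmax
class, the top-vs-second margin, and a tie flag.  Exact top-score ties
report the lexicographically first tied class with the flag set — a
deterministic, auditable convention.  The evaluation harness scores a tied
call as correct only if the reported winner matches the reference.

## Predictor families

**Centroids.**  Per class, genes pass a moderated t-test (p < 0.05) and a
folded class-vs-rest AUC gate (> 0.6; folding `max(AUC, 1−AUC)` admits
down-regulated markers symmetrically — with a one-sided gate no "down"
list could ever be populated), then are ranked by mean log fold change;
the top m up and m down genes per class are pooled into a deduplicated
union.  Centroids are class means over the union, of raw values (raw mode)
or per-gene mean-centered values (centered mode; the training row means
are stored and subtracted from new samples, so prediction stays
batch-independent).  Scores are Pearson correlations.  The moderated
t-test is an empirical-Bayes variance shrinkage: gene-wise pooled
variances are shrunk toward a scaled-F prior fitted by matching moments of
log s²; the posterior variances enter the t statistic with df = residual
+ prior df.  The implementation follows the standard limma algorithm,
including the infinite-prior-df branch (arithmetic-mean prior variance,
total df capped at the summed residual df), and the test suite verifies it
against Bioconductor limma via Rscript to ~1e-8.  A plain Welch t
(`test="welch"`) is available behind a flag.

**Multiclass k-TSP.**  One binary voter per class.  Gene selection: top n
up/down by the Mann–Whitney AUC form of the Wilcoxon rank-sum statistic
(one-vs-rest, or worst-case across one-vs-one comparisons).  Candidate
pairs (within-pool, plus pool × all-other-genes when pivot genes are
enabled) are scored by (delta, gamma), oriented toward the target class,
and picked greedily under gene-disjointness.  k is fixed, or chosen in
2..10 by variance optimization: maximize the between-group mean difference
of the per-sample vote sums divided by their pooled within-group standard
deviation — the criterion is stated here explicitly so results are
reproducible.  Platform-wise variants intersect per-platform top gene sets
(falling back to best worst-case rank) and take the minimum delta/gamma
across platforms; one-vs-one rule scoring takes the minimum signed
`P(1|c) − P(1|o)` across opponents (worst-case discrimination).  Scores
are vote fractions in {0, 1/k, …, 1}, so ties are structurally possible at
small k.

**Naive Bayes on rules.**  All gene pairs are enumerated (above a
300-gene cap, genes are pre-filtered by folded one-vs-rest AUC first — the
guard keeps the quadratic enumeration desk-scale) and ranked per class by
one-vs-rest delta; with dataset weights the delta is computed per training
dataset and combined as a weighted average, damping rules that only work
in the largest dataset.  The same k for every class is chosen at the peak
of a stratified 20-fold cross-validation accuracy curve over k = 1..50
(ties toward smaller k; folds are reduced with a warning when the smallest
class cannot support 20).  The final model is a Bernoulli Naive Bayes with
class-proportion priors and Laplace smoothing α = 1 (scikit-learn's
`BernoulliNB`; α exposed in the config).  Its posteriors are
characteristically extreme — near 1 for the called class even on
out-of-distribution samples — which the tests document as a property, not
a virtue.

**Rule-based Random Forest.**  Stage 1 trains an all-classes forest and C
one-vs-rest forests on within-sample *ranked* expression and takes each
model's top G genes by impurity importance (per-class models rescue
markers of small classes that the global ranking buries); the union keeps
all-classes provenance first.  Stage 2 binarizes all pairs of the union
and repeats the importance ranking with rules as features.  Stage 3 scans
each model's ranking top-down keeping a rule only while neither gene has
been used `gene_repetition` times (default 1), takes the top R filtered
rules per model, deduplicates, and trains a probability forest.
Selection forests use mtry = 10 % of features; the final forest uses
mtry = ⌊√(#rules)⌋; all forests use 5000 trees and node size 1 by default.
The forest is a bagging ensemble of fully grown CART trees (Gini) over
binary rule features — a split *is* a rule truth test.  It is implemented
as a thin wrapper over scikit-learn decision trees because per-tree
bootstrap membership must be retained: OOB class scores average the tree
class-frequency vectors over the trees where a sample is out-of-bag, OOB
accuracy is their argmax accuracy, and the OOB proximity of two samples is
their co-terminal-node frequency over trees where both are OOB (diagonal
1 by convention; pairs never jointly OOB are NaN).  With a bootstrap of
size n, a sample is OOB with probability (1−1/n)^n → e⁻¹ ≈ 0.368, i.e.
~37 % of samples per tree and ~1850 of 5000 trees per sample; the
acceptance script measures both.

Missing genes at prediction time: rules whose genes are present are
evaluated directly; each missing rule is imputed as the modal value among
the k = 5 training samples most similar by Hamming agreement over the
evaluable rules (pairwise-complete, no global pre-imputation), mode ties
broken by the single nearest neighbour.  Prediction refuses if more than
50 % of rules are unevaluable.

**Boruta pruning.**  Each iteration augments the active rules with
per-rule permuted shadow copies, trains a forest, and scores a hit for
every rule whose importance exceeds the maximum shadow importance.  A
two-sided binomial test at α = 0.01 over iterations confirms or rejects
rules (rejected rules leave the active set); rules undecided after the
iteration cap stay tentative.  The final forest is rebuilt on the
confirmed (optionally + tentative) rules.

## Synthetic cohorts

The generator emulates a bulk tumor cohort at the summarized-matrix level,
in order: (1) per-gene log2 baselines b ~ U(3, 10); (2) class profiles
b ± e on disjoint informative gene sets (half up, half down per class),
with per-gene effects e drawn uniformly in [0.5, 1.5] × `effect_size` so
fold-change rankings are meaningful; (3) a stromal/immune background
profile: a dedicated stromal gene set shifted by `stromal_effect_size`,
and — mirroring cohorts where the mesenchymal-like subtype is
stroma-rich — the background reproduces the stroma-like class's
informative profile; (4) per-sample tumor signal with N(0, `noise_sd`)
gene noise; (5) purity mixing **on the natural scale**,
x = p·2^t + (1−p)·2^s, because dilution is additive in transcript
abundance, not in log space; (6) per-platform distortion
y = x^κ · 2^offset (power-law dynamic-range compression plus per-gene
log-normal offsets — the two mechanisms that break rules across
platforms), returned as log2(y + 1).

Defaults are chosen once to resemble a realistic bulk cohort:
`effect_size` 2 (4-fold markers), `noise_sd` 1 (combined biological +
technical spread roughly half the marker effect, which puts accuracy in
the high-0.8s/0.9s regime rather than at ceiling), purity ~ Beta(8, 2)
(mean 0.8) except the stroma-like class at Beta(3, 3) (mean 0.5; its
infiltration is what makes it hard), `stromal_effect_size` 4 — lineage
markers separating stroma/immune cells from tumor cells span far larger
ranges than within-lineage subtype markers, which is why infiltrated
samples can dominate clustering — and background variability `noise_sd`/4,
since the background is a bulk average over many normal cells and is far
less variable between biopsies than the tumor component (this is also
what makes tumor-internal rule values comparatively stable under mixing).
All randomness flows from one seed through independent counter-based
per-stage, per-sample streams: the same seed is bitwise reproducible, and
`sample_seed_offset` draws fresh samples from an identical gene-level
ground truth (held-out cohorts, purity curves).

Planted platform-specific pairs take an up-gene A and a down-gene B of one
class: on the first platform B is offset so its rest-class level sits
midway between A's rest and class levels (the informative crossover), on
other platforms B is saturated above A's range (constant-FALSE rule and no
class signal — probe failure / dynamic-range loss).

What the simulator does **not** model: read counts and library-size
effects, probe sequences, correlated gene modules beyond the class/stromal
programs, label noise, and purity estimated with error.  Passing tests
therefore demonstrate the algorithms' contracts and their relative
behavior under purity and platform stress — not clinical performance on
real cohorts.

## Problem sizes used by the tests and the acceptance script

Experiments are scaled to desk size with the statistics they probe kept
intact: recovery/tie experiments use a 5-class cohort of 1000 training
samples (200/class, effect = 4 × noise, purity 1) with selection forests
of 200 trees and a 500-tree final forest; the SSP-invariance and tie-rate
cohorts have 500 samples at default noise; platform experiments use 2 × 5
× 15-sample cohorts with 10 planted pairs over 5 seeds; Boruta runs 30
iterations of 200-tree forests against 20 planted noise rules; the margin
sweep uses 1600 genes with 250 informative per class so centroids up to
m = 125 per direction stay populated.  Forest sizes only tighten Monte
Carlo error of importances and probabilities, so conclusions are unchanged
at the 5000-tree defaults.

## Known limitations

* Impurity importances are computed as the mean of per-tree normalized
  importances (scikit-learn convention); rankings match unnormalized
  impurity sums except in degenerate single-class trees.
* The NB classifier's dataset weighting ("weighted-average delta") is one
  reasonable reading of dataset-balanced rule scoring; it is isolated
  behind `NBRulesConfig.dataset_weights`.
* One-vs-one and platform-wise aggregation by minimum (worst case) are
  tool definitions, likewise isolated behind config flags.
* Raw-centroid predictions are invariant to per-sample *affine* maps (a
  property of Pearson correlation), not to arbitrary monotone transforms;
  the rule-based families are invariant to any strictly increasing
  per-sample transform.
* `stratified_split` guarantees at least one sample per class on each
  side, so extreme fractions on tiny classes deviate from exact
  proportionality by design.
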