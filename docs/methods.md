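# Methods

## The problem and the estimand

Subgingival plaque 16S data are compositional: sequencing reports relative
abundances, while total microbial load in periodontal pockets varies over
orders of magnitude and co-varies with disease. The package therefore works
exclusively with statistics that are invariant to per-sample count
rescaling. Its central quantity is the per-sample log-ratio

MIP = ln(Σ Treponema counts / Σ Corynebacterium counts),

a "reference frame" in which *Corynebacterium* — a scaffold taxon of healthy
plaque biofilms — serves as the denominator and *Treponema* — an anaerobe of
deep pockets — as the numerator. Samples with a zero on either side are
flagged and dropped, never imputed: the drop rule is part of the estimand,
and per-model sample sizes are reported so the deletions are auditable.
Taxon sets are resolved by rank-qualified lineage tokens (`g__Treponema`,
`s__Tannerella_forsythia`), so the indicator and the two published
alternative ratios (the Chen and Meuric presets, which mix genus- and
species-level definitions) share one matching rule.

## Read- and table-level filters

Reads are truncated at the start of the first run of 3 consecutive basecalls
with PHRED ≤ 4 and discarded if the truncated length is below 75% of the
original. The published wording ("trimmed after the first appearance" of the
low-quality run) is ambiguous about whether the offending window's first
base survives; this implementation cuts immediately *before* the window, and
the tests pin that convention. "Three basecalls" is read as three
*consecutive* calls (the q-score-filter behaviour of the standard tooling).
Samples with fewer than 1000 reads are dropped (exactly 1000 survives);
features present in fewer than 1% of samples are dropped (exactly 1%
survives). Taxonomic collapse sums features sharing a lineage prefix at the
requested rank, pooling features unassigned at that rank under their deepest
assigned prefix, and conserves per-sample totals exactly.

## Robust Aitchison PCA

The rclr transform maps each sample to ln(count) − mean(ln nonzero counts),
leaving structural zeros missing. Ordination is by low-rank completion of
the rclr matrix: alternating least squares on the observed entries (rank 3,
tolerance 1e-8 on the relative decrease of observed-entry MSE, at most 500
sweeps, ridge 1e-9 for conditioning, random-normal initialisation from the
run seed), followed by double-centering and SVD. Sample scores are scaled by
singular values; distances are Euclidean in the full k-dimensional score
space, not only axis 1. Because rclr is exactly scale-invariant and the
solver is deterministic given its seed, the resulting distances are
invariant to per-sample rescaling to floating-point precision.

PERMANOVA uses Anderson's pseudo-F with the permutation estimator
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), vectorised over permutations and
seeded. It is implemented in-package (rather than delegated) because a
seeded, reproducible permutation stream and an exhaustive-enumeration mode
for tiny designs are part of the package's contract; an external
implementation serves as a cross-check in the tests. Note that for very
small balanced designs a random permutation recreates the observed partition
with non-negligible probability, so the attainable p floor is larger than
1/(n_perm+1); this is a property of permutation tests, not a defect.

The four-way pairwise-distance comparison (shallow–shallow and deep–deep
between people, shallow–deep within and between people) treats sample pairs
as independent observations in a one-way ANOVA with Tukey HSD. Pairs sharing
a sample are not independent; the analysis replicates the conventional
figure-style presentation and the caveat is documented rather than "fixed".

Redundancy-analysis effect sizes are computed per covariate marginally: the
completed rclr matrix (or the scores) is regressed on the single dummy-coded
covariate, and the Ezekiel-adjusted R², clamped at zero, is reported with a
permutation p from shuffling the covariate. Raw R² is reported alongside.

## Multinomial differential ranking

Counts are modelled as counts_i ~ Multinomial(n_i, softmax(x_iᵀB)) with
x_i = (1, deep_i). The loss gives each sample its count-*proportion* vector
once, so the fit depends on compositions only and is exactly invariant to
rescaling any sample's counts; the Gaussian prior (scale 10) acts on the
*centered* coefficient rows, which makes the estimand well-defined despite
the softmax gauge freedom and makes any "reference feature" a pure gauge
choice that provably cannot move the centered differentials. Optimisation is
minibatch Adam with the published configuration (batch 10, 500 epochs,
learning rate 0.001, 10% of samples held out for per-epoch cross-entropy
monitoring), warm-started at the method-of-moments solution (centered log
group-mean compositions) and tail-averaged over the last 10% of epochs —
solver choices that matter because training is fixed-epoch with no early
stopping. The reported differential is the centered coefficient oriented to
the shallow pole: positive = health-associated, so *Corynebacterium* ranks
high and *Treponema* low.

Two quantified caveats: (i) optimizer reproducibility across seeds is ~4e-4
(max abs change in a differential), but duplicating every sample changes
rare-feature differentials by up to ~0.08 — not optimizer noise but the MAP
prior's weight halving relative to the data term, the statistically expected
behaviour; (ii) with the fixed epoch budget, coefficients of extremely rare
features remain partially shrunk toward the prior.

## Classifier validation

Two distinct procedures, as both are part of the protocol: (1) stratified
10-fold CV ROC AUC of a 500-tree Random Forest from out-of-fold probability
predictions (mean ± sd over folds); (2) ten stratified 50:50 splits in which
a full-table forest and an indicator-restricted forest (matching taxa plus
the log-ratio column, dropped samples imputed at the column minimum and
flagged) are trained on the same half, classify the other half at
probability threshold 0.5, and are compared by McNemar's test on the
discordant calls. McNemar is exact (two-sided binomial, capped at 1) below
b + c = 25 and continuity-corrected χ² above; b = c = 0 returns p = 1 by
convention. Forest hyperparameters beyond n_estimators stay at library
defaults (√p features per split, unlimited depth).

## Association models

The participant-level exposure is the mean of the participant's non-dropped
site values (mean of shallow and deep when both exist). Outcomes are
regressed on the exposure by OLS adjusting for age, sex, race, BMI and
smoking (collapsed never vs ever by default, configurable), with listwise
deletion; rank-deficient designs raise rather than silently pseudo-invert.
Quartile analyses bin the non-dropped values at empirical quartiles
(boundary ties to the lower bin; degenerate all-equal data collapse to bin 1
with a warning), then fit quartile-as-categorical for adjusted means
(marginal predictions with delta-method SEs) and quartile-as-ordinal for the
trend p. When participants contribute repeated rows a participant
random-intercept mixed model absorbs within-person correlation; with one row
per participant the model reduces to OLS, and the two agree within one SE in
the tests. P-values are two-sided and unadjusted across outcome panels,
matching the conventional presentation of such tables.

Faith's phylogenetic diversity is the total branch length of the minimal
subtree connecting a sample's nonzero features to the root, root path
included; it is computed by a single post-order traversal and checked
exactly against a brute-force union-of-root-paths oracle.

Site labels use shallow < 4 mm / deep ≥ 4 mm. The source protocols are
inconsistent about the 3–4 mm band (different sections use < 3 mm and
< 4 mm); the generator draws shallow pockets below 3 mm so both conventions
agree on synthetic data, and the threshold is a parameter rather than a
guess.

## The synthetic cohort generator

The generator defines the study conditions for every test. Each of
`n_participants` contributes a shallow sample and, for a fraction (default
1.0; the real cohort's ratio ≈ 0.4 is a parameter), a deep sample. Feature
log-abundances are baseline (genus offset sd 0.5 + feature sd 0.8) plus the
planted deep-site differentials (+2 on the 10 *Treponema* features, −2 on
the 10 *Corynebacterium* features, N(0, 0.25) background on the rest) scaled
by (is_deep + 0.5 · participant severity), plus N(0, 0.5) sample noise;
softmax gives compositions and counts are multinomial with log-normal totals
(μ = 8.5, σ = 1.25, spanning ≥ 2 orders of magnitude). A
Dirichlet-multinomial overdispersion option and a confounded mode (severity
coupled to age and smoking) exist to stress the estimators. Clinical
covariates are linear in the participant-level true log-ratio with default
slopes (e.g. 2.0 mmHg systolic BP per log unit, 0.03 %BOP per log unit;
glucose and HbA1c deliberately uncoupled) plus confounder terms and Gaussian
noise. The tree is a random coalescent with genus clades. All draws come
from one seeded generator stream.

Calibration notes. The baseline spread (0.8/0.5) was chosen so that the
rarest features still receive enough reads that their small true effects are
estimable at the 200-sample scale — with much wider spreads no estimator,
including a group-mean clr oracle, can rank them and recovery tests stop
discriminating. A consequence is that default sparsity is moderate (~5%
zeros) rather than the heavy sparsity of real plaque tables; heavier
sparsity is available by widening `baseline_sd` or lowering
`load_lognormal_mu`. What passing tests show is therefore that the
estimators recover the generative structure they assume (multinomial-logit
with planted effects); they do not certify behaviour under real-data
features the generator omits: read-level error and chimeras, contamination,
taxonomy misassignment, extreme rare-taxon sparsity, or non-linear
covariate relationships.

## Problem sizes used in verification

The standing cohort for recovery and classifier checks is 100 participants ×
2 sites × 100 features; coupling recovery uses 500 participants; type-I
calibration uses 500 replicates of 30–40-participant null cohorts per test
(1000 for the cheap tests) with the acceptance band widened accordingly
([0.025, 0.075] at 500 replicates); exact-oracle checks use n = 6 for
exhaustive PERMANOVA enumeration, b + c ≤ 12 for McNemar, and 100 random
trees of ≤ 20 leaves for Faith's PD.
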