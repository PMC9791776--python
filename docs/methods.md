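# Methods

## Scope and model

`progdx` implements a progressive-biomarker analysis for the
adenoma–carcinoma sequence: feature discovery by a two-cohort monotone
filter, linear "effect index" diagnostic scores trained on the discovered
markers, combination with the fecal immunochemical test (FIT), and
evaluation. This note records the modelling assumptions, parameter
defaults, numerical conventions, and the design choices that were genuinely
open.

## Disease-stage model

Six ordered stages: NC (normal control) < MP (multiple polypoid adenoma,
low-grade dysplasia) < AA_LGD < AA_HGD (advanced adenoma, low-/high-grade
dysplasia) < CRC_I_II < CRC_III_IV. Marker discovery collapses these to
three groups — NC, AA (= AA_LGD + AA_HGD), CRC (all stages) — and excludes
MP: multiple small polyps sit ambiguously between control and advanced
adenoma on the progression axis, and the filter's monotonicity criterion is
defined over the three-group sequence.

## Progressive-marker filter

Per cohort and feature: Kruskal–Wallis across the three collapsed groups
(tie-corrected H, chi-square p with k−1 df; an all-tied feature is assigned
H = 0, p = 1 rather than the 0/0 the tie-correction denominator would
produce), Benjamini–Hochberg adjustment across features, and median fold
ratios with a pseudocount of 1e-10 added to numerator and denominator so
zero medians yield defined ratios. A feature is retained iff in *both*
cohorts q < 0.05 and both consecutive fold ratios strictly exceed 1.5 (up)
or fall below 1/1.5 (down), with the same direction in both cohorts.
"More than 1.5 times continuously" is read as a strict per-step criterion
(NC→AA and AA→CRC each), not a cumulative one; whether medians are compared
before or after pseudocount stabilization is a convention, and the
stabilized form is used throughout. BH is the FDR procedure because it is
the field default where no procedure is named.

The filter is monotone in its thresholds (raising the fold threshold or
lowering the FDR threshold can only shrink the marker set), and the
two-cohort AND-ing drives the null false-discovery count far below the
nominal single-cohort bound — both properties are asserted in the test
suite.

## Species-panel selection

For the two-group (control vs advanced adenoma) species panel: a Wilcoxon
rank-sum prefilter at p ≤ 0.05 (exact enumeration when the pooled sample
size is ≤ 12 and tie-free, otherwise the tie-corrected normal
approximation), then greedy mRMR ranking, then a panel chosen by
cross-validated MCC of a linear maximum-margin classifier (SVC, C = 1) on
ln(abundance + 1e-10) features, 5-fold stratified CV. The mRMR variant is
MID (relevance minus mean redundancy) with mutual information on
tertile-discretized abundances and ties broken by input feature order; the
original analysis's exact mRMR implementation and discretization are not
recoverable, so this is a declared convention, checked against an
exhaustive greedy oracle. Panel size defaults to a fixed 25 features (the
full CV–MCC curve over ranking prefixes is always emitted); set
`panel_size: null` to instead take the prefix maximizing CV-MCC.

## Effect indexes

Transform: t(a) = ln(a + ε) + 23.026 with ε = 1e-10. The offset is the
conventional rounding of −ln(1e-10) = 23.02585…, so t(0) = 1.4907e-4 and an
absent feature contributes |cᵢ|·1.4907e-4 to the score — effectively zero.

Training ("dichotomy" iterative least squares):

1. Initial targets: 1 for the negative stages, 50 for the positive stages
   of the index definition. Intermediate stages (e.g. AA and CRC I/II when
   training CEI2) are excluded from training entirely — only the 1-group
   and the 50-group are defined, and including unlabeled intermediates
   would presume their score.
2. Least squares of targets on transformed features. With more features
   than samples ordinary least squares is ill-posed, so the minimum-norm
   solution (pseudoinverse via `lstsq` on centered data) is used; a ridge
   solver (`solver: ridge`, λ configurable, default 1.0) is available.
   Exactly constant feature columns receive coefficient 0 (detected by
   exact equality, not by centering, to avoid floating-point residue).
3. Relabeling: a sample whose fitted score falls on the correct side of the
   class midpoint 25.5 adopts its fitted score, clipped to [1, 50], as its
   new target; misclassified samples revert to 1/50. This is a
   deterministic formalization of "replace 1 or 50 by the good scores".
4. Stop when the training Youden index (max over thresholds of
   sensitivity + specificity − 1) improves by less than 0.005, or after 20
   iterations; the best iterate is kept, so accepted quality never
   decreases.

Decision cutoffs are specificity-first: the smallest observed score c such
that calling score > c positive achieves specificity ≥ 0.90 (configurable)
on the provided samples.

The Progressive Disease Index (PDI) is a separately fitted fifth score: a
single least-squares fit to ordinal targets 1 / 20 / 40 / 60 / 80 / 100
over the six stages, emitted with a reference warning line of 75 (between
the two CRC stage targets). Fitting it as its own ordinal-target score,
rather than rescaling one of the four dichotomous indexes, is a design
choice: it uses all six stage labels and directly encodes the monotone
trend the index is meant to display.

## FIT

FIT values are in µg hemoglobin per g dry stool; positivity is strict:
value > 20 µg/g (equivalently 100 ng/mL buffer). The published combination
scores (score1/score2, coefficients and cutoffs hard-coded in
`published_models`) consume the 0/1 positivity indicator — the coefficient
magnitudes (4.08, 21.77) are only plausible for a binary covariate, though
the encoding is a declared convention and `refit_combined` accepts any
numeric FIT column. Refitting reuses the 1/50 dichotomy targets on the
design [1, FIT, index].

## Evaluation

Sensitivity and specificity are stored as confusion counts plus percentages
rounded half-up to one decimal, so the printed percentage always re-derives
from the counts. AUC is pairwise concordance, P(score_case > score_control)
+ ½·P(tie), computed by the rank identity and verified against explicit
pair counting. Confidence intervals are stratified percentile bootstrap
(default 2,000 replicates, seeded; the CI method of the original tables is
unstated, and bootstrap is the assumption-light choice). Spearman clinical
correlations drop a sample only from the covariate columns where its value
is missing; covariates with fewer than 3 observed values are reported NaN.

## Bray–Curtis trees and co-cluster selection

BC(a,b) = 1 − 2·Σmin/Σ(a+b) on closed profiles; agglomeration by average
linkage by default (complete available) — no linkage is named in the
original tree analysis, and average linkage (UPGMA) is the community
standard for abundance dissimilarities. "Same branch as the reference
samples" is operationalized as co-membership in a cluster at a k-cluster
cut (default k = 2, configurable): the underlying selection rule the
package reproduces has no published cut parameter, so the convention is
explicit rather than implicit. Genus trees conventionally use the top-30
most abundant genera (`top_abundant_features`).

## Synthetic cohorts

The generator emulates the *structure* the pipeline assumes, not any real
cohort's distributions (which are uncharacterized): per-feature log-normal
intensities with Bernoulli zero-inflation, closed per sample to relative
abundance. Defaults: 2,000 features, zero-inflation 0.3, log-normal sd 1.0,
cohort batch offsets (sd 0.3 on the log scale) per cohort × feature, group
sizes 39 NC / 7 MP / 17 AA_LGD / 11 AA_HGD / 13 CRC I–II / 9 CRC III–IV per
cohort (a 1:10 scale-down of an 871-sample study design), planted fold
ln 2 per step (ln 4 in the discovery-scale acceptance study).

Planted markers shift on the log scale before closure, by stage positions
0 / 0.5 / 1 / 1.25 / 2 / 2.25 progression steps for the six stages: the
collapsed AA and CRC groups sit one step apart, so planted medians move by
the configured fold at each transition the filter tests, while the
fractional offsets grade the six-level severity for the PDI. Planted
baselines are drawn low-to-mid abundance (log-intensity N(−3,1), vs N(0,2)
for background features): disease-associated genes are not dominant
community members, and a small baseline share keeps closure-induced
saturation from eroding the planted fold (with high-abundance baselines the
renormalization visibly compresses the CRC-stage fold below threshold).
Closure spillover onto background features is accepted and is one reason
the null-study false-discovery test matters. FIT is truncated-at-zero
normal per stage (means 5 → 120 µg/g from NC to CRC III/IV) — only its
binarized value enters downstream scoring. Randomness flows through
per-(cohort, feature) substreams of one seed (cohort ids hashed by CRC32,
not Python's salted `hash`), so output is a pure function of (spec,
cohort id) and adding features does not reshuffle existing ones.

What passing synthetic tests does *not* show: the generator has no
phylogenetic correlation between features, no sequencing-depth variation,
no covariate structure (age/sex are independent noise), and its
zero-inflation is feature-independent; real-data performance claims cannot
be made from it.

## Problem sizes and determinism

The test suite and acceptance script use scaled-down study sizes chosen to
exercise every code path at comfortable desk-top cost: discovery-scale
marker recovery at 200 samples per collapsed group × 2,000 features, null
calibration over 20 seeds × 300 features, index behaviour at n = 300, and
an end-to-end pipeline at ~60 samples per cohort. Pipeline artifacts are
byte-deterministic given (config, seed): JSON is dumped with sorted keys,
no timestamps are recorded, and every artifact carries the config hash
(path-independent) and package version.

## Known limitations

- The iterative relabeling is a deterministic reconstruction of a
  qualitatively described procedure; other formalizations (e.g. relabeling
  only a "majority" fraction) would converge differently.
- Minimum-norm least squares on p ≫ n marker sets interpolates the targets;
  the ridge option trades that for shrinkage but is not the default.
- The specificity-first cutoff is chosen on training data; as the worked
  example shows, small validation control groups can fall short of the
  training specificity target.
- `spearman_clinical_correlation` treats covariates as numeric; categorical
  covariates must be encoded upstream.
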