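# Methods

This note documents the models and procedures implemented in `panprog`,
the choices made where the design was genuinely open, and what the
synthetic data can and cannot show.

## Pre-processing and labeling

Expression matrices are features × samples, log2(x+1). The log base is a
package choice (standard for expression; the pseudo-count handles zeros);
linear inputs are transformed on read, and isoform-level inputs are summed
per mature strand on the linear scale before the transform. Missing-value
filtering is two-pass and order-sensitive: features with any missing value
are dropped first, then samples with any remaining missing value — so a
sample is only lost for holes in features that survived the first pass.
Rows collapsing to one identifier are averaged on the stored log scale.
When a TCGA-style sample-type code is present, codes 01–09 (tumor) are
retained and 10–19 (normal) removed; inputs without the column skip the
filter.

Prognosis classes come from the cohort's median overall survival: high-OS
iff OS strictly exceeds the median (midpoint of the central pair for even
n). Ties at the median fall to low-OS, so the high-OS class never exceeds
⌊n/2⌋. The event flag defaults to 1 when absent: the upstream filtering
keeps only samples with a recorded OS value and the analysis treats that
value as the outcome.

## Differential expression

Each feature is scored with a Welch (unequal-variance) two-tailed *t*-test
— chosen over the pooled test because group variances are not assumed
equal — and a fold change computed on the linear scale after
back-transforming (2^x − 1), with ε = 1e-8 guarding all-zero groups.
Gates: miRNA passes at *P* < 0.05; lncRNA at *P* < 0.01 together with a
two-sided fold-change gate (FC ≥ 2 or FC ≤ 0.5), the absolute-value
reading that captures down-regulation. P-values are unadjusted by default;
Benjamini–Hochberg is available behind a flag. Zero-variance features with
equal group means get t = 0, p = 1; with unequal means the p → 0 limit is
taken and logged.

For small cohorts (projected training size below 50 samples) the merged
marker matrix is reduced by factor analysis: the number of factors comes
from the Kaiser criterion (correlation-matrix eigenvalues > 1, capped at
n − 1), loadings are varimax-rotated (the convention of the R
factor-analysis tooling this mirrors), and the union over factors of the
10 largest-|loading| features is kept. A degenerate fit falls back to
principal-component loadings, logged.

## Spatial subset sampling

Distances are Euclidean between sample vectors after per-feature
z-scoring (so no feature dominates by scale); zero-variance features get
zero weight. Within each OS class independently, a seed sample is drawn
from the split seed, then samples are added greedily — each new sample
maximizes its mean distance to the already-selected set, ties breaking to
the smallest sample index. The first round(2n/3) samples (round half up)
of each class train the model. The seed sample is the only random element;
the method is run per class so both classes keep the two-thirds ratio
exactly.

## Prognosis classifier

Gaussian naive Bayes with per-class feature means and variances
(population estimates) and priors equal to class frequencies. Variances
are floored at 1e-9 × the largest per-feature training variance so
constant features cannot produce singular likelihoods. Posteriors are
log-space sums of per-feature Gaussian log-densities plus the log prior,
normalized by logsumexp — stable for thousands of features. The
classification threshold is 0.5 on the high-OS posterior. The model state
serializes losslessly to JSON. LR/SVM/NN adapters expose the same
`predict_proba` surface via scikit-learn with library defaults (NN: one
hidden layer of 32 units); they are conveniences, not part of the
reference analysis.

## Survival evaluation

Kaplan–Meier estimation and the two-group log-rank test are delegated to
lifelines and cross-checked in the test suite against independently coded
textbook formulas (product-limit steps; hypergeometric moments with
χ² = (O−E)²/V). Predicted-group comparison reports the median of observed
OS per predicted group (the KM median is also exposed), the KM curves, and
the log-rank χ²/p over the predicted grouping; an empty predicted group
degrades to p = 1 with a logged note.

## Marker landscape

Marker sets from all cancers are deduplicated into a binary marker ×
cancer incidence matrix. Shared = row sum ≥ 2 cancer *types*;
cancer-specific = exactly 1. Ranking is by cancer count, ties
lexicographic. Category-level sharing (≥ 2 of the nine categories of the
bundled 19-type taxonomy) is reported additionally.

## Pathway refinement and regulation

Refinement removes every gene occurring in ≥ 2 of the eight gene sets,
leaving pairwise-disjoint pathway-specific cores; sets may become empty
(kept, warned). A cancer's pathway regulation fraction is the share of its
miRNA markers with ≥ 1 annotated target inside the refined core; markers
without any annotation stay in the denominator. Per-gene profiles use the
same per-cancer denominator and a strict > 0.07 gate (0.05 behind the same
parameter); the per-cancer denominator was chosen because the profiles are
drawn per cancer type, with the pan-cancer denominator available by
passing the pooled marker set. Target edge lists from multiple databases
are merged by union.

## The marker-oriented counterfactual screen (MOS)

The reference level of a marker is its mean expression among high-OS
training samples (mean rather than median as the natural point estimate;
median exposed as an option). Markers are perturbed alternately — one at a
time: every held-out low-OS sample whose value lies below the reference is
raised to it, all other features untouched, and the model re-scored. The
marker's score is the mean posterior change over the perturbed samples;
it is flagged prognosis-alternative iff it perturbed ≥ 1 sample and the
mean change exceeds ε = 1e-6. For an equal-variance NB marker whose
high-OS mean exceeds its low-OS mean the likelihood ratio is monotone in
expression, so the flag is guaranteed — verified numerically in the tests.
The screen runs on held-out low-OS samples by default (scoring training
samples with their own model would bias the deltas); a per-sample majority
rule is exposed as an alternative aggregation. Common genes per cancer
category are the intersection over member cancers of the genes targeted by
each cancer's alternative markers, restricted to the union of the
*unrefined* pathway sets (the candidate-target universe is "participates
in a canonical pathway", not "is pathway-specific"); a union-within-
category variant is available by flag.

## Synthetic data: what it emulates, what it does not

The generator emulates: log-scale expression with per-feature means
Uniform(3, 9) and Normal noise; survival times from an exponential model
(Weibull shape exposed, default 1) whose log hazard is log h₀ plus
±β · z per planted marker (− for protective); independent exponential
censoring calibrated so the expected censored fraction tracks the
requested rate; shared miRNA markers planted identically in every cancer
and lncRNA markers disjoint across cancers, directions alternating
protective/hazardous along the ordered marker list; a chain of eight
pathway gene sets in which consecutive sets share exactly `pathway_overlap`
genes; and a target map in which every planted miRNA targets ≥ 1
pathway-specific gene. All randomness derives from one seed, with
per-cancer streams hashed from (seed, cancer id) so adding a cancer leaves
the others untouched.

Default conditions: 4 cancers × 400 samples, 150 miRNAs, 200 lncRNAs,
3 shared miRNA + 1 per-cancer lncRNA markers, β = 1.0, baseline hazard
1/1000 events/day, expression noise σ = 2.2 (log2), censoring 0 (the
analysis treats every recorded OS as an outcome and carries no event
flag; censoring is available for sensitivity runs). The marker count and
σ follow a design calculation: with K markers per cancer, a marker's
expected between-class log2 shift under median-split labeling is
1.596 σ/√(K + π²/6); K = 4 and σ = 2.2 put that shift at ≈ 1.5 — large
enough for the omic-specific gates while keeping per-feature dispersion
realistic. Larger σ would inflate the lognormal-tail variance of
linear-scale fold-change estimates faster than the signal grows; many more
markers would dilute each marker's marginal effect below the fold-change
gate entirely.

Not emulated: realistic miRNA nomenclature or isoform biology,
heavy-tailed or count-based expression noise, batch effects, correlated
(co-regulated) features, informative censoring, copy-number/mutation
layers, or real pathway membership (the bundled eight-pathway GMT is a
synthetic stand-in with well-known member genes). Passing tests therefore
show the pipeline recovers the assumed generative structure — they do not
certify performance on TCGA-scale data, where effect sizes, marker counts
and noise are far less favorable.

## Numerical choices and degenerate inputs

- Fold change ε = 1e-8; MOS ε = 1e-6; NB variance floor 1e-9 × max
  feature variance.
- Round half up for the training count; farthest-point ties break to the
  smallest index; ranking ties break lexicographically.
- All-low-OS cohorts (no OS above the median), empty refined pathway
  sets, empty predicted groups, and zero-variance features degrade with
  logged warnings rather than errors; single-class training, empty marker
  sets and empty sample intersections raise.
- Problem sizes in the test and acceptance runs (400 samples/cancer,
  150 + 200 features, 10 seeds) keep the full study under ten seconds
  while leaving every rate estimate enough resolution to be meaningful.

## Known limitations

- The unadjusted gates replicate the reference analysis; with 150 null
  miRNAs per cancer, ~5 % false markers are expected and observed.
- The factor-analysis path triggers only for small cohorts and its
  factor count is heuristic (Kaiser); it is exercised by tests but not by
  the default-size acceptance study, whose cohorts are large.
- Marker directions alternate deterministically, so planted protective
  and hazardous markers are balanced only up to rounding.
- The MOS guarantee is proved for equal class variances; with unequal
  fitted variances the posterior is not globally monotone and a planted
  marker can in principle go unflagged (not observed at the default
  conditions).
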