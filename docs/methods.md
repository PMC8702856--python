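# Methods

This note records the models, defaults and numerical choices behind
`cazytyping`, and what the synthetic benchmarks do and do not demonstrate.

## Annotation consensus and aggregation

A dbCAN2-style overview file carries one row per predicted gene with the
family call of each tool (HMMER, Hotpep, DIAMOND; `-` = no call; multi-domain
calls joined with `+` or `|`; Hotpep/HMMER annotations in parentheses are
stripped). By default only Hotpep and DIAMOND are consulted, matching an
annotation protocol that runs two of the three tools; HMMER can be switched
in (`tools=` argument / `include_hmmer` in the pipeline config), and the
two-tool threshold is kept in both modes. The upstream search thresholds
(DIAMOND E < 1e-102, Hotpep hits > 6 and frequency > 2.6) act inside dbCAN2
before the overview file exists; they are recorded as provenance constants
(`DBCAN2_PROVENANCE`) and never applied here.

When the consulted tools disagree on a gene's family set, the retained set is
the intersection when non-empty, otherwise the union, and the event is
logged. Tool count alone decides retention; no reconciliation beyond this is
attempted. Subfamily suffixes are collapsed to family level (GH13_18 →
GH13) because all family-level summaries and downstream statistics operate
on families; a gene retained with *k* distinct canonical families adds one
copy to each of the *k* columns (flagged in logs at parse time).

Genus summaries use the sample standard deviation (n − 1): strains within a
genus are treated as a sample from the genus's diversity.

## Projection

`AC_strain = N · R · T` is exact arithmetic; the sample-level statistic
divides the panel sum by the actual panel size *P* rather than a hard-coded
constant, so the same formula generalises to any panel ("panel_mean",
default). The plain-sum mode exists because the two aggregations differ only
by the constant *P* per run: Z-scoring removes any per-family constant and
the count model absorbs it into size factors, which a dedicated test
asserts. No rarefaction or compositional renormalisation is applied at this
stage; depth handling is deferred to the size factors of the count model.
Panel strains missing from a sample's profile contribute R = 0 (absence is
treated as undetected).

## Transforms and clustering

log10(x + 1) maps zeros to zero and compresses the heavy right tail of
read-scale abundances. Z-scores use the sample sd (n − 1) by default
(`ddof` configurable; downstream clustering and sPLS-DA are invariant to
this constant). Zero-variance families cannot be standardized; they are set
to all-zero and flagged rather than erroring, so heatmap-stage consumers can
keep them while the sPLS-DA entry point drops them.

Spearman distance is 1 − ρ with midranks for ties, range [0, 2]; a constant
vector has no rank correlation and raises, naming the offending row or
column. Agglomeration runs on the condensed distance matrix via standard
linkage; the default linkage is "average" (configurable: single, complete,
average, ward), recorded in output metadata. Ties merge the smallest index
pair first, making trees deterministic given input order. Dendrograms
serialise to Newick with branch lengths derived from merge heights, so the
root-to-tip distance of every leaf equals the root merge height.

## Sparse PLS-DA

Classes are coded as a 0/1 indicator matrix, column-centred. Per component,
the weight vector is the dominant singular pair of `X_deflatedᵀ · Y_deflated`
with the X weight soft-thresholded by the smallest λ that leaves exactly
`keepX` non-zeros (ties at the threshold break by feature index); both
blocks are then deflated by regression on the component scores. Weights are
sign-fixed so the largest-magnitude entry is positive. With `keepX` equal to
the feature count this reduces exactly to dense PLS-DA, which the tests
verify against an independent NIPALS implementation.

Prediction supports `max_dist` (argmax of predicted dummy columns, the
default), `centroids` and `mahalanobis` (nearest class centroid in score
space, Euclidean or pooled-covariance metric). `keepX` is tuned per
component, sequentially, by stratified k-fold cross-validation (round-robin
assignment of shuffled within-class indices; one seed governs all shuffles)
repeated `repeats` times; the candidate minimising mean classification error
wins, ties going to the sparser model. A phenotype whose tuned error never
beats the majority-class null model (`null_model_error`) is reported as "no
features selected" rather than forcing a model.

## PERMANOVA

Sums of squared distances partition into within- and between-group parts;
pseudo-F = (SS_between/(a−1)) / (SS_within/(n−a)), R² = SS_between/SS_total,
and p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm) over seeded label
permutations (default 999). The default distance is Euclidean on the
log+Z-standardized matrix (configurable). All-coincident points make F
undefined; the result is flagged degenerate with p = 1 instead of raising.

## Negative-binomial differential abundance

Projected abundances are real-valued; they are rounded to the nearest
integer before modelling (the rounding mode is recorded in provenance).
Size factors are classic median-of-ratios against the geometric-mean
reference over families positive in every sample, falling back per sample
to its positive families (with a warning) when no family is
everywhere-positive.

Dispersions: a method-of-moments estimate on normalized counts (pooled
within-design-cell variance) initializes a Cox-Reid-adjusted
maximum-likelihood gene-wise estimate with fitted cell means; a parametric
trend α(μ) = a₀ + a₁/μ is fit by iteratively reweighted least squares with
gamma-style weights; gene-wise values are shrunk toward the trend in log
space with precision weights, taking trigamma((n − m)/2) as the sampling
variance of a log dispersion and flooring the prior variance at 0.25. The
moment estimator alone is too noisy at small n for that precision weight and
visibly inflates the Wald type-I rate, which is why the likelihood step
exists. Dispersions are bounded to [1e-8, 10]; all-zero families are
flagged and excluded from testing.

Per family, an NB GLM with log link and size-factor offsets is fit by IRLS
(tolerance 1e-8, max 100 iterations). A tiny ridge (1e-8) and a clamped
linear predictor keep separated designs finite — with disjoint site strain
pools many families are structurally absent from one body site, which would
otherwise drive coefficients to ±∞. Non-converged families keep their
estimates but receive a missing p. Wald z = c·β̂ / SE(c·β̂) with a two-sided
normal reference; contrasts are coefficient combinations under treatment
coding (reference levels: control phenotype, gut site), so a phenotype
contrast is the effect at the reference site when the interaction is
included. Whether site contrasts are tested inside the full interaction
model or a collapsed one is configurable (`interaction=`).

Shrunken log2 fold changes are the posterior mode under a heavy-tailed
(Cauchy) prior centred at zero using the normal approximation of the
likelihood; the prior scale is the excess of the across-family variance of
MLEs over their median squared standard error. This leaves well-determined
large effects essentially untouched while pulling noisy estimates toward
zero; the raw MLE is always reported alongside, and the marker rule uses the
shrunken value by default. Markers require |log2FC| strictly above 2 and
BH-adjusted p strictly below 0.01. BH is the step-up procedure with
monotonicity enforcement; missing p-values propagate and do not count
toward m. Cook's-distance outlier filtering and independent filtering of
low-count families are deliberately not applied by default, keeping the
tested family set explicit; no subject-pairing term enters the design by
default.

## Synthetic study conditions

The generator emulates the cohort structure the analysis assumes, at a
scale that runs in seconds. Defaults (one master seed drives panel, cohort
and fixture writing through per-stage child generators):

- 60 strains in 12 genera / 4 phyla; 80 families split GH 40 / GT 20 / CE 8
  / PL 6 / CBM 4 / AA 2, echoing the dominance of glycoside hydrolases in
  real panels. A `paper_scale()` preset (310 strains / 86 genera / 9 phyla /
  220 families, 117 subjects per phenotype) exists for slow runs.
- Copy numbers are Poisson with genus-blocked means: 20% core families with
  a shared mean (2.0); accessory families elevated by (1 + s) in two home
  genera and suppressed by 1/(1 + s) elsewhere, enrichment strength s = 7.
  s = 0 removes all genus structure (verified against a permutation-null
  silhouette).
- Genome size = 2 Mb + 20 kb × total copies + Gaussian noise scaled so the
  population squared correlation hits the configured target (0.72 by
  default); the realized value is within ±0.1 at n ≥ 200 strains.
- Each of 30 subjects per phenotype (control, CRC, T1D, RA) contributes one
  oral and one gut sample. The site pools are disjoint by default
  (overlap fraction 0), the regime in which the body-site effect is
  unambiguous; compositions are exp(Normal(0, 0.5)) over the pool,
  renormalised; read depths are log-uniform on [1e6, 1e7].
- Planted effects default to five families depleted 8-fold in T1D. Each
  planted family is made exclusive to one dedicated carrier strain (distinct
  carriers in distinct genera, forced into the gut pool); scaling that
  carrier's abundance realises the configured fold change at the family
  level almost exactly, while families the carrier shares with genus mates
  move by far less than the marker threshold, so the planted list is the
  complete differential truth. σ_log = 0.5 keeps the realized population
  fold change of an 8-fold depletion within [5-fold, 12-fold] at this cohort
  size; heavier-tailed compositions are available via the parameter.
- Fixture files carry every retained gene with two tool calls (occasional
  random subfamily suffixes exercise canonicalisation without changing
  counts) plus a configurable fraction of single-tool decoy genes that the
  consensus filter must drop; the round trip through the parser reproduces
  the panel exactly.

What the synthetic benchmark does **not** show: real strain abundance
estimation error, between-study batch structure, phylogenetic correlation of
repertoires, pangenome variation within species, or disease effects that act
through many weakly shifted taxa rather than a few carriers. Passing the
recovery tests therefore demonstrates the statistical machinery is correct
and calibrated under the stated generative model, not that real cohorts of
this size would yield the same sensitivity.

## Problem sizes used in checks

The bundled end-to-end checks run the default 60 × 80 × 240 configuration;
the Wald null calibration uses 2000 simulated families at two groups of 10;
PERMANOVA checks use 999 permutations (and full enumeration on 6 points);
cross-validated tuning examples use 5 folds with 1–10 repeats. These sizes
were chosen so the whole suite completes in well under a minute per stage on
one CPU while keeping Monte-Carlo error small relative to the asserted
tolerances.

## Known limitations

- The NB Wald p uses the normal reference; at very small sample sizes this
  is mildly anti-conservative even with exact dispersions (a t-like
  reference would trade this for conservatism; the normal reference is the
  convention of the count-model tools this stage mirrors).
- The dispersion trend a₀ + a₁/μ can misfit panels whose dispersion rises
  with abundance; the gene-wise estimate retains most of the weight in that
  case, which is the intended fallback.
- sPLS-DA tuning error estimates reuse the same folds across candidates
  (deliberately, for paired comparisons), so the absolute CV error is
  slightly optimistic as a generalisation estimate.
- `validate_inputs` checks schema and cross-references, not biological
  plausibility (e.g. it accepts a profile whose strains never co-occur).
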