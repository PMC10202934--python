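# Methods

This note documents the models, defaults and numerical choices behind
`oncomir`, and what the synthetic cohorts do and do not establish about
real data.

## Prioritization score

The combined score is `S = E + T` with the expression quartile score
`E ∈ {0,1,2,3}` and the evidence tier `T ∈ {1,3,5}`.

- Quartile boundaries are empirical 25/50/75% quantiles with linear
  interpolation; a mean lying exactly on a boundary is assigned to the
  lower group. This tie rule is deterministic and means a fully tied input
  scores everyone 0.
- The three evidence criteria (not validated & narrowly predicted;
  validated XOR widely predicted; validated AND widely predicted) are
  mapped to {1, 3, 5}. With `E ∈ {0..3}` this is the minimal odd-step
  assignment whose sums span exactly 1–8, and it makes the selection rule
  `S ≥ 7` equivalent to "validated, predicted by ≥6 of 12 algorithms, and
  expressed above the median". Both the tier values and the ≥6-algorithm
  cutoff are arguments.
- Mean expression is computed over the CDK2AP1-deficient samples by default
  (the screen profiles deficient lines; the proficient lines serve as the
  comparison arm), switchable to all samples.
- "In silico predicted" in the top criterion is interpreted as the same
  ≥6-of-12 rule used by the middle criterion, keeping the tier lattice
  monotone in both evidence axes.

## Assays

qPCR uses plain 2^−ΔCt / 2^−ΔΔCt with no amplification-efficiency
correction. Luciferase normalization is strictly per plate: each well's
firefly/renilla ratio is divided by the mean mock ratio of its own plate,
because transfection efficiency varies by batch; condition activities are
then averaged across plates. The CDI is the combination activity over the
*average* of the single activities (the product-form convention is
available behind `method="product"` for comparison). CDIs are computed on
condition means, not per-replicate pairings. The 0.9/1.1 classification
thresholds are a reporting convention only and are configurable; the raw
CDI is always reported alongside.

## Spatial TMA pipeline

- Outlier z-scores are computed per median-intensity channel (all eight
  nucleus/cytoplasm × channel combinations) over the merged cohort, before
  any per-core work, and a cell is flagged when |z| > 3 in any channel.
  The two-sided default reflects that both staining dropouts and
  saturations occur; a one-sided (high-only) mode is a flag. Channels with
  zero variance contribute no exclusions (z undefined) and emit a warning.
- Filtering only ever flags cells; downstream aggregates skip flagged cells
  but tables keep their full length, so cell counts are conserved and
  exclusions are auditable.
- Core summaries and the per-core Pearson correlation use tumor-compartment
  cells only by default (an all-cells mode exists), requiring ≥500
  contributing tumor cells for inclusion. Undefined correlations (constant
  channel, <2 cells) are stored as NaN and ranked last.
- The miR-21 = 150 stratification cutoff applies on the raw intensity
  scale; log2 transforms are used for visualization only. Exact equality
  with the cutoff goes to "low". The group contrast is Welch's t by
  default; the patient-paired mode averages core values per patient within
  each group and pairs patients represented in both groups (the pairing
  unit is genuinely ambiguous, so both modes are first-class).
- Digital reconstructions scatter cells at their (x, y) centroids, tumor
  red / stroma gray, or colored by the log2 median intensity of one
  channel; SVG output uses a fixed hash salt and no timestamp so renders
  are byte-stable.

## Variant cascade and CNV calls

The four rules are independent predicates applied in a fixed order
(functional class → recurrence ≥5 samples → population MAF ≥1% in any of
three databases → repeat/low-complexity indels); removal is attributed to
the first triggering rule so tallies are reproducible and always sum, with
survivors, to the input size. A missing MAF is treated as rare — absence
from population databases is precisely the signal the filter exploits.
CNV calls use strict inequalities (|log2 ratio| > 0.5 and P < 0.05), so
boundary segments stay neutral. VCF ingestion maps ANNOVAR-style INFO keys
(configurable) onto the cascade schema; an annotated TSV path bypasses VCF
entirely so the cascade is testable without external annotators.

## Survival stratification

The IHC rule is inclusive: ≥45% CDK2AP1-negative tumor cells classifies a
tumor as low/neg (an exclusive variant is a flag). Marker dichotomization
defaults to the median with ties to "low"; quantile and fixed cutpoints
are available. KM estimation and log-rank statistics come from lifelines;
the package's own tests additionally verify the log-rank p against a
label-permutation oracle. The threshold scanner maximizes the log-rank
statistic over a user grid and always annotates its output with a
multiple-testing warning; an optional permutation test (re-maximizing over
the grid under label permutation) gives an honest p-value for the maximum.

## Synthetic-data model

All generators derive their randomness from a single root seed split into
per-stage independent streams, so outputs are byte-identical for a fixed
`SimConfig` and stages never perturb each other.

- **Expression screen**: 60 miRs × (4 deficient + 3 proficient) samples on
  a log2 scale, baseline N(8, 1) per miR, residual SD 0.5, and a +2.0
  planted shift in the deficient group for the 12 screen-hit miRs.
- **TMA cohort**: 144 patients × 3 cores, 900–1500 cells per core, 70%
  tumor. Intensities are log-normal (positive, right-skewed, like real
  fluorescence). Core-level log-means of (miR-21, CDK2AP1) are bivariate
  normal with SD 0.25 and correlation −0.6 centered at log 150 / log 110;
  tumor-cell residuals are bivariate with SD 0.2 and the same correlation.
  Within-core correlation therefore carries the cell-level signal while the
  between-core anti-correlation makes the miR-21 ≷ 150 stratification
  informative about CDK2AP1. On this scale the raw-intensity Pearson r of
  exponentiated bivariate normals is attenuated to ≈ −0.58 for a planted
  −0.6 — the recovery tolerance (±0.05) accounts for this known bias.
  Stromal miR-21 is scaled ×2; stromal CDK2AP1 sits at a low fixed
  baseline.
- **Outliers**: a deterministic 3% of cells is displaced *upward* on every
  median channel by 8 clean channel SDs. A whole-cell displacement models
  debris/fold/saturation artifacts, which hit all channels of a cell at
  once; upward-only preserves intensity positivity. The displacement
  inflates each channel's cohort SD by a factor ≈ √(1 + 0.03·64) ≈ 1.7, so
  planted outliers sit near |z| ≈ 4.6 (always caught at |z| > 3) while
  clean log-normal cells would need ≈ 5 raw SDs to be flagged (essentially
  never).
- **Survival**: exponential event times with rate 0.03/month × group
  hazard ratio; censoring is independent exponential with per-patient rate
  λ·c/(1−c) so the expected censored fraction equals `censoring_rate`
  exactly and c = 0 censors nothing. Group assignment follows one of three
  rules: by IHC fraction vs 0.45, uniformly at random over the configured
  groups, or by the quadrant of the first two marker covariates.
- **Variants**: a deterministic 6-row fixture (order shuffled by seed) with
  one violator per cascade rule and two clean survivors, truth-labelled.

Hidden ground-truth columns carry the `truth_` prefix and are stripped
(`drop_truth_columns`) before data reach any analysis stage; analyses also
ignore them structurally (channel discovery excludes the prefix).

### What the synthetic cohorts do not show

The generators emulate the *statistical* structure of the study — group
shifts, correlations, compartment contrasts, hazards — not the biology or
measurement physics: no spatial autocorrelation within cores, no
segmentation errors beyond the planted whole-cell artifacts, no
heavy-tailed single-cell intensity mixtures, no batch effects between TMA
blocks, and survival hazards are proportional by construction. Passing
recovery tests therefore demonstrates that the pipeline's estimators and
filters are correct and well-calibrated under their stated models, not
that real cohorts satisfy those models.

## Problem sizes

Default test and acceptance runs use the study-scale cohorts (432 cores,
~0.4–0.5M cells, 500 null survival replicates of n=100 and 100 power
replicates of n=200); the whole suite completes in a few minutes on one
CPU. Unit tests use smaller cohorts (30 cores × 100 cells) chosen to keep
planted counts exact (3% of 3000 cells = 90 outliers).

## Known limitations

- The evidence generator draws tiers independently of the expression
  effect, so the default synthetic screen selects a score-≥7 set that need
  not coincide with the planted expression hits — convenient for testing
  the score's two axes independently, but unlike a real screen where the
  axes correlate.
- The TCGA/cBioPortal comparisons that require live downloads are out of
  scope; no network adapter is shipped.
- No Cox modelling or multivariable adjustment; the survival module covers
  KM/log-rank stratification only.
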