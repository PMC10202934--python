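# oncomir

Loss of the CDK2AP1 (DOC1) tumor suppressor protein is near-universal in
oral squamous cell carcinoma (OSCC), yet its coding sequence is almost never
mutated: repression is post-transcriptional, driven by microRNAs binding the
*CDK2AP1* 3'-UTR. `oncomir` implements the computational stages used to
identify and validate such CDK2AP1-antagonist miRNAs, for bioinformaticians
and wet-lab scientists who want the analyses reusable, tested and
reproducible:

- **miRNA prioritization** (`oncomir.mirscore`): each miR gets an expression
  score `E ∈ {0,1,2,3}` — the quartile of its mean normalized array
  intensity among all miRs — plus an interaction-evidence tier
  `T ∈ {1,3,5}`: lowest when the miR–target pair is neither experimentally
  validated nor predicted by ≥6 of 12 target-prediction algorithms, middle
  when exactly one holds, top when both hold. The combined score
  `S = E + T ∈ [1,8]`; candidates with `S ≥ 7` are selected.
- **Assay quantification** (`oncomir.assays`): qPCR fold changes by
  2^−ΔCt / 2^−ΔΔCt; dual-luciferase activities as firefly/renilla ratios
  normalized to same-plate mock wells; and the Coefficient of Drug
  Interaction for miR co-expression,
  `CDI = A_{a+b} / ((A_a + A_b)/2)`, ≈1 meaning no synergy.
- **Spatial TMA pipeline** (`oncomir.spatial`): merge per-core cell tables,
  exclude cells with |z| > 3 on any median-intensity channel, summarize
  cores with ≥500 tumor cells (mean median cytoplasmic miR-21, mean median
  nuclear CDK2AP1), rank cores by inverse Pearson correlation, stratify at
  miR-21 = 150, compare tumor vs stroma, and render digital core
  reconstructions.
- **Tumor-only variant filtering** (`oncomir.varfilter`): keep
  non-synonymous/splicing calls, drop variants recurring in ≥5 samples,
  with population MAF ≥1% (1000 Genomes / ESP6500 / gnomAD), and repeat
  indels; classify CNV segments (|log2 ratio| > 0.5, P < 0.05) as
  gain/loss.
- **Survival stratification** (`oncomir.survstrat`): IHC classification at
  ≥45% CDK2AP1-negative tumor cells, marker dichotomization, Kaplan–Meier
  curves and log-rank tests, including four-group two-marker stratification.
- **Synthetic cohorts** (`oncomir.syndata`): seeded generators for every
  input type with known ground truth (planted effect sizes, correlations,
  relative activities, hazard ratios, outlier fractions), so every stage is
  testable end to end without patient data.

## Worked example

Run the whole pipeline on the default synthetic study (144 patients × 3 TMA
cores, triplicate reporter plates, a 6-variant filter fixture):

```sh
oncomir run --seed 1 --outdir demo_out
```

Headline numbers from `demo_out/report.json`:

```json
"tma": {
  "n_cells": 518114,
  "excluded_fraction": 0.031802,
  "n_cores": 432,
  "mean_pearson_r": -0.581299,
  "stratification": {
    "cutoff": 150.0, "n_high": 226, "n_low": 206,
    "mean_cdk2ap1_high": 103.004562, "mean_cdk2ap1_low": 137.113259,
    "p_value": 4.33e-32, "status": "ok"
  },
  "stroma_tumor_mir21_ratio": 1.996529
}
```

The z-filter removed 3.2% of cells (3% planted artifacts plus the Gaussian
tail); the mean per-core Pearson r of −0.58 recovers the planted −0.6
anti-correlation between cytoplasmic miR-21 and nuclear CDK2AP1 (the small
attenuation is the expected log-normal bias); miR-21-high cores show lower
CDK2AP1 (103 vs 137, Welch p ≈ 4e-32); and stromal miR-21 is 2.0× the tumor
compartment, recovering the planted shift. The assays block reports, e.g.,
relative luciferase activity 0.2548 for miR-21-5p (planted 0.25) and
`CDI = 0.9986` ("additive-like") for miR-21-5p + miR-93-5p — no synergy, as
planted. The variant tally reads one removal per rule and 2 survivors,
matching the fixture's hidden truth.

Individual stages are available as subcommands (`oncomir score`,
`oncomir assay luciferase`, `oncomir tma run`, `oncomir variants filter`,
`oncomir survival km`) and as plain library functions.

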