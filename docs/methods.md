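# Methods

## Problem and scope

`ctdnatrack` implements a tumor-informed circulating tumor DNA (ctDNA)
analysis for a randomized two-arm trial setting: patient-specific somatic
mutations called in tumor tissue are tracked in plasma sequencing data,
per-sample ctDNA status feeds a biomarker-by-treatment survival analysis,
and a set of detection-theory models quantifies what a negative result can
and cannot mean. Upstream steps (alignment, variant calling, copy-number
segmentation, HLA typing, peptide-affinity prediction) are out of scope;
their outputs are the package's inputs.

## Variant identity and matching

Tissue and plasma calls are matched on the normalized
`(chrom, pos, ref, alt)` tuple. Normalization uppercases alleles, trims the
shared suffix, then trims the shared prefix (shifting `pos`), yielding the
minimal left-aligned representation; gene annotation never participates in
identity. Coordinates are 1-based inclusive everywhere; BED-style intervals
are shifted by +1 exactly once on ingest.

## Filtering and the two calling routes

The plasma filter chain is support -> population-SNP -> matched-PBMC
exclusion. De novo (tumor-naive) calls require >= 8 supporting reads for
SNVs and >= 2 for indels; any variant also called in the matched PBMC
sample is presumed germline or clonal hematopoiesis (CH) and excluded; a
configurable CH gene list only *flags* plasma-only calls for the
"CH-only patient" statistic.

Tumor-informed calling deliberately bypasses the de novo support
thresholds: a tracked variant is detected with `tracked_min_reads` (default
3) supporting reads. The rationale is that prior knowledge of the variant
converts detection into a lookup, and the route's empirical floor
(~0.07% allele fraction at 10,000x, i.e. ~7 reads) is unreachable under an
8-read rule. The filter chain therefore exposes both a thresholded call
set (naive route) and an unthresholded population/PBMC-filtered set
(informed route). A sample is informed-positive when one or more tissue
variants is detected; naive-positive when any fully filtered call reaches
the 0.5% assay LOD.

Quantification: MSAF is the maximum allele fraction over the
detected/somatic calls (0 if none). MTM/mL is mean tracked allele fraction
x cfDNA genome equivalents per mL, using 0.0033 ng per haploid genome
equivalent; the constant and formula are exposed as configuration because
no canonical definition exists.

Percentages in summary tables are rounded half-up to one decimal, the
convention under which the published marginal counts reproduce their
printed percentages (345/393 is the one fraction whose commonly quoted
figure differs by a final-digit slip; the package reports the arithmetic
87.8).

## Detection models

**Binomial LOD.** With read depth `N` and detection rule "at least `k`
supporting reads", the limit of detection at confidence `c` is the smallest
allele fraction `p` with `P(X >= k) >= c`, `X ~ Binomial(N, p)`. The exact
survival function is monotone in `p`, so the solver is a plain bisection to
relative tolerance 1e-6 (no normal approximation). `implied_min_reads`
inverts the map: given a printed LOD it reports the read rule that would
produce it. At 10,000x the 8-read LOD is ~0.135%, below the assay's quoted
0.208% SNV LOD — the quoted figures imply a stricter effective rule
(unique-molecule depth and the exact decision rule are not published), and
the package documents this calibration gap rather than tuning to it.

**Shedding regression.** Ordinary least squares of log10(MSAF) on
log10(tumor size, mm) and a squamous-histology indicator. The classifier
for informed-negative patients uses the 95% *prediction* interval for a new
tumor — `x'b ± t(df) * s * sqrt(1 + x'(X'X)^{-1}x)` on the log scale,
exponentiated — not the mean-response interval, because the question is
about an individual patient; the mean-response band shrinks with training
size and would push essentially every case to one side. Lower bound
strictly below 0.1% (five-fold below the naive LOD): potential technical
negative; at or above (boundary inclusive): non-shedder. A single-histology
training design drops the indicator with a warning. The model stores its
own interval machinery (beta, sigma, df, scaled inverse cross-product) so a
serialized model reproduces intervals exactly; tests cross-check against
statsmodels' `get_prediction`.

The shipped training table is a synthetic stand-in for the gated
early-stage cohort the published model was trained on: rows follow the
stated log-linear law with beta = (-3.0, 1.2, 0.4) and sigma = 0.5, so
fitted coefficients are placeholders, not estimates of the published ones.
Under these placeholder coefficients and the default tumor-size
distribution, nearly all informed negatives classify as non-shedders; the
published technical-negative/non-shedder split is not reproducible without
the gated data and is out of scope.

## Dynamics

Baseline (C1D1) and on-treatment (C3D1) informed statuses map onto
clearance / persistent-positive / turn-positive / persistent-negative; any
missing timepoint is NOT_EVALUABLE and never imputed. The on-treatment
grouping pools {persistent-positive, turn-positive} against {clearance,
persistent-negative}; within radiographic response strata (PR/SD/PD, CR
collapsed into PR) groups are compared by log-rank, with strata holding
fewer than two events in either group flagged untested.

## Genomic indices

* **TMB**: raw count of nonsynonymous mutations (missense, nonsense,
  frameshift, in-frame indel, splice-site, stop/start-lost), optional
  per-Mb normalization.
* **Neoantigen binders**: a peptide binds when its minimum percentile rank
  over the patient's MHC-I alleles is <= 2 (strong <= 0.5, weak
  otherwise); each peptide counted once.
* **wGII**: aberrant means total copy number != round(ploidy), ties
  half-to-even; default is the weighted convention (per-chromosome
  aberrant fraction averaged over covered chromosomes) with a pooled
  genome-wide alternative behind a flag.
* **LOH**: minor copy number 0 with >= 1 copy retained — copy-neutral LOH
  counts, homozygous deletions do not. **HRD-LOH** counts LOH segments
  > 15 Mb that do not span their whole chromosome; adjacent LOH segments
  are not merged across gaps unless `merge_gap` is given (the source
  definition is silent on merging).

## Survival statistics

Kaplan-Meier and log-rank come from lifelines. Cox fits use the
statsmodels partial-likelihood implementation because it exposes both
Efron (default) and Breslow tie handling; lifelines' independent Cox
implementation serves as a cross-check in the test suite. The predictive
analysis is one pooled model per endpoint with terms for biomarker, arm,
and their product: the arm coefficient is the treatment log-HR in the
biomarker-negative stratum, arm + product in the positive stratum (variance
by linear combination), and the differential treatment effect is the Wald
test on the product coefficient (likelihood-ratio behind a flag).
Group comparisons: two-sided Mann-Whitney for continuous variables;
Pearson chi-square without continuity correction for categorical, routed
to Fisher's exact test when any expected cell is below 5; BH step-up for
multiplicity. Confidence level 95% and alpha 0.05 throughout.

## Synthetic cohort generator

The generator defines the study conditions the tests and acceptance script
run under: 393 patients, 2:1 allocation, 10,000x plasma / 2,000x PBMC
depth, 30% squamous, tumor size log-normal around 40 mm, 24% biological
non-shedders (chosen once to match the trial's 76.1% informed positivity),
shedding law as above, ~12 tracked variants per patient with per-variant
allele fractions = MSAF x Beta(2,3) relative clonality (MSAF is the max by
construction), binomial read sampling, 25% CHIP prevalence with identical
variant identity in plasma and PBMC. Survival is exponential with the
configured stratum hazard ratios (PFS 0.45/0.74, OS 0.66/1.13 in
positive/negative strata), chemotherapy-arm medians 8 (PFS) and 17 (OS)
months — a plausible advanced-NSCLC scale, not a published value — and
administrative censoring at 30/48 months. C3D1 samples exist for ~23% of
patients with arm-specific clearance probabilities (0.40 vs 0.15).

`inject_discordance` constructs a cohort with an exact 2x2 discordance
margin: informed-only positives get tracked reads pinned into the window
detectable for tracking but below both the de novo read rule and the naive
LOD; naive-only positives get plasma-only CH-gene calls >= 0.5% absent
from tissue and PBMC. Natural discordance beyond the requested counts is
normalized back to concordance so the margin holds exactly.

What the generator does **not** emulate: read-level error and UMI
structure, mutation signatures, subclonal copy-number evolution,
informative censoring, correlated biomarker measurement error. Passing
tests therefore demonstrate correctness of the analysis logic under the
stated model, not assay performance on real specimens.

## Numerical choices and degenerate inputs

Bisection tolerance 1e-6 relative on allele fraction; Cox convergence
tolerance 1e-8 with non-finite estimates surfaced as errors (separation);
empty call sets yield NEGATIVE status with MSAF 0; `min_reads = 0` LOD is
0 with a warning; zero-depth rows, ref == alt, negative survival times and
duplicate patient ids are rejected at ingest with row numbers. Problem
sizes in the test and acceptance runs (200-replicate HR recovery at
stratum sizes 299/94, 2,000-patient coverage checks, 521-row training
tables) were chosen to keep Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

Tracked-variant read thresholds and the assay's effective unique-molecule
depth are calibrated constructs, not published values; MTM/mL uses a
package-defined formula; the shedding stand-in's coefficients are
placeholders; radiographic response in the generator is a coarse
three-level draw loosely coupled to clearance, sufficient for exercising
the stratified comparison but not a response model.
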