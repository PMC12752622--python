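"""Central registry of analysis thresholds.

Every tunable cutoff used by the pipeline lives here so that no stage
carries magic numbers. Values can be overridden per call or via the CLI.
"""

#: Minimum supporting reads for a de novo (tumor-naive) SNV call.
MIN_SNV_READS = 8
#: Minimum supporting reads for a de novo (tumor-naive) indel call.
MIN_INDEL_READS = 2
#: Minimum supporting reads to score a tissue-tracked variant as detected
#: in plasma. Prior knowledge of the variant justifies weaker evidence than
#: the de novo thresholds; detection of tracked variants down to ~0.07%
#: allele fraction at 10,000x implies a sub-8-read rule.
TRACKED_MIN_READS = 3
#: Read-level mapping-quality floor applied upstream of variant tables.
MIN_MAPQ = 60
#: Read-level mismatch ceiling applied upstream of variant tables.
MAX_MISMATCHES = 8
#: Allele-fraction limit of detection of the tumor-naive assay.
NAIVE_LOD = 0.005
#: Lower-interval threshold separating technical negatives from
#: non-shedders (five-fold below the naive LOD).
SHEDDER_THRESHOLD = 0.001
#: Target plasma cfDNA sequencing depth.
PLASMA_DEPTH = 10_000
#: Target white-blood-cell (PBMC) gDNA sequencing depth.
PBMC_DEPTH = 2_000
#: Percentile-rank cutoff for a predicted MHC-I neoantigen binder.
NEO_RANK_CUT = 2.0
#: Percentile-rank cutoff for a strong binder.
NEO_STRONG_CUT = 0.5
#: Minimum length (Mb) of a non-whole-chromosome LOH segment counted by
#: the HRD-LOH score.
HRD_LOH_MIN_MB = 15.0
#: Mass of one haploid human genome equivalent, in nanograms. Used to
#: convert cfDNA concentration into genome equivalents per mL for the
#: MTM/mL metric.
NG_PER_HAPLOID_GENOME = 0.0033
#: Confidence level used for detection limits and interval estimates.
CONFIDENCE = 0.95
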