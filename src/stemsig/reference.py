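"""Documented reference constants for the mammosphere scRNA-seq study design.

These are the QC-passing cell counts reported for the two ER+ breast cancer
cell-line mammosphere experiments and the thresholds of the QC filters that
produced them.  They serve as fixed points for regression tests and for the
pipeline's default parameters; they are not recomputed here.
"""

# QC-passing cells per cell line after the standard filters
MCF7_MS_QC_CELLS = 2974
T47D_MS_QC_CELLS = 2765
# size of the integrated two-line dataset
INTEGRATED_MS_CELLS = 5739

# QC filter thresholds: minimum expressed genes per cell, maximum
# mitochondrial read fraction
QC_MIN_GENES = 2000
QC_MAX_MITO_FRAC = 0.15

# enrichment call thresholds
ENRICHMENT_AUC = 0.6
ENRICHMENT_P = 0.01

# cohort stratification: z-score alteration threshold (standard deviations)
COHORT_Z_THRESHOLD = 2.0
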