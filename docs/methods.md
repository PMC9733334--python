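# Methods

This note documents the models behind `stemsig`, the parameters that
matter, what the synthetic-data generators do and do not emulate, and the
design choices made where conventions differ between tools.

## Preprocessing

Quality control removes cells with fewer than `min_genes` (default 2000)
expressed genes, more than `max_mito_frac` (default 0.15) of reads on
mitochondrial genes, and cells carrying an external doublet label.  No
doublet detector is implemented: doublet calls are accepted as a per-cell
label (from the simulator's ground truth, or a user-run detector).  The
filter is idempotent and reports per-reason counts.

Normalization is depth normalization to a fixed scale factor (default
10^4) followed by `log1p`; the method and scale are recorded in the
output's provenance.  Scaling is a per-gene z-score across cells (ddof 1)
clipped to ±10 to bound outlier leverage; zero-variance genes map to
all-zero rows rather than NaN so signature scores stay finite.

Clustering is PCA (20 components by default; full SVD for small matrices,
seeded randomized SVD for large ones) followed by k-means with a fixed
seed, defaulting to 4 clusters.  Any externally produced labelling can be
substituted — all downstream statistics depend only on the partition, and
relabelling permutes result rows without changing any AUC or p-value.

Multi-batch combination deliberately does **not** implement anchor-based
integration: each batch is normalized and z-scored independently on the
shared gene universe and concatenated, which removes per-batch location
effects by construction.  This is sufficient for the package's claims,
which concern enrichment logic rather than batch geometry; residual
batch-by-gene scale differences are not corrected, and the simplification
is recorded in output provenance.

## Signature scoring and AUC enrichment

A signature score is the **mean** (not sum) of per-gene z-scores, so
scores are comparable across signatures of different sizes.  Signature
genes missing from a matrix are dropped with a recorded count; an overlap
below 20% warns rather than errors, since curated collections never fully
overlap a given matrix.

Enrichment of a score in a cluster is the Mann–Whitney AUC with midranks.
The two-sided rank-sum p-value uses exact enumeration when the two groups
together hold at most 20 cells — a dynamic program over the exact null
distribution of the rank sum when scores are tie-free, full enumeration of
all in-group subsets of the midranks otherwise — and a tie-corrected
normal approximation (no continuity correction) above that.  The
enrichment call is AUC > 0.6 **and** p < 0.01 on the raw p-value; a
Benjamini–Hochberg column is emitted alongside for transparency but does
not affect the call.

Pearson correlations between signature scores are labelled by the
convention |r| ∈ [0.3, 0.5) moderate and [0.5, 0.9] strong; values outside
these bands (including near-collinear |r| > 0.9) are labelled `none`.
Multiple regression between scores is ordinary least squares with an
intercept; designs with condition number above 1e8 are rejected as
collinear.

## Cluster signatures from differential expression

Marker genes for a cluster are called by a per-gene two-sided Wilcoxon
rank-sum test (in-cluster vs rest) on normalized expression, BH-adjusted
over tested genes.  The log2 fold change is computed on de-logged
per-group means with a 1e-9 pseudocount, which is stable on sparse data.
Defaults — log2FC > 0.25, adjusted p < 0.05, expressed in ≥ 10% of
in-cluster cells, up-regulated only — mirror the standard single-cell
marker-test conventions and are recorded in each derived signature's
provenance.  Signature overlap reports are exact set arithmetic with
percentages on each base set.

## Cell-cycle scoring and regression

Phase scoring bins genes into 25 equal-occupancy bins by mean expression
and draws 50 control genes per program gene from the gene's own bin.  Two
departures from the simplest control-gene scheme matter:

1. **Program exclusion.**  Genes of either program are excluded from
   control and null pools.  In compact gene universes the (highly
   expressed) program genes can dominate the top bins, and controls drawn
   from among them cancel exactly the signal being measured.
2. **Null calibration.**  The raw score (program mean − control mean) is
   symmetric noise in cells expressing neither program, so its sign cannot
   separate quiescent cells from cycling ones.  Each program score is
   therefore calibrated against 50 random bin-matched gene sets scored per
   cell against the same controls: the stored score is the raw score minus
   (null mean + 2.5 null SD).  The 2.5-SD cut keeps the *joint* false-call
   rate across the two programs to a few percent, so a population with no
   cycling cells is called ~all G1, while program-on cells (at the 2-log2
   effects the simulator plants) remain far above zero.

A cell is G1 iff both calibrated scores are ≤ 0; otherwise the larger
score decides S vs G2M.  The packaged 43-gene S and 54-gene G2M human
symbol lists are the standard cell-cycle program lists used across the
field; users may substitute their own.

Cell-cycle regression computes least-squares residuals of every gene on
(s_score, g2m_score, intercept) and re-standardizes gene-wise so the
result is a valid z-matrix.  Residual correlation with the scores is zero
to machine precision before clipping; constant score vectors skip the
regression with a warning.

## Pathway-activity classes

Cells are classified on two signature scores by strict thresholds
(default 0, i.e. above the population mean): dual-positive, single-active
(either pathway), dual-negative; a score exactly at its threshold counts
inactive.  The threshold is a free parameter because no canonical cutoff
for "active" exists; 0 is symmetric and self-calibrating on z-scored data.
Cluster-level abundance shifts are reported as relative percent change,
100·(f_cluster − f_overall)/f_overall, with an absolute-difference mode
available, and a two-proportion chi-squared p per class.  Marker fold
changes between classes are computed on de-logged means with a pseudocount
against a reference class (default dual-negative).

## Cohort stratification and outcome tests

Bulk expression is z-scored per gene across tumors (precomputed z matrices
pass through unchanged up to idempotence).  A tumor is signature-positive
when ≥ `min_altered_genes` (default 1) signature genes have z ≥ 2; the
default direction is up-only because the package's signatures are built
from up-regulated genes, with a symmetric |z| ≥ 2 mode available.
Categorical associations use Pearson chi-squared without continuity
correction; survival endpoints use the two-group log-rank test with
Kaplan–Meier tables (via lifelines); score comparisons between strata use
Welch t-tests by default (pooled-variance optional).

## Limiting-dilution analysis

The single-hit Poisson model gives P(response | dose d) = 1 − exp(−f·d).
On the log-frequency scale this is a binomial regression with
complementary log-log link and offset log d; the intercept is estimated by
direct 1-D maximum likelihood (bounded Brent search), which remains stable
on nearly separated designs, with a Wald CI from the observed information.
A single-dose design reduces analytically to f = −log(1 − r/n)/d and the
numeric fit reproduces it.  Fully saturated designs (all or no wells
responding) have no interior MLE: they are flagged and a one-sided 95%
likelihood bound is reported instead.  Group comparison is a
likelihood-ratio test of one common frequency against per-group
frequencies, with groups − 1 degrees of freedom.

## Synthetic data

The single-cell generator draws negative-binomial counts (gamma–Poisson,
variance m + φm² with shared dispersion φ = 0.2) with log-normal gene
means (log-mean log 5, log-sd 0.5) and per-cell log-normal library-size
factors (sd 0.3).  These baselines are chosen so that ordinary cells
express comfortably more than the 2000-gene QC threshold at the default
3000-gene universe — i.e. they emulate QC-passing droplet cells — while
5% of genes are mitochondrial and contribute ~5% of reads.  Planted
programs multiply program-gene means by 2^effect in carrier clusters;
designated low-depth cells retain only half the QC gene threshold,
designated high-mito cells have mitochondrial reads inflated to twice the
QC fraction, and doublets are sums of two sampled same-batch profiles.
All randomness flows from one root seed through `SeedSequence` spawning,
so outputs are bit-reproducible.

The cycle-program generator assigns each cell a true phase (carriers split
evenly between S-on and G2M-on; carrier fraction may vary per cluster to
plant quiescent clusters) and boosts the respective program genes.  The
cohort generator produces gene-wise standard-normal expression with
signature genes shifted by `z_shift` SD in a positive subgroup,
exponential event times with the positive group's rate multiplied by the
hazard ratio, independent exponential censoring calibrated so the baseline
group is censored at the requested rate, and categorical grade/subtype
columns with configurable odds enrichment in positives.  The
limiting-dilution generator draws independent binomial well counts under
the single-hit model.

What the generators do **not** emulate: ambient RNA, UMI saturation,
gene–gene correlation beyond the planted programs, dropout beyond what the
NB produces, batch effects beyond location shifts, non-proportional
hazards, and competing risks.  Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the stated
model, not robustness to every artifact of real data.

## Problem sizes and tolerances

The test and acceptance runs use 2,000-cell simulations with 800–1,000
gene universes, 4 clusters, 2-log2 planted effects; 200-replicate null
calibrations (nominal 5% tests accepted at 2–9% rejection); 100-replicate
power runs (log-rank at hazard ratio 3, n = 500, 20% censoring; ELDA
likelihood-ratio test at a 100-fold frequency difference with 20 wells at
3 doses); and 200-replicate 95%-CI coverage checks at f = 1/1000 (accepted
at ≥ 90%).  Exactness checks (AUC pair-counting, exact rank-sum
enumeration, chi-squared by definition, ELDA closed form and grid-search
likelihood oracle) are at machine precision or 1e-4 relative as noted.

## Known limitations

- The batch-combination stand-in removes location effects only; use a
  dedicated integration method when batch geometry is the question.
- The AUC enrichment rule applies a fixed AUC > 0.6, p < 0.01 call with no
  multiplicity correction on the call itself (BH values are reported).
- K-means clustering assumes roughly convex clusters in PC space; labels
  from any other method can be supplied instead.
- ELDA assumes the single-hit model; no multi-hit or heterogeneity
  extensions are provided.
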