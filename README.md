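# stemsig

Signature-based identification of quiescent, stem-like cell populations in
single-cell RNA-seq data, with the downstream analyses that connect such a
population to patient outcomes: bulk-cohort stratification with survival
testing, and limiting-dilution estimation of tumor-initiating cell
frequency.

## Who this is for

Cancer-biology groups that profile sphere cultures (e.g. mammospheres from
ER+ breast cancer lines) or tumors by scRNA-seq and want to ask: *is there
a cluster enriched for stem-cell gene programs, is it quiescent, and does
its transcriptional signature predict outcome in bulk cohorts?*  The
package implements the complete computational chain with synthetic-data
generators for every input, so each stage is testable without any download.

## The core statistics

**Per-cell signature score.** Expression is depth-normalized
(`log(1 + 10^4 · x/total)`), z-scored gene-wise, and a signature's score in
cell *c* is the mean z over the signature's genes present in the matrix.

**AUC enrichment.** For a signature *S* and cluster *k*, enrichment is the
area under the ROC curve separating in-cluster from out-of-cluster cells on
the score — by the Mann–Whitney identity, the probability that a random
in-cluster cell outscores a random out-of-cluster cell:

    AUC = (R_in − n_in(n_in+1)/2) / (n_in · n_out)

with midranks for ties.  Significance is a two-sided Wilcoxon rank-sum
p-value (exact enumeration of the null when the groups hold ≤ 20 cells,
tie-corrected normal approximation otherwise).  A cluster is called
**enriched** when AUC > 0.6 and p < 0.01.

**Cell-cycle phase.** S and G2M program scores use expression-bin-matched
control genes and are null-calibrated against random bin-matched gene sets;
a cell with both scores ≤ 0 is G1, otherwise the larger score wins.
Cell-cycle regression residualizes every gene on the two scores and
re-standardizes, so stemness calls can be shown to survive removal of
proliferation signal.

**Cohort stratification.** A tumor is signature-positive when at least one
signature gene has expression z ≥ 2 SD above the cohort mean.  Groups are
compared by Pearson chi-squared (categorical covariates), two-group
log-rank with Kaplan–Meier tables (survival endpoints), and Welch t-tests
on the per-tumor mean-z signature score.

**Limiting dilution.** Under the single-hit Poisson model a well seeded
with *d* cells responds with probability `1 − exp(−f·d)`.  The active-cell
frequency *f* is the maximum-likelihood intercept of the equivalent
binomial model with complementary log-log link and offset `log d`, with a
Wald CI on the log scale; groups are compared by likelihood-ratio test.

## Worked example

Simulate a 2,000-cell, 4-cluster experiment with an 80-gene stem program
planted in cluster 1 (2 log2 effect), cluster it blind, and test the
program's signature across clusters:

```python
from stemsig import (SimConfig, simulate_counts, normalize_log, scale_genes,
                     cluster_cells, enrichment_table)

cfg = SimConfig(
    n_genes=1000, n_cells=2000, n_clusters=4,
    program_assignments={1: ["stem_program"]},
    program_log2_effect={"stem_program": 2.0},
    program_size=80, qc_min_genes=150, seed=0,
)
counts, truth = simulate_counts(cfg)
scaled = scale_genes(normalize_log(counts))
clusters = cluster_cells(scaled, n_clusters=4, n_pcs=20, seed=0)
table = enrichment_table(scaled, [truth.signature("stem_program")], clusters)
print(table[["signature", "cluster", "auc", "p_value", "enriched"]].round(3))
```

```
      signature  cluster    auc  p_value  enriched
0  stem_program        0  0.227      0.0     False
1  stem_program        1  1.000      0.0      True
2  stem_program        2  0.384      0.0     False
3  stem_program        3  0.296      0.0     False
```

Only the carrier cluster is called enriched: its AUC of 1.000 means every
in-cluster cell outscores every out-of-cluster cell.  The other clusters
have tiny p-values too — they are significantly *depleted* (AUC well below
0.5) — but the AUC > 0.6 requirement keeps them negative.

The same logic is available from the shell.  A limiting-dilution table
(`dose  tested  response  group`) comparing mammosphere-derived against
2D-cultured cells:

```bash
$ stemsig elda lda.tsv
group  frequency       one_in  ci_low  ci_high saturated
   2D   0.000082 12269.459487 0.00003 0.000222
   MS   0.001203   831.412096 0.00048 0.003013
group comparison: LRT chi2 = 15.106, df = 1, p = 0.0001016
```

One tumor-initiating cell per ~831 mammosphere cells versus ~1 per 12,000
in 2D culture, a difference the likelihood-ratio test calls at p ≈ 1e-4.

Other subcommands: `simulate`, `qc`, `score`, `enrich`, `derive-signature`,
`cellcycle`, `classify`, `stratify`, and `run` (full pipeline from a YAML
config).

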