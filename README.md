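# txmod

Transcriptional-module deconvolution of bulk immune transcriptomes.

Bulk RNA-seq of mixed-cell samples — whole blood, bronchoalveolar lavage
(BAL) — confounds two things: changes in what cells *do* and changes in which
cells are *there*. `txmod` implements a module-based workflow to pull these
apart without single-cell sequencing:

1. **Module derivation.** From sorted-cell reference transcriptomes, a cell
   type's module is the set of genes significantly elevated in the cognate
   population versus comparator populations (BH q < 0.05, elevated in every
   comparison under the default intersection rule). Central/effector-memory
   (CM/EM) CD8 modules use a different rule: two-sided t-test p < 0.01
   (uncorrected) and a strict >10-fold difference of linear-scale means.
2. **Module scoring.** The score of module *M* in sample *s* is the geometric
   mean of its genes' linear expression, computed on log2(CPM+1):
   `score(M, s) = (1/|M|) * sum_{g in M} log2(CPM_gs + 1)`.
   It proxies the relative abundance (or activity) of the cognate cell type
   in the bulk sample.
3. **Regression attribution.** For each gene *g*, fit
   `expr_g = a_g + b_g * score(M) + e_g` by OLS across samples and re-test the
   condition contrast on the residuals `e_g`. If significance is *abrogated*
   by regressing on one cell type's module but survives regression on the
   others, the condition signal is attributed to that cell type.

Around this core the package provides the standard plumbing: count-matrix QC
(genes detected in <15 samples discarded; libraries with <500,000 reads or
<10,000 detected genes excluded), log-CPM normalization, a lightweight
two-group DE engine (Welch t / empirical-Bayes moderated t / Mann-Whitney)
with Benjamini-Hochberg control at FDR 0.05, hypergeometric
over-representation, PCA, GMT/TSV/MatrixMarket I/O, and a synthetic-cohort
generator with known ground truth (cell fractions, marker maps, induced
programs) that makes every stage testable end to end.

## Worked example

`examples/04_attribution.py` simulates a paired blood/BAL cohort in which the
HIV-like condition expands the effector-memory CD8 fraction 1.8-fold in every
compartment, derives modules from simulated sorted cells, selects the BAL
genes with a nominal condition difference, and attributes them:

```
10 focal genes; Mann-Whitney p before/after regression:
        unadjusted  CD8_EM  CD8_CM     CD4       B
G00043      0.0312  0.6776  0.0452  0.1041  0.0257
G00044      0.0003  0.1620  0.0002  0.0640  0.0003
...
significant fraction: unadjusted 1.00, after CD8_EM 0.00, after B 0.80
```

Every focal gene is significant before adjustment; regressing each gene on
the EM CD8 module score removes all significance (the signal is carried by
the EM fraction), while regressing on the uninvolved B-cell module leaves 80%
significant. That asymmetry is the attribution: the BAL condition signal
reflects EM CD8 T-cell enrichment, not B cells.

The other examples cover cohort simulation (`01`), module derivation and
AUROC validation (`02`, all eight cell-type modules reach cognate-vs-rest
AUROC 1.0 at default separation), module scoring with per-compartment
Mann-Whitney tests (`03`), and the full pipeline with truth-recovery metrics
(`05`). A thin CLI mirrors the stages
(`txmod simulate-cohort | qc | de | derive-modules | score | attribute |
run-all`).

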