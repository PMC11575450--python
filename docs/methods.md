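# Methods

## Scope and model

`txmod` quantifies immune-cell composition and attributes condition-associated
differential expression in bulk transcriptomes of two compartments (whole
blood and bronchoalveolar lavage, BAL) profiled under a two-level condition
(here labeled HIVneg/HIVpos). The compartments are analyzed independently
throughout — separate QC, differential expression, module testing and
attribution — because cross-compartment exchange is not modeled.

### Module scores

A transcriptional module is a named gene set marking a cell type or cytokine
response. Its per-sample score is the geometric mean of the constituent
genes' linear expression. Scores are computed and reported in log2 units —
the arithmetic mean of log2(CPM + 1) over module genes — which is identical
to the antilogged geometric mean (tested to 1e-10) and more convenient for
regression and plotting. The pseudocount is mandatory: a geometric mean is
undefined at zero. Genes missing from the expression matrix are dropped and
reported as a coverage fraction; below 50% coverage (configurable) the score
is flagged unreliable but still computed, since published module lists rarely
share a complete gene universe with a user's matrix.

### Module derivation

A cell type's module is derived from sorted-cell transcriptomes as the genes
significantly elevated (BH q < 0.05, positive log2 fold change) in the
cognate population relative to comparator populations. A derivation plan
lists one or more comparator sets; under the default **intersection** rule a
gene must be elevated versus every comparator set (the stricter reading,
which maximizes specificity), under the optional **union** rule versus any
one. Typical plans: lineage-specific (CD4 vs CD8, CD4 vs MAIT — two singleton
sets) or "cognate versus all others pooled" (one set). Provenance (plan,
thresholds, engine, dataset hash) is stored with every module and written
next to the GMT output.

The derivation engine defaults to an empirical-Bayes **moderated t** (pooled
two-sample t whose per-gene variance is squeezed toward a prior fitted by
Smyth's method of moments, prior df estimated by trigamma inversion). With
~5 replicates per sorted population, an unmoderated test's far tail is
dominated by chance-small variance estimates; once a module's true markers
occupy the top BH ranks, those tail genes ride along under the step-up
threshold and contaminate the module. Variance moderation is the standard
remedy and restores module precision from ~0.7 to ~0.99 on the synthetic
references. Welch t and Mann-Whitney remain available via the pluggable
`method` argument.

CM/EM (central/effector-memory) CD8 modules use a distinct two-part rule:
two-sided t-test p < 0.01 with no multiplicity correction, *and* a strictly
greater than 10-fold difference of linear-scale means (pseudocount-protected;
a gene at exactly 10.0-fold is excluded). The t-test runs on log2 expression,
the fold on linear CPM — a fold rule is a linear-scale statement. The two
modules are disjoint by construction. Noise-free degenerate inputs are
handled by a fixed convention: zero variance in both groups gives p = 1 when
the means are equal and p = 0 when they differ.

Specificity of any module collection is validated on labeled expression by
scoring every sample and computing the cognate-vs-rest AUROC per module plus
the rank of the cognate type's mean score (a module passes when the cognate
ranks first).

### Regression attribution

To ask whether a gene's condition effect merely reflects a shift in one cell
type's abundance, each gene is regressed (OLS, one covariate plus intercept)
on that cell type's module score across samples, and the two-group test is
repeated on the residual matrix. Residuals are orthogonal to the centered
score by construction; regressing the same score twice changes nothing
(slopes of the second pass are ~0). The grid of p-values — one "unadjusted"
column plus one column per module, star-coded at 0.05/0.005/0.0001 — makes
attribution visual: a column that erases significance names the mediating
cell type. Group testing on residuals defaults to Mann-Whitney (Welch
optional); residuals are not counts, so a count-model test would be
inappropriate. Module quantification on residual matrices uses the
arithmetic mean of residuals (geometric means are undefined on negatives);
the deviation is recorded in the score units.

Focal genes for attribution are *selected* significant genes — the
compartment's BH-significant up-list when nonempty, mirroring how such gene
lists arise in practice. At the default synthetic cohort size the
composition-mediated BAL signal rarely clears genome-wide BH correction (a
1.8-fold fraction shift bounds every mediated gene's group fold change at
1.8, against a within-group log2 SD of ~0.65 from the count noise alone), so
the demonstration falls back to screening the true effector-memory markers
for a nominal Mann-Whitney p < 0.05; the selection mode is recorded in the
output. The abrogation contrast is evaluated on the selected genes, exactly
as it would be on a real selected gene list.

### QC, normalization, DE, and supporting statistics

- **Gene filter:** keep genes with count > 0 in at least 15 samples.
- **Library filter:** exclude samples with fewer than 500,000 reads (from a
  `total_reads` metadata column when present, else column sums) or fewer than
  10,000 detected genes. Both are strict less-than exclusions; boundary
  values are retained. Alignment-rate/exon-rate columns are accepted as
  metadata but not computed (no BAM access).
- **Normalization:** log2(count * 1e6 / library_size + 1). The pseudocount
  sits on the CPM scale, so the transform is invariant to sequencing depth.
- **DE engine:** per-gene two-group contrast on log2(CPM+1); Welch t by
  default, moderated t or Mann-Whitney (tie-corrected normal approximation)
  by flag; BH step-up q-values; significance at q < 0.05. The engine is
  deliberately simple and pluggable — the package's contribution is the
  module/attribution machinery, not a count-model DE method — and a
  negative-binomial engine can be substituted behind the same interface.
- **Mann-Whitney:** exact tail enumeration when both groups have <= 8
  observations and no cross-group ties; tie-corrected normal approximation
  otherwise (the 10-vs-10 cohort arms use the approximation).
- **Overlap bookkeeping:** two up-lists are summarized with a
  pooled-with-multiplicity denominator, percent = 100 * shared / (nA + nB),
  rounded half-up for display.
- **ORA:** one-sided hypergeometric upper tail per gene set (sets intersected
  with the universe first), BH across sets.
- **PCA:** per-gene centering, full SVD, deterministic sign (largest-magnitude
  loading positive).

## Synthetic cohort generator

The generator emulates the statistical structure of a paired blood/BAL cohort
so that every stage has a known truth. What it models:

- **Gene universe** (default 2,000 genes): lognormal(0, 1) relative
  abundances. Disjoint index blocks are reserved for each cell type's markers,
  each induced program, and the two memory programs. Marker and memory blocks
  are rescaled to equal total base weight so all cell profiles share one
  normalizer — cell types then differ *only* on their markers, keeping the
  marker truth sharp rather than leaking compositional fold-changes into
  every background gene.
- **Cell types** (8): CD4, CD8_CM, CD8_EM, MAIT, NK, B, monocyte,
  macrophage; 20 markers each, elevated 6 log2 (64x) in the cognate profile.
  64-fold cognate enrichment is typical of canonical lineage markers.
- **Mixing proportions:** blood lymphocyte/monocyte dominant (CD4 0.30,
  monocyte 0.23, ...), BAL macrophage dominant (0.60). Per-sample fractions
  are Dirichlet-jittered around the compartment mean (concentration 200 x
  mean vector, i.e. modest inter-individual variability).
- **Condition effects:** multiplicative proportion shifts, renormalized —
  CD4 x0.5, CD8_EM x1.8 for the HIV-like condition — plus cytokine-inducible
  programs (default: one 30-gene interferon-like program, +1.5 log2, blood
  only) applied multiplicatively to the mixture and renormalized (fixed
  sequencing depth is compositional).
- **Counts:** negative binomial, var = mu + 0.2 mu^2 (single shared
  dispersion), library sizes log-uniform in [5e5, 2e6] — above the
  500,000-read QC floor. Dispersion below 1e-8 falls back to Poisson.
- **Design:** 10 bulk samples per compartment x condition cell (40 total);
  5 replicates per sorted reference population; 12 replicates per CM/EM
  memory subset (a multi-donor sorted-subset panel) with two disjoint
  30-gene programs at 12-fold — above the 10-fold rule so derivation is
  exercised with margin.
- **Determinism:** one integer seed feeds named SeedSequence substreams
  (universe, references, bulk, memory); identical configuration gives
  bitwise-identical output.

What it does **not** model: batch effects, gene-length bias, isoform
structure, gene-gene correlation beyond the mixture itself, compartment
crosstalk, or read-level noise. Passing tests therefore demonstrate that the
machinery recovers composition signal under clean mixture assumptions, not
that it is robust to every artifact of real data.

## Problem sizes and numerical choices

The test suite and acceptance script run the generator at its default sizes
(2,000 genes, 40 bulk samples, 40 reference samples) across 10–20 seeds per
property — sizes chosen so a full sweep completes in seconds while keeping
per-seed power representative of the emulated cohort. The demo pipeline caps
the detected-genes QC floor at half the simulated gene universe, since the
genome-scale default (10,000) is unsatisfiable on 2,000 genes. Null-cohort
calibration has intrinsic binomial noise: with two compartments of 2,000
calibrated tests each, the probability that a null cohort yields zero BH
discoveries is ~0.90, so the observed fraction over 20 seeds moves a few
percent around that value from seed set to seed set.

## Known limitations

- The DE engine is a two-group contrast without covariates, shrinkage of fold
  changes, or count-model dispersion sharing; it is not a DESeq2/edgeR
  replacement.
- Attribution is one module at a time (matching the column-wise design of the
  attribution grid); collinear cell fractions can make single-module
  regressions remove shared signal, and no joint or causal mediation model is
  attempted.
- Module scores are relative: they order samples by cognate-cell content but
  are not calibrated cell fractions.
- Gene identifiers are opaque strings; no namespace mapping is attempted.
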