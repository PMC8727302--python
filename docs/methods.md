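# Methods

This note documents the models, estimators and numerical conventions behind
`relapse-score`, the defaults it ships with and why, and what the synthetic
cohorts do and do not establish about real data.

## Preprocessing

Filters run in a fixed order, recorded in the matrix's provenance list:

1. **Mitochondrial gene removal.** Mitochondrial content is highly variable
   in plate-based scRNA-seq; these genes are dropped before anything else.
2. **Transcript threshold.** Cells with fewer than 500 remaining transcripts
   are removed. The threshold is inclusive (a cell with exactly 500 is
   kept).
3. **Gene blacklist.** XIST/TSIX, Y-chromosome and hemoglobin genes are
   removed: sex-linked genes encode donor sex rather than biology of
   interest, and hemoglobin marks erythrocyte contamination.
4. **Healthy-cell exclusion.** Contaminating healthy T cells are removed by
   a marker-module z-score filter: cells whose T-cell marker-module score
   exceeds `mean + 2·SD` are excluded and reported. This replaces manual
   inspection of clusters with a deterministic, auditable rule; the
   threshold is configurable. Clustering itself is out of scope.
5. **Normalization.** Each cell is rescaled to a common transcript budget
   (default 3500) and log-transformed: `x = log(1 + count·3500/total)`.
   Normalization runs after all cell filters (the alternative ordering is
   indistinguishable for the downstream statistics, but one order had to be
   fixed and documented).
6. **Gene scaling** (for PCA only): per-gene z-score with **sample SD
   (n−1)**. Zero-variance genes become zero columns and are flagged, not
   dropped, so gene indices stay aligned across stages.

One normalization scheme is used for all data. Regularized-regression
normalization schemes used for some droplet datasets are deliberately not
implemented: the classification is robust across platforms, and a single
count-based normalization keeps the pipeline self-contained and exactly
testable.

## Module scores

Genes are ranked by mean expression across cells and partitioned into 24
near-equal bins (24 is the long-standing default of the binned-control
scoring scheme; the bin count is configurable). Genes with exactly equal
means always share a bin so results cannot depend on sort-tie behavior; if
that collapses bins a warning is emitted.

For each signature gene one control set of `n_ctrl = 100` genes is drawn
from its bin, **excluding all genes of the signature being scored**, with
replacement only when the bin holds fewer than 100 admissible genes (this
keeps the estimator defined on toy fixtures). Control sets are drawn once
and reused for every cell: per-cell resampling would break determinism and
add noise without changing the estimand. The per-cell score is the mean over
signature genes of (gene expression − mean control expression). Two exact
consequences, both tested: a cell-wide constant shift cancels exactly, and a
matrix whose columns are identical within each cell scores exactly zero.

The **PC score** projects cells on the leading principal component of the
gene-scaled expression restricted to the union of the two modules (SVD of
the centered submatrix). The sign of a principal component is arbitrary, so
it is oriented data-dependently: flipped if negatively correlated with the
sensitivity module score, making high PC = predicted sensitive. Module
scores use normalized (unscaled) values; the PC score uses scaled values.

## Categorization, patient summaries, risk calls

The median-quadrant rule uses medians of the **complete dataset** passed in
— cross-patient, never per patient (a per-patient median would erase exactly
the between-patient differences the method measures; a test documents the
contrast). Inequalities are strict: cells tied with a median stay
unclassified, which makes the rule well defined on discrete score
distributions and caps each category at ⌈n/2⌉. For control-vs-treated
comparisons the two samples are pooled before computing medians — the only
choice under which the two fractions are comparable.

Per patient: sensitive/resistant fractions, PC-score mean and SEM (sample
SD, n−1; a single-cell patient gets a missing SEM), and a risk call. The
default rule — predicted relapse iff `frac_resistant > frac_sensitive`,
with exact ties called no-relapse (conservative toward the unclassified
mass) — is an explicit stand-in: no quantitative decision boundary is
published for this classification, so the rule is pluggable and always
recorded in the output.

## Differential expression and correlation

Per-gene two-sided Wilcoxon rank-sum between the sensitive and resistant
cells: exact null distribution for tie-free groups of ≤10 cells, otherwise
the tie-corrected normal approximation with continuity correction. Genes
enter testing only if expressed in ≥10% of cells of at least one group;
Bonferroni correction uses the number of genes actually tested (the
prefilter makes "all genes" ambiguous, so the choice is fixed and recorded).
The fold change is `ln(mean(expm1 x)+1)` per group, differenced — the
natural-log fold change on the depth-normalized scale — and a gene is
flagged at adjusted p < 0.05 with |lnFC| > 0.20. No balancing of group
sizes is performed by default; the quadrant rule does not guarantee equal
groups, and subsampling to balance is available to the caller but off.

Gene–score association is Spearman rank correlation (average ranks for
ties); constant genes are reported as missing rather than zero.

## Pseudobulk

*Complete* pooling sums all transcripts per sample; it preserves transcript
mass exactly. *Equal-contribution* pooling first downsamples each cell
without replacement (multivariate hypergeometric) to a common depth `d`
(default: the minimum cell total), so every contributing cell contributes
exactly `d` transcripts; cells below `d` are dropped and counted in the
output. Without-replacement sampling is the only reading under which "equal
contribution" is exact. Pseudobulk profiles are then normalized and scored
exactly like cells, with samples in the role of cells; at least two samples
are required because expression binning needs cross-sample means.

Because resistant cells carry fewer transcripts, their share of a
complete-pooled profile is strictly below their share of cells, and equal
pooling restores it — both facts are asserted in the tests. Note a subtlety
established while designing the pseudobulk experiment: this
under-representation is a monotone compression of the signal and therefore
cannot, by itself, reduce a standardized group difference; it degrades
discrimination only relative to patient-level variation that does not scale
with the signal. The generator therefore includes coherent per-patient
program offsets (below), without which the phenomenon cannot exist in any
simulation.

## Synthetic cohorts

The generator emulates the statistical structure the analysis relies on:

* **Latent resistance.** Per cell, a level in [0, 1] from a patient-specific
  Beta distribution. The per-patient (a, b) are either given directly or
  derived by numerically inverting the Beta tail so that
  `P(latent > 0.5)` — the planted resistant fraction — hits a target;
  default targets are evenly spaced over [0.05, 0.60] across patients. The
  latent level is continuous, not a clone label, matching the observed
  continuum from sensitivity to resistance.
* **Programs.** Resistance-program gene means scale as
  `exp(+effect·loading·(latent−0.5))`, sensitivity genes with the opposite
  sign; loadings are gene-specific (uniform 0.5–1.5) and `program_effect`
  defaults to 2.0, i.e. a mean natural-log fold change of ~2 across the full
  continuum — the strong end of a treatment-response signature.
* **Depth.** Expected library size interpolates linearly from 4000
  (sensitive) to 1500 (resistant) transcripts. No quantitative depth
  difference is published, only that resistant cells carry substantially
  fewer transcripts; these plate-based-scale values are plausible
  placeholders and are clearly exposed as parameters.
* **Counts.** Negative binomial via a gamma–Poisson mixture
  (inverse-dispersion 2.0); dropout arises from low means, with no separate
  zero-inflation term.
* **Patient structure.** Log-normal mean offsets (SD 0.3) on a random 20% of
  genes per patient reproduce patient-wise clustering, plus a coherent
  per-patient log-offset on each program as a whole
  (`program_patient_sd`, default 0.10): real patients differ in where their
  module-score distributions sit, not only gene by gene. The default is
  small enough that the planted resistant fraction remains the dominant
  patient-level signal — the regime in which the single-cell classification
  is reported to work — while the pseudobulk experiment (below) uses 0.25,
  the bulk-cohort regime where patient heterogeneity is strong.
* **Contaminants.** A fraction (default 5%) of healthy T-like cells with
  their own marker program (30 genes boosted 8×), baseline programs, and
  sensitive-level depth, so the exclusion filter is exercised.
* **Outcome.** Relapse iff the realized planted resistant fraction exceeds
  0.30. With the default targets this yields 8 relapsing and 7 relapse-free
  patients in the 15-patient reference cohort, mirroring the composition of
  the study cohort this pipeline is modeled on. Label noise is available as
  an option for robustness tests.
* **Seeding.** One master seed; every patient draws from its own
  counter-derived stream, so adding patients (with pinned per-patient
  parameters) never perturbs existing ones, and all outputs are
  bit-reproducible from the config.

The in-silico selection operator retains each cell with probability
`kill_curve(latent)` — emulating glucocorticoid exposure, which removes
sensitive cells preferentially. Contaminants are treated as fully sensitive.

**What the generator does not model:** fusion-oncogene biology, clonal
genetic structure, realistic gene–gene covariance beyond the two programs
and patient offsets, cell-cycle structure, ambient RNA, or doublets.
Passing tests therefore show that the estimators recover planted structure
of the stated form at realistic noise levels — not that the biological
signature itself generalizes.

## Reference conditions and problem sizes

* Reference cohort: 15 patients × 300 cells × 2000 genes (370 + 78 program
  genes, 70 flagged special genes), defaults as above.
* Selection experiment: one 1200-cell sample (target resistant fraction
  0.25), split into control/treated halves, survival = latent level, scored
  and categorized as one pooled dataset; 50 replicates.
* Pseudobulk experiment: 12 patients × 120 cells × 800 genes,
  `program_patient_sd = 0.25` and depth means 4000/800 — the pronounced
  depth-asymmetry, heterogeneous-cohort regime the depth-bias phenomenon
  concerns; 50 replicates, win measured as a larger standardized mean
  difference of the bulk resistance score between planted outcome groups.
* Technology-concordance check: the same latent patients drawn at a
  deep/few-cell regime (8000/3000 depth, 150 cells) and a shallow/many-cell
  regime (3000/1100, 500 cells); risk calls agree on ≥90% of patients.

## Numerical conventions and edge cases

* Sample SD (ddof = 1) everywhere a SD or SEM is reported.
* Expression-bin ties: genes with equal means share a bin (stable rule).
* Median ties: unclassified. Risk-call ties: no-relapse.
* Empty results (all cells filtered, nothing survives selection) raise an
  explicit `EmptyResultError` rather than returning silent empty objects.
* Matrix Market files store genes as rows (the 10x convention); in-memory
  orientation is always cells × genes, converted only at the I/O boundary.
* Gene identity is the symbol string; no alias resolution.
* The published description of the module scoring mentions unspecified
  modifications to the standard routine; this implementation follows the
  verbal algorithm exactly as stated, and whether the original excluded
  signature genes from their own control sets is unstated — they are
  excluded here.

## Known limitations

* The patient-level decision boundary is a stand-in (see above); with real
  cohorts it should be calibrated and the choice reported.
* Equal-contribution pooling discards cells below the common depth; the
  dropped count is reported so the induced bias is visible.
* Bulk scoring of a single sample is impossible by construction (binning
  needs cross-sample means); supply a reference panel.
* The generator's effect sizes are stand-ins wherever the literature gives
  no number; conclusions about real-data power must not be read off the
  synthetic defaults.
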