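# relapse-score

Single-cell drug-sensitivity scoring and relapse-risk classification for
leukemia cohorts.

In infant acute lymphoblastic leukemia driven by *MLL*/*KMT2A*
rearrangements, most blasts respond to glucocorticoid-based induction
therapy, yet the majority of patients relapse — plausibly because a small,
quiescent subpopulation of therapy-resistant cells survives treatment and
seeds the relapse. This package implements a transcriptomic pipeline that
detects that subpopulation in diagnostic scRNA-seq samples and turns its
abundance into a patient-level relapse-risk call. It is aimed at
computational biologists who want the classification machinery as a tested,
reusable library rather than as an analysis notebook, together with a
synthetic-cohort generator that makes every stage testable without access to
controlled patient data.

## Method

Each cell `c` is scored against two directed gene sets: a **sensitivity
module** (genes apparently downregulated after in vivo glucocorticoid
treatment — markers of cells the drug eliminates) and a **resistance
module** (apparently upregulated genes — markers of surviving cells).  The
module score is the binned-control statistic standard in single-cell
signature scoring:

    score(c) = (1/|M|) * sum_{g in M} [ x_cg − mean_{g' in C(g)} x_cg' ]

where `x` is log, depth-normalized expression (every cell scaled to the same
transcript budget, default 3500), each signature gene `g` is compared to a
control set `C(g)` of 100 genes drawn from the same average-expression bin
(24 bins), and control sets are drawn once and shared across cells.  The
subtraction of bin-matched controls cancels cell-wide technical shifts
exactly.

Cells are categorized by the **median-quadrant rule**: sensitive if the
sensitivity score is above the dataset-wide median and the resistance score
below its median; resistant in the mirrored case; unclassified otherwise.
Per patient the pipeline reports the sensitive/resistant cell fractions, the
mean ± SEM of a **PC score** (projection on the first principal component of
the union of module genes, oriented so high = predicted sensitive), and a
risk call — by default *predicted relapse iff the resistant fraction exceeds
the sensitive fraction*.

Supporting analyses: Wilcoxon rank-sum differential expression between
sensitive and resistant cells (Bonferroni-corrected, natural-log fold-change
threshold 0.20), Spearman correlation of every gene with either module
score, and pseudobulk construction by complete pooling or by
equal-contribution pooling (each cell downsampled without replacement to a
common depth) — the latter matters because resistant cells carry fewer
transcripts and are under-represented in naively pooled "bulk" data.

The synthetic generator plants a per-cell latent resistance level (Beta
distributed per patient) that drives anti-correlated expression of the two
gene programs, lower library sizes in resistant cells, and a per-patient
outcome label (relapse iff the planted resistant fraction exceeds a
threshold), with negative-binomial counts, per-patient expression offsets
and optional healthy T-like contaminants.  See `docs/methods.md` for the
full model and parameter rationale.

## Worked example

```python
import relapse_score as rs

cfg = rs.RunConfig(seed=0, sim={
    "n_patients": 5, "cells_per_patient": 150, "n_genes": 800,
    "n_sens_genes": 120, "n_res_genes": 40,
    "target_resistant_fractions": [0.08, 0.2, 0.3, 0.42, 0.55]})
manifest = rs.run_pipeline(cfg, "demo_run")
print(manifest["report"])
```

prints

```
# Relapse-risk report

| patient | n_cells | frac_sensitive | frac_resistant | mean_pc | risk_call | outcome |
|---|---|---|---|---|---|---|
| P01 | 147 | 0.782 | 0.109 | 4.849 | predicted-no-relapse | no-relapse |
| P02 | 139 | 0.525 | 0.410 | 0.813 | predicted-no-relapse | no-relapse |
| P03 | 145 | 0.414 | 0.462 | -0.604 | predicted-relapse | relapse |
| P04 | 144 | 0.326 | 0.521 | -1.517 | predicted-relapse | relapse |
| P05 | 145 | 0.186 | 0.738 | -3.585 | predicted-relapse | relapse |

Prediction accuracy: 5/5 (relapse 3/3, no-relapse 2/2)
```

Each row is one diagnostic sample: `frac_sensitive`/`frac_resistant` are the
fractions of that patient's cells falling in the sensitive and resistant
median quadrants, `mean_pc` is the patient's average position along the
sensitivity–resistance continuum (positive = sensitive side), and the risk
call compares the two fractions.  Here the three patients with the largest
planted resistant subpopulations are called high-risk, matching their
simulated outcomes.

The same stages are available from a shell:

```bash
relapse-score simulate --out sim --seed 0
relapse-score preprocess --counts sim/counts --out pp
relapse-score score --norm pp/normalized.csv --modules sim/modules.csv --out scores.csv --seed 0
relapse-score classify --scores scores.csv --meta pp/cells_meta.csv \
    --patients sim/patients_meta.csv --out summary.csv
relapse-score run --out full_run --seed 0     # everything at once
```

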