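"""Differential expression, gene-score correlation, and pseudobulk pooling.

Differential expression between sensitive and resistant cells is a per-gene
two-sided Wilcoxon rank-sum test (exact for small tie-free groups, otherwise
the tie-corrected normal approximation), Bonferroni-corrected over the genes
actually tested.  The fold change is the natural-log ratio of the group means
on the depth-normalized scale, ``ln(mean(expm1(x)) + 1)`` per group, and a
gene is flagged significant at adjusted p < 0.05 with |lnFC| > 0.20.

Pseudobulk ("bulkified") profiles come in two flavours: *complete* pooling
sums every transcript, so deep cells dominate; *equal* pooling first
downsamples every cell without replacement (multivariate hypergeometric) to a
common depth ``d`` so each cell contributes the same number of transcripts.
Because therapy-resistant cells carry fewer transcripts, complete pooling
under-represents them and equal pooling restores their share.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.stats

from ._utils import as_matrix

EXACT_MAX_GROUP = 10  # exact Wilcoxon enumeration up to this group size


def _wilcoxon_p(xa: np.ndarray, xb: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p for one gene."""
    if len(xa) <= EXACT_MAX_GROUP and len(xb) <= EXACT_MAX_GROUP:
        ties = len(np.unique(np.concatenate([xa, xb]))) < len(xa) + len(xb)
        method = "asymptotic" if ties else "exact"
    else:
        method = "asymptotic"
    return float(
        scipy.stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method).pvalue
    )


def differential_expression(
    norm,
    labels: pd.Series,
    group_a: str = "sensitive",
    group_b: str = "resistant",
    min_pct: float = 0.1,
) -> pd.DataFrame:
    """Wilcoxon rank-sum DE between two labelled cell groups.

    Genes are tested only when expressed (value > 0) in at least ``min_pct``
    of the cells of one of the groups.  Returns a DataFrame indexed by gene
    with columns ``lnFC`` (group_a minus group_b, natural log), ``p``,
    ``p_bonferroni``, ``pct.1``/``pct.2`` (expressing fraction per group) and
    ``significant``.
    """
    X, cells, genes = as_matrix(norm)
    labels = labels.reindex(cells)
    in_a = (labels == group_a).to_numpy()
    in_b = (labels == group_b).to_numpy()
    if in_a.sum() == 0 or in_b.sum() == 0:
        raise ValueError(f"both groups must be non-empty ({group_a}: {in_a.sum()}, {group_b}: {in_b.sum()})")
    Xa, Xb = X[in_a], X[in_b]
    pct_a = (Xa > 0).mean(axis=0)
    pct_b = (Xb > 0).mean(axis=0)
    tested = (pct_a >= min_pct) | (pct_b >= min_pct)

    ln_fc = np.log(np.expm1(Xa).mean(axis=0) + 1) - np.log(np.expm1(Xb).mean(axis=0) + 1)

    pvals = np.full(len(genes), np.nan)
    idx = np.flatnonzero(tested)
    if len(Xa) <= EXACT_MAX_GROUP and len(Xb) <= EXACT_MAX_GROUP:
        for j in idx:
            pvals[j] = _wilcoxon_p(Xa[:, j], Xb[:, j])
    elif len(idx):
        res = scipy.stats.mannwhitneyu(
            Xa[:, idx], Xb[:, idx], alternative="two-sided", method="asymptotic", axis=0
        )
        pvals[idx] = res.pvalue
    n_tested = int(tested.sum())
    p_bonf = np.minimum(pvals * n_tested, 1.0)

    out = pd.DataFrame(
        {
            "lnFC": ln_fc,
            "p": pvals,
            "p_bonferroni": p_bonf,
            "pct.1": pct_a,
            "pct.2": pct_b,
            "tested": tested,
        },
        index=genes,
    )
    out["significant"] = (out["p_bonferroni"] < 0.05) & (out["lnFC"].abs() > 0.20)
    out["significant"] = out["significant"].fillna(False)
    out.attrs["n_tested"] = n_tested
    return out


def correlate_genes_with_scores(norm, scores) -> pd.DataFrame:
    """Spearman correlation of every gene with the sensitivity and resistance
    module scores (average-rank ties; constant genes yield NaN)."""
    X, cells, genes = as_matrix(norm)
    table = getattr(scores, "table", scores).loc[cells]
    if X.shape[0] < 3:
        raise ValueError("Spearman correlation needs at least 3 cells")
    ranks = scipy.stats.rankdata(X, axis=0)
    ranks = ranks - ranks.mean(axis=0)
    denom_g = np.sqrt((ranks**2).sum(axis=0))
    out = {}
    for col, name in (
        ("sensitivity_score", "rho_sensitivity"),
        ("resistance_score", "rho_resistance"),
    ):
        s = scipy.stats.rankdata(table[col].to_numpy())
        s = s - s.mean()
        denom_s = np.sqrt((s**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (ranks.T @ s) / (denom_g * denom_s)
        rho[denom_g == 0] = np.nan
        out[name] = rho
    return pd.DataFrame(out, index=genes)


@dataclasses.dataclass
class PseudobulkResult:
    """Per-sample pooled profiles plus the pooling metadata."""

    profiles: pd.DataFrame  # samples x genes, integer totals
    mode: str  # "complete" or "equal"
    d: int | None  # per-cell contribution depth (equal mode)
    cells_used: pd.Series  # per sample
    cells_dropped: pd.Series  # per sample (equal mode: cells with total < d)


def pool_bulk(
    counts,
    sample_map: pd.Series,
    mode: str = "complete",
    d: int | str | None = "auto",
    seed: int | np.random.Generator = 0,
) -> PseudobulkResult:
    """Pool single-cell counts into per-sample pseudobulk profiles.

    ``complete`` sums all transcripts of all cells.  ``equal`` first
    downsamples each cell without replacement to exactly ``d`` transcripts
    (``d="auto"`` uses the minimum cell total); cells with fewer than ``d``
    transcripts are dropped and reported in ``cells_dropped``.
    """
    X, cells, genes = as_matrix(counts)
    X = np.asarray(np.rint(X), dtype=np.int64)
    sample_map = sample_map.reindex(cells)
    if sample_map.isna().any():
        raise ValueError("sample_map does not cover every cell")
    totals = X.sum(axis=1)
    samples = pd.unique(sample_map)

    if mode == "complete":
        rows, used, dropped = {}, {}, {}
        for s in samples:
            m = (sample_map == s).to_numpy()
            rows[s] = X[m].sum(axis=0)
            used[s] = int(m.sum())
            dropped[s] = 0
        prof = pd.DataFrame(rows, index=genes).T
        return PseudobulkResult(prof, "complete", None, pd.Series(used), pd.Series(dropped))

    if mode != "equal":
        raise ValueError(f"unknown pooling mode {mode!r}")
    if d in (None, "auto"):
        d = int(totals.min())
    d = int(d)
    if d <= 0:
        raise ValueError("per-cell depth d must be positive")
    if not np.any(totals >= d):
        raise ValueError(f"no cell has >= {d} transcripts")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows, used, dropped = {}, {}, {}
    for s in samples:
        m = (sample_map == s).to_numpy()
        acc = np.zeros(len(genes), dtype=np.int64)
        n_used = n_drop = 0
        for i in np.flatnonzero(m):
            if totals[i] < d:
                n_drop += 1
                continue
            acc += rng.multivariate_hypergeometric(X[i], d)
            n_used += 1
        rows[s], used[s], dropped[s] = acc, n_used, n_drop
    prof = pd.DataFrame(rows, index=genes).T
    return PseudobulkResult(prof, "equal", d, pd.Series(used), pd.Series(dropped))


def bulk_module_score(
    profiles,
    resistance_module,
    sensitivity_module,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    target_sum: int = 3500,
) -> pd.DataFrame:
    """Score pseudobulk samples with the cell module-score machinery.

    Profiles are depth-normalized and log-transformed exactly like cells
    (samples play the role of cells), then scored with the binned-control
    module score.  Needs at least two samples because expression binning
    requires cross-sample means.
    """
    prof = profiles.profiles if isinstance(profiles, PseudobulkResult) else profiles
    if len(prof) < 2:
        raise ValueError(
            "bulk scoring needs >= 2 samples (binning uses cross-sample means); "
            "supply a reference panel alongside a single sample"
        )
    from . import scoring

    totals = prof.sum(axis=1).to_numpy(dtype=float)
    if np.any(totals <= 0):
        raise ValueError("pseudobulk profile with zero total")
    norm = pd.DataFrame(
        np.log1p(prof.to_numpy(dtype=float) * (target_sum / totals)[:, None]),
        index=prof.index,
        columns=prof.columns,
    )
    bins = scoring.bin_genes_by_expression(norm, n_bins=n_bins)
    rng = np.random.default_rng(seed)
    sens = scoring.module_score(norm, sensitivity_module, bins=bins, n_ctrl=n_ctrl, seed=rng)
    res = scoring.module_score(norm, resistance_module, bins=bins, n_ctrl=n_ctrl, seed=rng)
    return pd.DataFrame({"sensitivity_score": sens, "resistance_score": res})
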