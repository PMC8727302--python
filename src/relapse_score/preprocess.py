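"""QC filtering, gene blacklisting, healthy-cell exclusion, normalization, scaling.

The filter order is fixed: mitochondrial genes are dropped first, then cells
whose remaining total falls below the transcript threshold, then the
blacklist (XIST/TSIX, Y-linked and hemoglobin genes).  Normalization rescales
every cell to the same transcript budget (default 3500) before the log
transform, so proportional cells map to identical rows.  Every step appends
to a provenance list carried in ``.uns["provenance"]``.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._utils import EmptyResultError, as_matrix
from .io_formats import GeneModule

DEFAULT_MIN_TRANSCRIPTS = 500
DEFAULT_TARGET_SUM = 3500


def _record(adata: ad.AnnData, step: str, **info) -> None:
    prov = list(adata.uns.get("provenance", []))
    prov.append({"step": step, **info})
    adata.uns["provenance"] = prov


def _row_totals(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    if sp.issparse(X):
        return np.asarray(X.sum(axis=1)).ravel()
    return np.asarray(X).sum(axis=1)


def qc_filter(
    counts: ad.AnnData, min_transcripts: int = DEFAULT_MIN_TRANSCRIPTS
) -> ad.AnnData:
    """Remove mitochondrial genes, then cells below the transcript threshold.

    The threshold is inclusive: a cell with exactly ``min_transcripts``
    non-mitochondrial transcripts is retained.  Raises
    :class:`EmptyResultError` if no cell survives.
    """
    if "is_mito" not in counts.var.columns:
        raise ValueError("gene annotations must carry an 'is_mito' flag")
    out = counts[:, ~counts.var["is_mito"].to_numpy()].copy()
    n_mito = int(counts.var["is_mito"].sum())
    totals = _row_totals(out)
    keep = totals >= min_transcripts
    if not keep.any():
        raise EmptyResultError(
            f"no cell has >= {min_transcripts} non-mitochondrial transcripts"
        )
    n_removed = int((~keep).sum())
    out = out[keep].copy()
    _record(
        out,
        "qc_filter",
        min_transcripts=min_transcripts,
        mito_genes_removed=n_mito,
        cells_removed=n_removed,
    )
    return out


def remove_blacklist_genes(counts: ad.AnnData) -> ad.AnnData:
    """Drop XIST/TSIX, Y-chromosome and hemoglobin genes; cells untouched."""
    var = counts.var
    mask = np.zeros(counts.n_vars, dtype=bool)
    for col in ("is_hemoglobin", "is_y", "is_xist_tsix"):
        if col in var.columns:
            mask |= var[col].to_numpy(dtype=bool)
    if "chromosome" in var.columns:
        mask |= (var["chromosome"].astype(str) == "Y").to_numpy()
    mask |= counts.var_names.isin(["XIST", "TSIX"])
    out = counts[:, ~mask].copy()
    _record(out, "remove_blacklist_genes", genes_removed=int(mask.sum()))
    return out


def normalize(counts: ad.AnnData, target_sum: int = DEFAULT_TARGET_SUM) -> ad.AnnData:
    """Depth-normalize each cell to ``target_sum`` transcripts and log-transform.

    ``value(c, g) = log(1 + count(c, g) * target_sum / total(c))``, so that
    ``sum_g expm1(value(c, g)) == target_sum`` for every cell.
    """
    totals = _row_totals(counts)
    if np.any(totals <= 0):
        raise ValueError("zero-total cell encountered; run qc_filter first")
    X, _, _ = as_matrix(counts)
    norm = ad.AnnData(
        X=np.log1p(X * (target_sum / totals)[:, None]),
        obs=counts.obs.copy(),
        var=counts.var.copy(),
        uns=dict(counts.uns),
    )
    norm.uns["target_sum"] = target_sum
    _record(norm, "normalize", target_sum=target_sum)
    return norm


def exclude_healthy_cells(
    norm: ad.AnnData,
    marker_module: GeneModule,
    threshold_sd: float = 2.0,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> tuple[ad.AnnData, list[str]]:
    """Remove cells scoring high on a healthy-cell marker module.

    Stand-in for cluster-based removal of contaminating healthy T cells: a
    cell is excluded when its marker-module score exceeds
    ``mean + threshold_sd * SD`` over all cells.  Returns the filtered matrix
    and the excluded cell ids for audit.
    """
    from . import scoring

    score = scoring.module_score(
        norm, marker_module, n_ctrl=n_ctrl, n_bins=n_bins, seed=seed
    )
    cutoff = score.mean() + threshold_sd * score.std(ddof=1)
    excluded = score.index[score > cutoff].tolist()
    if len(excluded) == norm.n_obs:
        raise EmptyResultError("all cells excluded as healthy contaminants")
    out = norm[~norm.obs_names.isin(excluded)].copy()
    _record(
        out,
        "exclude_healthy_cells",
        threshold_sd=threshold_sd,
        cells_excluded=len(excluded),
    )
    return out, excluded


def scale_genes(norm: ad.AnnData) -> ad.AnnData:
    """Z-score each gene (mean 0, sample SD with n-1) across cells.

    Zero-variance genes become all-zero columns and are flagged in
    ``.var["zero_variance"]`` rather than dropped, keeping gene indices
    aligned across stages.  Idempotent up to floating-point error.
    """
    X, _, _ = as_matrix(norm)
    if X.shape[0] < 2:
        raise ValueError("scaling needs at least 2 cells")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero_var = sd == 0
    sd_safe = np.where(zero_var, 1.0, sd)
    out = ad.AnnData(
        X=(X - mu) / sd_safe,
        obs=norm.obs.copy(),
        var=norm.var.copy(),
        uns=dict(norm.uns),
    )
    out.X[:, zero_var] = 0.0
    out.var["zero_variance"] = zero_var
    _record(out, "scale_genes", zero_variance_genes=int(zero_var.sum()))
    return out
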