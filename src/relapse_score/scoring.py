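"""Per-cell gene-module scores and the first-PC continuum score.

The module score follows the binned-control scheme standard in single-cell
signature scoring: every gene is assigned to an expression bin by its mean
expression across cells, each signature gene is compared against the average
of ``n_ctrl`` control genes drawn from its bin, and the gene-minus-control
differences are averaged over the signature.  Control sets are drawn once per
signature gene and shared across cells, which makes the score deterministic
given a seed and invariant under adding a cell-wide constant (the control
average cancels it exactly).

The PC score is the projection of each cell onto the leading principal
component of the gene-scaled expression restricted to the union of the
sensitivity and resistance module genes, oriented so that a high score means
predicted sensitive.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from ._utils import as_matrix
from .io_formats import GeneModule

DEFAULT_N_BINS = 24
DEFAULT_N_CTRL = 100


@dataclasses.dataclass
class ModuleScoreTable:
    """Per-cell sensitivity / resistance / PC scores plus run parameters."""

    table: pd.DataFrame  # columns: sensitivity_score, resistance_score, pc_score
    n_ctrl: int
    n_bins: int
    seed: int
    genes_used: dict[str, int]

    @property
    def sensitivity(self) -> pd.Series:
        return self.table["sensitivity_score"]

    @property
    def resistance(self) -> pd.Series:
        return self.table["resistance_score"]

    @property
    def pc(self) -> pd.Series:
        return self.table["pc_score"]


def bin_genes_by_expression(norm, n_bins: int = DEFAULT_N_BINS) -> pd.Series:
    """Partition genes into ``n_bins`` near-equal-size bins by mean expression.

    Bins are 0-indexed in increasing order of mean expression.  Genes with
    exactly equal means always share a bin (the bin of the first of them in
    the rank order), so the result does not depend on how a sorting algorithm
    breaks ties; if that collapses bins a warning is emitted.
    """
    X, _, genes = as_matrix(norm)
    if X.size == 0:
        raise ValueError("cannot bin genes of an empty matrix")
    means = X.mean(axis=0)
    n = len(genes)
    order = np.argsort(means, kind="stable")
    bins = np.empty(n, dtype=int)
    bins[order] = np.arange(n) * n_bins // n
    # equal means share the bin of the run's first member
    sorted_means = means[order]
    run_start = 0
    for i in range(1, n + 1):
        if i == n or sorted_means[i] != sorted_means[run_start]:
            bins[order[run_start:i]] = bins[order[run_start]]
            run_start = i
    if len(np.unique(bins)) < min(n_bins, n):
        warnings.warn(
            "tied mean expression collapsed some expression bins", stacklevel=2
        )
    return pd.Series(bins, index=genes, name="expression_bin")


def module_score(
    norm,
    module: GeneModule,
    bins: pd.Series | None = None,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int | np.random.Generator = 0,
    n_bins: int = DEFAULT_N_BINS,
) -> pd.Series:
    """Binned-control module score for every cell.

    For each signature gene present in the matrix one control set of
    ``n_ctrl`` genes is drawn from the gene's expression bin, excluding the
    module's own genes (with replacement only when the bin holds fewer than
    ``n_ctrl`` admissible genes).  The score of a cell is the mean over
    signature genes of (gene expression - mean control expression).
    """
    X, cells, genes = as_matrix(norm)
    if bins is None:
        bins = bin_genes_by_expression(norm, n_bins=n_bins)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    gene_pos = pd.Series(np.arange(len(genes)), index=genes)
    present = [g for g in module.genes if g in gene_pos.index]
    if not present:
        missing = list(module.genes)[:10]
        raise ValueError(
            f"module {module.name!r} has no genes in the matrix "
            f"(first missing: {missing})"
        )
    module_set = set(module.genes)

    m = len(present)
    weights = np.zeros(len(genes))
    for g in present:
        gi = gene_pos[g]
        weights[gi] += 1.0 / m
        bin_id = bins[g]
        candidates = bins.index[(bins.values == bin_id) & ~bins.index.isin(module_set)]
        if len(candidates) == 0:
            raise ValueError(
                f"no admissible control genes in expression bin {bin_id} for gene {g!r}"
            )
        replace = len(candidates) < n_ctrl
        ctrl = rng.choice(gene_pos[candidates].to_numpy(), size=n_ctrl, replace=replace)
        np.add.at(weights, ctrl, -1.0 / (m * n_ctrl))
    return pd.Series(X @ weights, index=cells, name=f"{module.name}_score")


def pc_score(
    scaled,
    union_genes,
    orient_by: pd.Series | np.ndarray | None = None,
) -> pd.Series:
    """Project cells on the leading PC of the gene-scaled matrix restricted
    to ``union_genes``; flip the sign so that it correlates positively with
    ``orient_by`` (normally the sensitivity score: high PC = predicted
    sensitive)."""
    X, cells, genes = as_matrix(scaled)
    if X.shape[0] < 2:
        raise ValueError("PC score needs at least 2 cells")
    keep = [g for g in union_genes if g in set(genes)]
    if not keep:
        raise ValueError("none of the requested genes are in the matrix")
    sub = X[:, pd.Index(genes).get_indexer(keep)]
    sub = sub - sub.mean(axis=0, keepdims=True)
    if not np.any(sub):
        raise ValueError("rank-0 submatrix: no variance on the module genes")
    U, S, _ = np.linalg.svd(sub, full_matrices=False)
    scores = U[:, 0] * S[0]
    if orient_by is not None:
        ref = np.asarray(orient_by, dtype=float)
        r = np.corrcoef(scores, ref)[0, 1]
        if np.isfinite(r) and r < 0:
            scores = -scores
    return pd.Series(scores, index=cells, name="pc_score")


def score_cells(
    norm,
    scaled,
    resistance_module: GeneModule,
    sensitivity_module: GeneModule,
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
) -> ModuleScoreTable:
    """Compute sensitivity, resistance and PC scores for every cell.

    Module scores use the normalized (log, depth-normalized) values; the PC
    score uses the gene-scaled values, both restricted to the same cells.
    """
    bins = bin_genes_by_expression(norm, n_bins=n_bins)
    rng = np.random.default_rng(seed)
    sens = module_score(norm, sensitivity_module, bins=bins, n_ctrl=n_ctrl, seed=rng)
    res = module_score(norm, resistance_module, bins=bins, n_ctrl=n_ctrl, seed=rng)
    union = list(dict.fromkeys(sensitivity_module.genes + resistance_module.genes))
    pc = pc_score(scaled, union, orient_by=sens)
    _, _, genes = as_matrix(norm)
    gene_set = set(genes)
    table = pd.DataFrame(
        {
            "sensitivity_score": sens,
            "resistance_score": res,
            "pc_score": pc,
        }
    )
    return ModuleScoreTable(
        table=table,
        n_ctrl=n_ctrl,
        n_bins=n_bins,
        seed=seed if isinstance(seed, int) else -1,
        genes_used={
            sensitivity_module.name: sum(g in gene_set for g in sensitivity_module.genes),
            resistance_module.name: sum(g in gene_set for g in resistance_module.genes),
        },
    )
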