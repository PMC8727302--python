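"""Shared helpers: matrix coercion, seed derivation, empty-result signalling."""

from __future__ import annotations

import numpy as np
import pandas as pd


class EmptyResultError(RuntimeError):
    """Raised when a filter or selection step leaves no cells.

    An explicit signal: callers must decide what an empty cohort means for
    them instead of silently propagating a 0-row matrix.
    """


def as_matrix(data) -> tuple[np.ndarray, pd.Index, pd.Index]:
    """Coerce an AnnData or cells-by-genes DataFrame to (values, cell_ids, gene_ids).

    Values are returned as a dense float64 array; sparse AnnData layers are
    densified (all matrices in this pipeline are small enough for that).
    """
    try:
        import anndata as ad
    except ImportError:  # pragma: no cover
        ad = None
    if ad is not None and isinstance(data, ad.AnnData):
        X = data.X
        if not isinstance(X, np.ndarray):
            X = np.asarray(X.todense())
        return np.asarray(X, dtype=float), data.obs_names, data.var_names
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), data.index, data.columns
    raise TypeError(f"expected AnnData or DataFrame, got {type(data).__name__}")


# Stage tags for seed fan-out.  A single master seed plus a per-stage tag feeds
# a SeedSequence, so each stage can be rerun in isolation and adding a stage
# never perturbs another stage's stream.
STAGE_TAGS = {
    "simulate": 1,
    "simulate_patient": 2,
    "score": 3,
    "exclude": 4,
    "bulkify": 5,
    "selection": 6,
    "de": 7,
}


def stage_rng(master_seed: int, stage: str, *extra: int) -> np.random.Generator:
    """Derive an independent Generator for a named pipeline stage."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), STAGE_TAGS[stage], *map(int, extra)])
    )
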