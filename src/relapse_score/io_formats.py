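"""On-disk formats: sparse count matrices, gene-module tables, result tables.

Counts live on disk as Matrix Market coordinate integer files with genes as
rows (the 10x convention), accompanied by header-less ``genes.tsv`` and
``barcodes.tsv`` annotation files.  In memory the orientation is always
cells x genes (an :class:`anndata.AnnData`); the transpose happens here, at
the I/O boundary, and nowhere else.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

GENE_FLAG_COLUMNS = [
    "is_mito",
    "is_hemoglobin",
    "is_y",
    "is_xist_tsix",
    "is_tcell_marker",
]

#: genes.tsv column order (no header, 10x style)
_GENE_COLUMNS = ["gene", "chromosome", *GENE_FLAG_COLUMNS]
#: barcodes.tsv column order (no header)
_CELL_COLUMNS = ["cell", "patient", "source"]


@dataclasses.dataclass(frozen=True)
class GeneModule:
    """A named, directed gene set.

    ``direction`` is ``"up"`` for the resistance program (genes apparently
    upregulated after in vivo glucocorticoid treatment, i.e. markers of
    surviving cells) and ``"down"`` for the sensitivity program (markers of
    cells preferentially eliminated by treatment).
    """

    name: str
    direction: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if len(self.genes) == 0:
            raise ValueError(f"module {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"module {self.name!r} contains duplicate genes")
        object.__setattr__(self, "genes", tuple(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


def _validate_counts(adata: ad.AnnData) -> None:
    if adata.obs_names.duplicated().any():
        raise ValueError("duplicate cell ids")
    if adata.var_names.duplicated().any():
        raise ValueError("duplicate gene ids")
    X = adata.X
    data = X.data if sp.issparse(X) else np.asarray(X)
    if data.size and data.min() < 0:
        raise ValueError("count matrix contains negative entries")
    if data.size and np.any(data != np.floor(data)):
        raise ValueError("count matrix contains non-integer entries")


def write_counts(adata: ad.AnnData, path: str | Path) -> Path:
    """Write a cells x genes count matrix as MTX + genes.tsv + barcodes.tsv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _validate_counts(adata)
    X = adata.X
    if not sp.issparse(X):
        X = sp.coo_matrix(np.asarray(X))
    # genes-as-rows on disk
    scipy.io.mmwrite(str(path / "matrix.mtx"), X.T.astype(np.int64), field="integer")
    genes = pd.DataFrame({"gene": adata.var_names})
    genes["chromosome"] = adata.var.get("chromosome", pd.Series("NA", index=adata.var_names)).values
    for col in GENE_FLAG_COLUMNS:
        flags = adata.var.get(col, pd.Series(False, index=adata.var_names))
        genes[col] = flags.astype(int).values
    genes.to_csv(path / "genes.tsv", sep="\t", header=False, index=False)
    cells = pd.DataFrame({"cell": adata.obs_names})
    cells["patient"] = adata.obs.get("patient", pd.Series("NA", index=adata.obs_names)).values
    cells["source"] = adata.obs.get("source", pd.Series("NA", index=adata.obs_names)).values
    cells.to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
    return path


def read_counts(path: str | Path, fmt: str = "mtx") -> ad.AnnData:
    """Read a count matrix written by :func:`write_counts` (or a dense TSV).

    Raises on dimension mismatches between the matrix and its annotation
    files, naming the offending file.
    """
    path = Path(path)
    if fmt == "mtx":
        M = scipy.io.mmread(str(path / "matrix.mtx"))  # genes x cells
        X = sp.csr_matrix(M.T)
        n_cells, n_genes = X.shape
    elif fmt == "tsv":
        df = pd.read_csv(path / "counts.tsv", sep="\t", index_col=0)
        X = df.to_numpy()
        n_cells, n_genes = X.shape
    else:
        raise ValueError(f"unknown format {fmt!r}")

    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None, names=_GENE_COLUMNS)
    cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None, names=_CELL_COLUMNS)
    if len(genes) != n_genes:
        raise ValueError(
            f"genes.tsv has {len(genes)} rows but matrix has {n_genes} genes"
        )
    if len(cells) != n_cells:
        raise ValueError(
            f"barcodes.tsv has {len(cells)} rows but matrix has {n_cells} cells"
        )
    var = genes.set_index("gene")
    var.index = var.index.astype(str)
    for col in GENE_FLAG_COLUMNS:
        var[col] = var[col].astype(bool)
    obs = cells.set_index("cell")
    obs.index = obs.index.astype(str)
    adata = ad.AnnData(X=X, obs=obs, var=var)
    if fmt == "tsv":
        # trust the TSV's own labels, cross-checked against the sidecars
        adata.obs_names = df.index.astype(str)
        adata.var_names = df.columns.astype(str)
    _validate_counts(adata)
    return adata


def read_modules(path: str | Path) -> tuple[GeneModule, GeneModule]:
    """Read a gene-module CSV (columns ``gene,direction``).

    Returns ``(resistance_up, sensitivity_down)``.  Direction tokens
    ``up``/``resistance`` and ``down``/``sensitivity`` are accepted.
    """
    table = pd.read_csv(path)
    if table.empty:
        raise ValueError(f"module table {path} is empty")
    if not {"gene", "direction"}.issubset(table.columns):
        raise ValueError("module table must have columns 'gene' and 'direction'")
    alias = {"up": "up", "resistance": "up", "down": "down", "sensitivity": "down"}
    unknown = set(table["direction"].astype(str).str.lower()) - set(alias)
    if unknown:
        raise ValueError(f"unknown direction token(s): {sorted(unknown)}")
    table["direction"] = table["direction"].astype(str).str.lower().map(alias)
    groups: dict[str, list[str]] = {"up": [], "down": []}
    for _, row in table.iterrows():
        groups[row["direction"]].append(str(row["gene"]))
    for direction, genes in groups.items():
        if len(set(genes)) != len(genes):
            raise ValueError(f"duplicate gene within direction {direction!r}")
        if not genes:
            raise ValueError(f"no genes with direction {direction!r}")
    overlap = set(groups["up"]) & set(groups["down"])
    if overlap:
        raise ValueError(f"gene(s) listed under both directions: {sorted(overlap)}")
    return (
        GeneModule("resistance", "up", tuple(groups["up"])),
        GeneModule("sensitivity", "down", tuple(groups["down"])),
    )


def write_modules(modules, path: str | Path) -> Path:
    """Write one or more GeneModules as a ``gene,direction`` CSV."""
    rows = [(g, m.direction) for m in modules for g in m.genes]
    pd.DataFrame(rows, columns=["gene", "direction"]).to_csv(path, index=False)
    return Path(path)


def write_results(per_cell: pd.DataFrame, per_patient: pd.DataFrame, path: str | Path) -> Path:
    """Write per-cell and per-patient result tables as CSV (full precision)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    per_cell.to_csv(path / "cells.csv", index=True)
    per_patient.to_csv(path / "patients.csv", index=True)
    return path


def read_results(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    path = Path(path)
    per_cell = pd.read_csv(path / "cells.csv", index_col=0)
    per_patient = pd.read_csv(path / "patients.csv", index_col=0)
    return per_cell, per_patient
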