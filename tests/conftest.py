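import anndata as ad
import numpy as np
import pandas as pd
import pytest

import relapse_score as rs


def make_counts(X, cell_ids=None, gene_ids=None, patients=None, **var_flags):
    """Build a small AnnData count matrix with the standard annotation columns."""
    X = np.asarray(X, dtype=np.int64)
    n_cells, n_genes = X.shape
    cell_ids = cell_ids or [f"c{i}" for i in range(n_cells)]
    gene_ids = gene_ids or [f"g{j}" for j in range(n_genes)]
    obs = pd.DataFrame(index=pd.Index(cell_ids, name="cell"))
    obs["patient"] = patients if patients is not None else "P01"
    obs["source"] = "BM"
    var = pd.DataFrame(index=pd.Index(gene_ids, name="gene"))
    var["chromosome"] = "1"
    for col in rs.io_formats.GENE_FLAG_COLUMNS:
        flags = var_flags.get(col, np.zeros(n_genes, dtype=bool))
        var[col] = np.asarray(flags, dtype=bool)
    return ad.AnnData(X=X, obs=obs, var=var)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 4-patient cohort for unit-level checks."""
    cfg = rs.SimConfig(
        n_patients=4,
        cells_per_patient=120,
        n_genes=600,
        n_sens_genes=120,
        n_res_genes=40,
        seed=11,
    )
    counts, truth, meta, modules = rs.generate_cohort(cfg)
    return cfg, counts, truth, meta, modules


@pytest.fixture(scope="session")
def default_cohort_results():
    """The reference 15-patient cohort pushed through the full analysis."""
    cfg = rs.SimConfig(seed=0)
    counts, truth, meta, (res_mod, sens_mod) = rs.generate_cohort(cfg)
    qc = rs.qc_filter(counts)
    qc = rs.remove_blacklist_genes(qc)
    norm = rs.normalize(qc)
    norm, excluded = rs.exclude_healthy_cells(norm, rs.tcell_marker_module(qc), seed=0)
    scaled = rs.scale_genes(norm)
    scores = rs.score_cells(norm, scaled, res_mod, sens_mod, seed=0)
    summary = rs.summarize_patients(scores, norm.obs["patient"], outcomes=meta["outcome"])
    return {
        "config": cfg,
        "counts": counts,
        "truth": truth,
        "meta": meta,
        "modules": (res_mod, sens_mod),
        "norm": norm,
        "excluded": excluded,
        "scores": scores,
        "summary": summary,
    }
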