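"""Replicate experiments on synthetic cohorts.

These functions reproduce, at simulation scale, the study-level analyses that
go beyond a single pipeline run: in-silico drug-selection enrichment of
resistant-classified cells, and the depth-bias comparison of complete versus
equal-contribution pseudobulk pooling.  Both are used by the test suite and
the acceptance script and are part of the public API.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from . import bulk_and_de, classification, preprocess, scoring, synthgen
from ._utils import stage_rng


def _preprocess_and_score(counts, res_mod, sens_mod, seed: int):
    qc = preprocess.qc_filter(counts)
    qc = preprocess.remove_blacklist_genes(qc)
    norm = preprocess.normalize(qc)
    scaled = preprocess.scale_genes(norm)
    return qc, norm, scoring.score_cells(norm, scaled, res_mod, sens_mod, seed=seed)


def selection_enrichment_experiment(
    seed: int,
    n_cells: int = 1200,
    n_genes: int = 800,
    kill_curve=None,
) -> tuple[float, float]:
    """In-vitro-style selection on one synthetic diagnosis sample.

    The sample's cells are split in half into a control and a treated
    culture; the treated half goes through in-silico drug selection with
    ``kill_curve`` (default: survival probability equal to the latent
    resistance level).  Both cultures are then pooled into one dataset,
    scored, and categorized against the shared medians, mirroring how a
    control/treated pair is analyzed as one complete dataset.

    Returns ``(frac_resistant_control, frac_resistant_treated)``.
    """
    if kill_curve is None:
        kill_curve = lambda latent: latent  # noqa: E731
    cfg = synthgen.SimConfig(
        n_patients=1,
        cells_per_patient=n_cells,
        n_genes=n_genes,
        target_resistant_fractions=[0.25],
        contaminant_fraction=0.0,
        seed=seed,
    )
    counts, truth, _, (res_mod, sens_mod) = synthgen.generate_cohort(cfg)
    rng = stage_rng(seed, "selection")
    treated_mask = np.zeros(counts.n_obs, dtype=bool)
    treated_mask[rng.choice(counts.n_obs, size=counts.n_obs // 2, replace=False)] = True

    control = counts[~treated_mask].copy()
    treated, _ = synthgen.apply_selection(
        counts[treated_mask].copy(), truth.loc[counts.obs_names[treated_mask]],
        kill_curve, seed=rng,
    )
    control.obs["culture"] = "control"
    treated.obs["culture"] = "treated"
    import anndata as ad

    merged = ad.concat([control, treated], merge="same")
    merged.var = counts.var.copy()  # concat drops var annotations
    _, _, scores = _preprocess_and_score(merged, res_mod, sens_mod, seed)
    categories, _ = classification.categorize_cells(scores)
    culture = merged.obs["culture"].reindex(categories.index)
    fracs = classification.patient_fractions(categories, culture)
    return (
        float(fracs.loc["control", "frac_resistant"]),
        float(fracs.loc["treated", "frac_resistant"]),
    )


def _standardized_difference(values: pd.Series, groups: pd.Series) -> float:
    """|mean difference| / pooled SD between two outcome groups."""
    g1 = values[groups == "relapse"]
    g2 = values[groups == "no-relapse"]
    n1, n2 = len(g1), len(g2)
    pooled = np.sqrt(
        ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (n1 + n2 - 2)
    )
    if pooled == 0:
        return 0.0
    return float(abs(g1.mean() - g2.mean()) / pooled)


def pseudobulk_depth_experiment(
    seed: int,
    n_patients: int = 12,
    cells_per_patient: int = 120,
    n_genes: int = 800,
    program_patient_sd: float = 0.25,
    depth_mean_resistant: float = 800.0,
) -> tuple[float, float]:
    """Compare pooling modes on a cohort where resistant cells are shallower.

    The experiment is run in the regime the depth-bias phenomenon concerns:
    a pronounced library-size asymmetry (quiescent resistant cells carrying a
    small fraction of a sensitive cell's transcripts) and strong patient-level
    heterogeneity of the gene programs, as real bulk cohorts show.  Note that
    a pure monotone compression of the resistant transcript share cannot by
    itself reduce a *standardized* group difference; the compression hurts
    only relative to patient-level noise that does not scale with the signal,
    which is why ``program_patient_sd`` matters here.

    Each patient's cells are pooled into pseudobulk profiles by complete and
    by equal-contribution downsampled pooling, profiles are scored with the
    resistance module, and each mode's separation of planted relapse versus
    non-relapse patients is measured as the standardized mean difference
    (SMD) of the bulk resistance score.

    Returns ``(smd_equal, smd_complete)``; the depth bias predicts
    ``smd_equal > smd_complete``.
    """
    cfg = synthgen.SimConfig(
        n_patients=n_patients,
        cells_per_patient=cells_per_patient,
        n_genes=n_genes,
        program_patient_sd=program_patient_sd,
        depth_mean_resistant=depth_mean_resistant,
        contaminant_fraction=0.0,
        seed=seed,
    )
    counts, _, meta, (res_mod, sens_mod) = synthgen.generate_cohort(cfg)
    qc = preprocess.qc_filter(counts)
    qc = preprocess.remove_blacklist_genes(qc)
    patients = qc.obs["patient"]
    rng = stage_rng(seed, "bulkify")

    smd = {}
    for mode in ("equal", "complete"):
        pooled = bulk_and_de.pool_bulk(qc, patients, mode=mode, seed=rng)
        bulk = bulk_and_de.bulk_module_score(pooled, res_mod, sens_mod, seed=seed)
        smd[mode] = _standardized_difference(
            bulk["resistance_score"], meta["outcome"].reindex(bulk.index)
        )
    return smd["equal"], smd["complete"]


def technology_concordance_experiment(seed: int, n_patients: int = 10) -> float:
    """Risk-call agreement between a deep/few-cell and a shallow/many-cell draw.

    Emulates profiling the same patients with a plate-based platform (few
    cells, deep) and a droplet platform (many cells, shallow): two cohorts
    share the latent patient composition (same per-patient Beta parameters
    and seed-derived targets) but differ in depth regime and cell counts.
    Returns the fraction of patients with concordant risk calls.
    """
    targets = list(np.linspace(0.05, 0.60, n_patients))
    base = dict(
        n_patients=n_patients,
        n_genes=800,
        target_resistant_fractions=targets,
        contaminant_fraction=0.0,
    )
    calls = {}
    for name, depth_s, depth_r, n_cells in (
        ("sortseq", 8000.0, 3000.0, 150),
        ("tenx", 3000.0, 1100.0, 500),
    ):
        cfg = synthgen.SimConfig(
            cells_per_patient=n_cells,
            depth_mean_sensitive=depth_s,
            depth_mean_resistant=depth_r,
            seed=seed,
            **base,
        )
        counts, _, _, (res_mod, sens_mod) = synthgen.generate_cohort(cfg)
        _, norm, scores = _preprocess_and_score(counts, res_mod, sens_mod, seed)
        summary = classification.summarize_patients(scores, norm.obs["patient"])
        calls[name] = summary["risk_call"]
    agree = (calls["sortseq"] == calls["tenx"]).mean()
    return float(agree)
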