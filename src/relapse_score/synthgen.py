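"""Synthetic scRNA-seq cohorts with the statistical structure the analysis assumes.

The generator plants, per cell, a latent resistance level in [0, 1] drawn
from a patient-specific Beta distribution, and couples three observable
consequences to it:

* a resistance gene program whose expression rises with the latent level and
  a sensitivity program that falls with it (multiplicative, log-scale, with
  gene-specific loadings), producing the anti-correlated module structure;
* a lower expected library size for resistant cells (expected depth
  interpolates linearly between the sensitive and resistant depth means);
* a patient-level outcome: a patient relapses when the planted fraction of
  resistant cells (latent level > 0.5) exceeds a threshold.

Counts are negative binomial via a gamma-Poisson mixture — the standard
overdispersed scRNA-seq noise model; dropout arises naturally from low means.
Per-patient identity comes from log-normal mean offsets on a random gene
subset, which reproduces the patient-wise clustering typical of leukemia
cohorts.  Optional healthy T-like contaminant cells carry their own marker
program and no malignant program, so the marker-score exclusion filter is
exercised.  All randomness derives from one master seed through per-patient
substreams, so adding patients never perturbs existing ones.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special

from ._utils import EmptyResultError, stage_rng
from .io_formats import GeneModule

# stand-in special gene groups (flagged in the gene annotation)
N_MITO = 20
N_HEMOGLOBIN = 8
N_Y = 10
RESISTANT_LATENT_CUTOFF = 0.5  # a cell counts as planted-resistant above this


@dataclasses.dataclass
class SimConfig:
    """Full parameterization of the synthetic cohort generator.

    Defaults describe the reference cohort: 15 patients of 300 cells whose
    planted resistant fractions are evenly spread over [0.05, 0.60], so that
    the relapse threshold of 0.30 splits the cohort into 8 relapsing and 7
    relapse-free patients.
    """

    n_patients: int = 15
    cells_per_patient: int | tuple[int, int] = 300
    n_genes: int = 2000
    n_sens_genes: int = 370
    n_res_genes: int = 78
    patient_effect_sd: float = 0.3
    patient_effect_gene_frac: float = 0.2
    #: SD of the per-patient coherent log-offset applied to each gene program
    #: as a whole (patients shift entire module-score distributions, not just
    #: individual genes)
    program_patient_sd: float = 0.10
    #: per-patient (a, b) Beta parameters of the latent resistance level;
    #: None derives them from target_resistant_fractions
    resistance_beta_params: Sequence[tuple[float, float]] | None = None
    #: target per-patient P(latent > 0.5); None -> linspace(0.05, 0.60)
    target_resistant_fractions: Sequence[float] | None = None
    resistance_concentration: float = 4.0
    program_effect: float = 2.0
    depth_mean_sensitive: float = 4000.0
    depth_mean_resistant: float = 1500.0
    nb_dispersion: float = 2.0
    contaminant_fraction: float = 0.05
    n_tcell_marker_genes: int = 30
    tcell_marker_boost: float = 8.0
    relapse_rule_threshold: float = 0.30
    outcome_label_noise: float = 0.0
    sample_source: str = "BM"
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1 or self.n_genes < 1:
            raise ValueError("n_patients and n_genes must be >= 1")
        lo, hi = self._cell_range()
        if lo < 1 or hi < lo:
            raise ValueError("cells_per_patient must be >= 1 (or a valid range)")
        if self.n_sens_genes < 1 or self.n_res_genes < 1:
            raise ValueError("program sizes must be >= 1")
        n_special = N_MITO + N_HEMOGLOBIN + N_Y + 2 + self.n_tcell_marker_genes
        if self.n_sens_genes + self.n_res_genes + n_special > self.n_genes:
            raise ValueError(
                f"programs + special genes ({self.n_sens_genes + self.n_res_genes + n_special}) "
                f"exceed n_genes ({self.n_genes})"
            )
        if self.depth_mean_sensitive <= 0 or self.depth_mean_resistant <= 0:
            raise ValueError("depth means must be positive")
        if not 0 <= self.contaminant_fraction < 1:
            raise ValueError("contaminant_fraction must be in [0, 1)")
        if self.nb_dispersion <= 0 or self.resistance_concentration <= 0:
            raise ValueError("dispersion parameters must be positive")
        if self.resistance_beta_params is not None:
            for a, b in self.resistance_beta_params:
                if a <= 0 or b <= 0:
                    raise ValueError("Beta parameters must be positive")
            if len(self.resistance_beta_params) != self.n_patients:
                raise ValueError("need one (a, b) pair per patient")

    def _cell_range(self) -> tuple[int, int]:
        if isinstance(self.cells_per_patient, int):
            return self.cells_per_patient, self.cells_per_patient
        lo, hi = self.cells_per_patient
        return int(lo), int(hi)

    def beta_params(self) -> list[tuple[float, float]]:
        if self.resistance_beta_params is not None:
            return [tuple(p) for p in self.resistance_beta_params]
        targets = self.target_resistant_fractions
        if targets is None:
            targets = np.linspace(0.05, 0.60, self.n_patients)
        k = self.resistance_concentration
        return [beta_params_for_resistant_fraction(f, k) for f in targets]


def beta_params_for_resistant_fraction(
    fraction: float, concentration: float
) -> tuple[float, float]:
    """Beta(a, b) with a + b = concentration and P(X > 0.5) = fraction.

    Inverts the regularized incomplete beta function numerically so that the
    planted resistant fraction of a patient matches its target in
    expectation.
    """
    if not 0 < fraction < 1:
        raise ValueError("target fraction must be in (0, 1)")
    k = concentration

    def tail(mu: float) -> float:
        return 1.0 - scipy.special.betainc(k * mu, k * (1 - mu), 0.5) - fraction

    mu = scipy.optimize.brentq(tail, 1e-6, 1 - 1e-6)
    return (k * mu, k * (1 - mu))


def _gene_annotation(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay out gene names, chromosome labels, flags and program membership."""
    names: list[str] = []
    chrom: list[str] = []
    names += [f"MT-G{i}" for i in range(1, N_MITO + 1)]
    chrom += ["MT"] * N_MITO
    names += [f"HBG{i}" for i in range(1, N_HEMOGLOBIN + 1)]
    chrom += ["16"] * N_HEMOGLOBIN
    names += [f"YG{i}" for i in range(1, N_Y + 1)]
    chrom += ["Y"] * N_Y
    names += ["XIST", "TSIX"]
    chrom += ["X", "X"]
    names += [f"TMARK{i}" for i in range(1, cfg.n_tcell_marker_genes + 1)]
    chrom += ["14"] * cfg.n_tcell_marker_genes
    names += [f"SENS{i}" for i in range(1, cfg.n_sens_genes + 1)]
    chrom += ["1"] * cfg.n_sens_genes
    names += [f"RES{i}" for i in range(1, cfg.n_res_genes + 1)]
    chrom += ["2"] * cfg.n_res_genes
    n_bg = cfg.n_genes - len(names)
    names += [f"G{i}" for i in range(1, n_bg + 1)]
    chrom += ["3"] * n_bg
    var = pd.DataFrame(index=pd.Index(names, name="gene"))
    var["chromosome"] = chrom
    var["is_mito"] = var.index.str.startswith("MT-")
    var["is_hemoglobin"] = var.index.str.startswith("HBG")
    var["is_y"] = np.asarray(chrom) == "Y"
    var["is_xist_tsix"] = var.index.isin(["XIST", "TSIX"])
    var["is_tcell_marker"] = var.index.str.startswith("TMARK")
    var["is_sens_program"] = var.index.str.startswith("SENS")
    var["is_res_program"] = var.index.str.startswith("RES")
    return var


def generate_cohort(
    config: SimConfig,
) -> tuple[ad.AnnData, pd.DataFrame, pd.DataFrame, tuple[GeneModule, GeneModule]]:
    """Generate a full synthetic cohort.

    Returns ``(counts, truth, patient_meta, (resistance_module,
    sensitivity_module))``.  ``counts`` is a cells x genes AnnData of UMI
    counts with flagged gene annotation; ``truth`` carries the per-cell
    latent resistance, contaminant flag and expected library size;
    ``patient_meta`` carries source, outcome label and the planted resistant
    fraction.  Bit-identical for identical config (the master seed lives in
    the config).
    """
    cfg = config
    gene_rng = stage_rng(cfg.seed, "simulate")
    var = _gene_annotation(cfg, gene_rng)
    n_genes = cfg.n_genes

    # baseline relative expression (log-normal spread across genes)
    base_log = gene_rng.normal(0.0, 1.25, size=n_genes)
    base = np.exp(base_log)
    # gene-specific program loadings
    loadings = gene_rng.uniform(0.5, 1.5, size=n_genes)
    sens_mask = var["is_sens_program"].to_numpy()
    res_mask = var["is_res_program"].to_numpy()
    tmark_mask = var["is_tcell_marker"].to_numpy()

    beta_params = cfg.beta_params()
    lo, hi = cfg._cell_range()

    blocks: list[np.ndarray] = []
    obs_rows: list[dict] = []
    truth_rows: list[dict] = []
    meta_rows: list[dict] = []

    for p in range(cfg.n_patients):
        prng = stage_rng(cfg.seed, "simulate_patient", p)
        pid = f"P{p + 1:02d}"
        n_cells = int(prng.integers(lo, hi + 1)) if lo != hi else lo
        a, b = beta_params[p]
        latent = prng.beta(a, b, size=n_cells)
        contam = prng.random(n_cells) < cfg.contaminant_fraction
        latent[contam] = np.nan

        # patient identity: log-normal offsets on a random gene subset
        n_affected = int(round(cfg.patient_effect_gene_frac * n_genes))
        affected = prng.choice(n_genes, size=n_affected, replace=False)
        offset = np.zeros(n_genes)
        offset[affected] = prng.normal(0.0, cfg.patient_effect_sd, size=n_affected)
        patient_base = base * np.exp(offset)
        # coherent per-patient shift of each whole program: patients differ in
        # where their module-score distributions sit, not only gene by gene
        d_res, d_sens = prng.normal(0.0, cfg.program_patient_sd, size=2)
        patient_base = patient_base.copy()
        patient_base[res_mask] *= np.exp(d_res)
        patient_base[sens_mask] *= np.exp(d_sens)

        # per-cell gene means (cells x genes), programs modulated by latent level
        z = np.where(contam, 0.0, np.nan_to_num(latent) - 0.5)[:, None]
        log_mod = np.zeros((n_cells, n_genes))
        log_mod[:, sens_mask] = -cfg.program_effect * z * loadings[None, sens_mask]
        log_mod[:, res_mask] = cfg.program_effect * z * loadings[None, res_mask]
        # contaminant rows have z = 0, so their programs stay at baseline
        mean = patient_base[None, :] * np.exp(log_mod)
        if contam.any():
            mean[np.ix_(contam, tmark_mask)] *= cfg.tcell_marker_boost
        mean /= mean.sum(axis=1, keepdims=True)

        depth = cfg.depth_mean_sensitive + np.nan_to_num(latent) * (
            cfg.depth_mean_resistant - cfg.depth_mean_sensitive
        )
        depth[contam] = cfg.depth_mean_sensitive

        rate = mean * depth[:, None]
        gamma = prng.gamma(cfg.nb_dispersion, 1.0 / cfg.nb_dispersion, size=rate.shape)
        counts = prng.poisson(rate * gamma)
        blocks.append(counts)

        for i in range(n_cells):
            cid = f"{pid}_C{i:04d}"
            obs_rows.append({"cell": cid, "patient": pid, "source": cfg.sample_source})
            truth_rows.append(
                {
                    "cell": cid,
                    "patient": pid,
                    "latent_resistance": latent[i],
                    "is_contaminant": bool(contam[i]),
                    "true_library_size": int(round(depth[i])),
                }
            )

        blast_latent = latent[~contam]
        planted = float((blast_latent > RESISTANT_LATENT_CUTOFF).mean())
        relapse = planted > cfg.relapse_rule_threshold
        if cfg.outcome_label_noise > 0 and prng.random() < cfg.outcome_label_noise:
            relapse = not relapse
        meta_rows.append(
            {
                "patient": pid,
                "source": cfg.sample_source,
                "outcome": "relapse" if relapse else "no-relapse",
                "planted_resistant_fraction": planted,
                "n_cells": n_cells,
            }
        )

    X = np.concatenate(blocks, axis=0)
    obs = pd.DataFrame(obs_rows).set_index("cell")
    counts = ad.AnnData(X=X, obs=obs, var=var.copy())
    truth = pd.DataFrame(truth_rows).set_index("cell")
    meta = pd.DataFrame(meta_rows).set_index("patient")

    res_module = GeneModule("resistance", "up", tuple(var.index[res_mask]))
    sens_module = GeneModule("sensitivity", "down", tuple(var.index[sens_mask]))
    return counts, truth, meta, (res_module, sens_module)


def tcell_marker_module(counts: ad.AnnData) -> GeneModule:
    """The healthy T-like marker module of a generated cohort."""
    genes = tuple(counts.var_names[counts.var["is_tcell_marker"].to_numpy()])
    return GeneModule("tcell_markers", "up", genes)


def generate_module_table(
    n_up: int = 78,
    n_down: int = 370,
    gene_universe: Sequence[str] | None = None,
    up_genes: Sequence[str] | None = None,
    down_genes: Sequence[str] | None = None,
    seed: int | None = None,
) -> tuple[GeneModule, GeneModule, pd.DataFrame]:
    """Build a resistance/sensitivity module pair and its CSV-serializable table.

    By default 78 up (resistance) and 370 down (sensitivity) genes — the size
    of the published glucocorticoid-response signature — are taken from
    ``gene_universe`` (randomly when ``seed`` is given, else the first
    ``n_up + n_down``).  Pass ``up_genes``/``down_genes`` explicitly to match
    a simulator's program genes.
    """
    if up_genes is None or down_genes is None:
        if gene_universe is None:
            raise ValueError("need a gene_universe when genes are not given explicitly")
        universe = list(dict.fromkeys(map(str, gene_universe)))
        if len(universe) < n_up + n_down:
            raise ValueError(
                f"gene universe of {len(universe)} cannot supply {n_up + n_down} disjoint genes"
            )
        if seed is not None:
            rng = np.random.default_rng(seed)
            picked = list(rng.choice(universe, size=n_up + n_down, replace=False))
        else:
            picked = universe[: n_up + n_down]
        up_genes, down_genes = picked[:n_up], picked[n_up:]
    if set(up_genes) & set(down_genes):
        raise ValueError("up and down modules overlap")
    res = GeneModule("resistance", "up", tuple(up_genes))
    sens = GeneModule("sensitivity", "down", tuple(down_genes))
    table = pd.DataFrame(
        [(g, "up") for g in res.genes] + [(g, "down") for g in sens.genes],
        columns=["gene", "direction"],
    )
    return res, sens, table


def apply_selection(
    counts: ad.AnnData,
    truth: pd.DataFrame,
    kill_curve: Callable[[np.ndarray], np.ndarray],
    seed: int | np.random.Generator = 0,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """In-silico drug exposure: retain each cell with probability
    ``kill_curve(latent_resistance)``.

    Emulates in vitro glucocorticoid treatment, which preferentially removes
    sensitive cells.  Contaminant cells (no latent level) are treated as
    fully sensitive (latent 0).  Raises :class:`EmptyResultError` when
    nothing survives.
    """
    truth = truth.loc[counts.obs_names]
    latent = truth["latent_resistance"].to_numpy(dtype=float)
    latent = np.where(np.isnan(latent), 0.0, latent)
    surv = np.asarray(kill_curve(latent), dtype=float)
    if surv.shape != latent.shape:
        raise ValueError("kill_curve must map the latent vector elementwise")
    if np.any(surv < 0) or np.any(surv > 1):
        raise ValueError("kill_curve must map [0, 1] into [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = rng.random(len(surv)) < surv
    if not keep.any():
        raise EmptyResultError("no cell survived the selection")
    return counts[keep].copy(), truth.loc[keep]
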