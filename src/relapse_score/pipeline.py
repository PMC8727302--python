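"""End-to-end orchestration: simulate -> preprocess -> score -> classify -> DE/bulkify.

One :class:`RunConfig` (loadable from YAML) plus a master seed fully
determine every output.  Each stage writes its artifacts to the output
directory, and a manifest records parameters, seeds and the cell/gene counts
surviving each filter, so any stage can be rerun in isolation from the
serialized artifacts of the previous one.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import bulk_and_de, classification, io_formats, preprocess, scoring, synthgen

log = logging.getLogger("relapse_score")


@dataclasses.dataclass
class RunConfig:
    """Parameters of a full pipeline run (all stage defaults repeated here)."""

    seed: int = 0
    simulate: bool = True
    counts_path: str | None = None  # used when simulate=False
    modules_path: str | None = None
    sim: dict = dataclasses.field(default_factory=dict)  # SimConfig overrides
    min_transcripts: int = 500
    target_sum: int = 3500
    exclude_healthy: bool = True
    healthy_threshold_sd: float = 2.0
    n_bins: int = 24
    n_ctrl: int = 100
    risk_rule: str = "resistant-majority"
    run_de: bool = True
    de_min_pct: float = 0.1
    run_bulkify: bool = True
    bulk_mode: str = "equal"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline; returns the manifest dictionary.

    Writes counts, module table, per-cell and per-patient tables, DE table,
    pseudobulk scores, the verbatim config, a manifest and a human-readable
    report into ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    manifest: dict = {"seed": config.seed, "stages": []}

    def stage(name, **info):
        log.info("stage %s: %s", name, info)
        manifest["stages"].append({"stage": name, **info})

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        sim_cfg = synthgen.SimConfig(seed=config.seed, **config.sim)
        counts, truth, meta, (res_mod, sens_mod) = synthgen.generate_cohort(sim_cfg)
        io_formats.write_counts(counts, outdir / "counts")
        truth.to_csv(outdir / "truth.csv")
        meta.to_csv(outdir / "patients_meta.csv")
        io_formats.write_modules([res_mod, sens_mod], outdir / "modules.csv")
        stage("simulate", n_cells=counts.n_obs, n_genes=counts.n_vars,
              n_patients=sim_cfg.n_patients)
    else:
        if not config.counts_path or not Path(config.counts_path).exists():
            raise FileNotFoundError(
                f"simulation disabled and counts path missing: {config.counts_path!r}"
            )
        counts = io_formats.read_counts(config.counts_path)
        res_mod, sens_mod = io_formats.read_modules(config.modules_path)
        meta_path = Path(config.counts_path).parent / "patients_meta.csv"
        meta = pd.read_csv(meta_path, index_col=0) if meta_path.exists() else None
        stage("load", n_cells=counts.n_obs, n_genes=counts.n_vars)

    # --- preprocess -------------------------------------------------------
    qc = preprocess.qc_filter(counts, min_transcripts=config.min_transcripts)
    stage("qc_filter", n_cells=qc.n_obs, n_genes=qc.n_vars)
    qc = preprocess.remove_blacklist_genes(qc)
    stage("remove_blacklist_genes", n_genes=qc.n_vars)
    norm = preprocess.normalize(qc, target_sum=config.target_sum)
    if config.exclude_healthy and qc.var["is_tcell_marker"].any():
        marker = synthgen.tcell_marker_module(qc)
        norm, excluded = preprocess.exclude_healthy_cells(
            norm, marker, threshold_sd=config.healthy_threshold_sd, seed=config.seed
        )
        stage("exclude_healthy_cells", n_excluded=len(excluded), n_cells=norm.n_obs)
    scaled = preprocess.scale_genes(norm)

    # --- score ------------------------------------------------------------
    scores = scoring.score_cells(
        norm, scaled, res_mod, sens_mod,
        n_bins=config.n_bins, n_ctrl=config.n_ctrl, seed=config.seed,
    )
    stage("score", n_cells=len(scores.table), genes_used=scores.genes_used)

    # --- classify ---------------------------------------------------------
    patients = norm.obs["patient"]
    outcomes = meta["outcome"] if meta is not None and "outcome" in meta else None
    summary = classification.summarize_patients(
        scores, patients, outcomes=outcomes, rule=config.risk_rule
    )
    categories, medians = classification.categorize_cells(scores)
    per_cell = scores.table.copy()
    per_cell["category"] = categories
    per_cell["patient"] = patients
    io_formats.write_results(per_cell, summary, outdir)
    evaluation = None
    if outcomes is not None:
        evaluation = classification.evaluate_predictions(summary["risk_call"], outcomes)
        stage("classify", medians=list(medians),
              accuracy=f"{evaluation.n_correct}/{evaluation.n_total}")
    else:
        stage("classify", medians=list(medians))

    # --- DE ---------------------------------------------------------------
    if config.run_de:
        de = bulk_and_de.differential_expression(
            norm, categories, min_pct=config.de_min_pct
        )
        de.to_csv(outdir / "de.csv")
        stage("de", n_tested=de.attrs["n_tested"],
              n_significant=int(de["significant"].sum()))

    # --- pseudobulk -------------------------------------------------------
    if config.run_bulkify:
        pooled = bulk_and_de.pool_bulk(
            norm_counts_for_bulk(qc, norm), patients,
            mode=config.bulk_mode, seed=config.seed,
        )
        bulk_scores = bulk_and_de.bulk_module_score(
            pooled, res_mod, sens_mod,
            n_bins=min(config.n_bins, max(2, len(pooled.profiles) // 2)),
            n_ctrl=config.n_ctrl, seed=config.seed,
        )
        bulk_scores.to_csv(outdir / "bulk_scores.csv")
        stage("bulkify", mode=pooled.mode, d=pooled.d,
              cells_dropped=int(pooled.cells_dropped.sum()))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    report = make_report(summary, evaluation)
    (outdir / "report.md").write_text(report)
    manifest["report"] = report
    return manifest


def norm_counts_for_bulk(qc, norm):
    """Raw counts restricted to the cells that survived all filters."""
    return qc[qc.obs_names.isin(norm.obs_names)].copy()


def make_report(summary: pd.DataFrame | None, evaluation=None) -> str:
    """Human-readable per-patient report: fractions, calls vs outcomes, accuracy."""
    if summary is None or len(summary) == 0:
        return "# Relapse-risk report\n\nNo patients in input.\n"
    lines = ["# Relapse-risk report", ""]
    lines.append(
        "| patient | n_cells | frac_sensitive | frac_resistant | mean_pc | risk_call | outcome |"
    )
    lines.append("|---|---|---|---|---|---|---|")
    for pid, row in summary.iterrows():
        lines.append(
            f"| {pid} | {row['n_cells']} | {row['frac_sensitive']:.3f} "
            f"| {row['frac_resistant']:.3f} | {row['mean_pc']:.3f} "
            f"| {row['risk_call']} | {row.get('outcome', 'unknown')} |"
        )
    lines.append("")
    if evaluation is not None:
        lines.append(
            f"Prediction accuracy: {evaluation.n_correct}/{evaluation.n_total} "
            f"(relapse {evaluation.relapse_correct}/{evaluation.relapse_total}, "
            f"no-relapse {evaluation.no_relapse_correct}/{evaluation.no_relapse_total})"
        )
    else:
        lines.append("Prediction accuracy: unavailable (no outcome labels).")
    lines.append("")
    return "\n".join(lines)
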