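"""Median-quadrant cell categorization, per-patient summaries, risk calls.

A cell is *sensitive* when its sensitivity score is above the median
sensitivity score of the complete dataset and its resistance score below the
median resistance score, *resistant* in the mirrored case, and *unclassified*
otherwise.  Medians are computed over whichever cell set is passed in; the
pipeline always passes the full multi-patient dataset so the quadrant is
anchored to the cohort, not to individual patients.  Ties at a median leave a
cell unclassified (strict inequalities), which keeps the rule well defined on
discrete score distributions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

SENSITIVE = "sensitive"
RESISTANT = "resistant"
UNCLASSIFIED = "unclassified"

RELAPSE = "relapse"
NO_RELAPSE = "no-relapse"
PRED_RELAPSE = "predicted-relapse"
PRED_NO_RELAPSE = "predicted-no-relapse"


def _score_frame(scores) -> pd.DataFrame:
    return getattr(scores, "table", scores)


def categorize_cells(scores) -> tuple[pd.Series, tuple[float, float]]:
    """Apply the median-quadrant rule; returns (categories, (med_sens, med_res))."""
    table = _score_frame(scores)
    if len(table) < 2:
        raise ValueError("categorization needs at least 2 scored cells")
    sens = table["sensitivity_score"]
    res = table["resistance_score"]
    med_s = float(sens.median())
    med_r = float(res.median())
    cat = pd.Series(UNCLASSIFIED, index=table.index, name="category")
    cat[(sens > med_s) & (res < med_r)] = SENSITIVE
    cat[(res > med_r) & (sens < med_s)] = RESISTANT
    return cat, (med_s, med_r)


def patient_fractions(categories: pd.Series, patients: pd.Series) -> pd.DataFrame:
    """Per-patient sensitive/resistant cell fractions.

    ``patients`` maps cell id -> patient id and must cover every categorized
    cell.
    """
    missing = categories.index.difference(patients.index)
    if len(missing):
        raise ValueError(f"no patient id for cell(s): {list(missing[:5])}")
    df = pd.DataFrame({"category": categories, "patient": patients.loc[categories.index]})
    out = []
    for pid, grp in df.groupby("patient", sort=True):
        n = len(grp)
        out.append(
            {
                "patient": pid,
                "n_cells": n,
                "frac_sensitive": (grp["category"] == SENSITIVE).sum() / n,
                "frac_resistant": (grp["category"] == RESISTANT).sum() / n,
            }
        )
    return pd.DataFrame(out).set_index("patient")


def patient_pc_summary(pc: pd.Series, patients: pd.Series) -> pd.DataFrame:
    """Mean and standard error of the PC score per patient.

    SEM uses the sample SD (n-1); for a single-cell patient the SEM is
    undefined and reported as NaN.
    """
    df = pd.DataFrame({"pc": pc, "patient": patients.loc[pc.index]})
    grp = df.groupby("patient", sort=True)["pc"]
    summary = pd.DataFrame(
        {
            "mean_pc": grp.mean(),
            "sem_pc": grp.apply(lambda s: s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else np.nan),
        }
    )
    summary.index.name = "patient"
    return summary


def risk_call(summary: pd.DataFrame, rule: str = "resistant-majority") -> pd.DataFrame:
    """Call relapse risk per patient from the classified-cell fractions.

    The default ``resistant-majority`` rule predicts relapse when the
    resistant fraction strictly exceeds the sensitive fraction; an exact tie
    is called no-relapse (conservative toward the unclassified mass).  A
    custom rule may be passed as a callable ``f(frac_sensitive,
    frac_resistant) -> bool`` (True = predicted relapse).  The rule used is
    recorded in ``.attrs["risk_rule"]``.
    """
    out = summary.copy()
    if callable(rule):
        pred = [
            bool(rule(s, r))
            for s, r in zip(out["frac_sensitive"], out["frac_resistant"])
        ]
        rule_name = getattr(rule, "__name__", "custom")
    elif rule == "resistant-majority":
        pred = (out["frac_resistant"] > out["frac_sensitive"]).tolist()
        rule_name = rule
    else:
        raise ValueError(f"unknown risk rule {rule!r}")
    out["risk_call"] = [PRED_RELAPSE if p else PRED_NO_RELAPSE for p in pred]
    out.attrs["risk_rule"] = rule_name
    return out


@dataclasses.dataclass
class PredictionEvaluation:
    n_correct: int
    n_total: int
    relapse_correct: int
    relapse_total: int
    no_relapse_correct: int
    no_relapse_total: int

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total


def evaluate_predictions(calls: pd.Series, outcomes: pd.Series) -> PredictionEvaluation:
    """Compare risk calls against known outcomes (``unknown`` rows excluded)."""
    common = calls.index.intersection(outcomes.index)
    known = [i for i in common if outcomes[i] in (RELAPSE, NO_RELAPSE)]
    if not known:
        raise ValueError("no patients with a known outcome label")
    rel = [i for i in known if outcomes[i] == RELAPSE]
    norel = [i for i in known if outcomes[i] == NO_RELAPSE]
    rel_ok = sum(calls[i] == PRED_RELAPSE for i in rel)
    norel_ok = sum(calls[i] == PRED_NO_RELAPSE for i in norel)
    return PredictionEvaluation(
        n_correct=rel_ok + norel_ok,
        n_total=len(known),
        relapse_correct=rel_ok,
        relapse_total=len(rel),
        no_relapse_correct=norel_ok,
        no_relapse_total=len(norel),
    )


def summarize_patients(
    scores,
    patients: pd.Series,
    outcomes: pd.Series | None = None,
    rule: str = "resistant-majority",
) -> pd.DataFrame:
    """Full per-patient summary: fractions, PC mean +/- SEM, risk call, outcome."""
    table = _score_frame(scores)
    categories, _ = categorize_cells(table)
    summary = patient_fractions(categories, patients)
    summary = summary.join(patient_pc_summary(table["pc_score"], patients))
    summary = risk_call(summary, rule=rule)
    if outcomes is not None:
        summary["outcome"] = outcomes.reindex(summary.index).fillna("unknown")
    else:
        summary["outcome"] = "unknown"
    return summary
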