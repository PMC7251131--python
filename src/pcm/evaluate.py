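"""Scoring inferred causal networks against ground truth.

An *edge score table* has one row per ordered pair (no self-pairs) with a
real-valued score (rho_C, rho_D or gamma), the boolean ground truth from
the generating coupling matrix, and optionally the thresholded decision.
ROC curves and AUROC treat the score as a ranking of candidate edges;
threshold sweeps compare the robustness of the pairwise (MCM) and
conditioned (PCM) decision rules to the choice of T.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

__all__ = ["make_edge_table", "roc_curve", "threshold_sweep", "RocResult"]


@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def make_edge_table(
    edge_frame: pd.DataFrame,
    truth_edges: Sequence[tuple[str, str]],
    score_column: str = "rho_D",
) -> pd.DataFrame:
    """Attach boolean truth to an inferred edge table.

    ``edge_frame`` is the ``edge_table`` of a network result (columns
    ``source``, ``target``, scores, ``decision``); ``truth_edges`` the
    ground-truth directed edges.
    """
    truth = set(truth_edges)
    df = edge_frame.copy()
    df = df[df["source"] != df["target"]].reset_index(drop=True)
    df["score"] = df[score_column]
    df["truth"] = [
        (s, t) in truth for s, t in zip(df["source"], df["target"])
    ]
    return df


def roc_curve(table: pd.DataFrame) -> RocResult:
    """ROC curve and AUROC of ``score`` against ``truth``.

    Threshold sweep over the unique scores with simultaneous inclusion of
    ties; AUROC by the trapezoid rule, which under the midrank tie
    convention equals the Mann-Whitney rank statistic.
    """
    truth = np.asarray(table["truth"], dtype=bool)
    score = np.asarray(table["score"], dtype=float)
    if truth.all() or not truth.any():
        raise ValueError("ROC requires both true and false edges")
    fpr, tpr, thr = _skm.roc_curve(truth, score)
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_skm.auc(fpr, tpr)))


def _metrics(pred: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    return {
        "precision": tp / (tp + fp) if (tp + fp) else np.nan,
        "recall": tp / (tp + fn) if (tp + fn) else np.nan,
        "accuracy": (tp + tn) / pred.size,
    }


def threshold_sweep(
    tables: Sequence[pd.DataFrame], grid: Sequence[float]
) -> pd.DataFrame:
    """Decision metrics over a grid of thresholds, for both rules.

    For each trial table and threshold T the MCM rule predicts an edge
    when ``rho_C >= T`` and the PCM rule when ``rho_D >= T``.  Returns a
    tidy frame with per-T mean and standard deviation of precision,
    recall and accuracy across trials (precision is absent for trials
    with no predicted edges and is averaged over the remaining trials).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    if not tables:
        raise ValueError("at least one trial table is required")
    rows = []
    for T in grid:
        for method, col in (("MCM", "rho_C"), ("PCM", "rho_D")):
            per_trial = []
            for tab in tables:
                truth = np.asarray(tab["truth"], dtype=bool)
                pred = np.asarray(tab[col], dtype=float) >= T
                per_trial.append(_metrics(pred, truth))
            row = {"method": method, "T": T, "n_trials": len(tables)}
            for m in ("precision", "recall", "accuracy"):
                vals = np.array([p[m] for p in per_trial], dtype=float)
                ok = np.isfinite(vals)
                row[f"{m}_mean"] = float(vals[ok].mean()) if ok.any() else np.nan
                row[f"{m}_std"] = float(vals[ok].std()) if ok.any() else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
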