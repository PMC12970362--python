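"""Scoring of discovered models against ground truth.

Support recovery is treated as entrywise classification of the coefficient
matrix: a term is "included" when its coefficient magnitude exceeds a small
tolerance (pruning produces exact zeros, so the tolerance only guards refit
round-off).  Accuracy = (TP+TN)/total, FPR = FP/(FP+TN), and the scaled mean
absolute error SMAE = ||Xi_true - Xi_pred||_1 / ||Xi_true||_1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetricsReport", "classify_support", "smae", "batch_metrics"]

#: |coefficient| above this counts as an included term.
INCLUSION_TOL = 1e-10


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    fpr: float
    smae: float
    replicates: int = 1
    fpr_undefined: bool = False  # no true negatives existed (fp+tn == 0)


def classify_support(xi_true: np.ndarray, xi_pred: np.ndarray) -> tuple[int, int, int, int]:
    """Entrywise confusion counts (tp, fp, tn, fn) of the nonzero patterns."""
    xi_true = np.asarray(xi_true, dtype=float)
    xi_pred = np.asarray(xi_pred, dtype=float)
    if xi_true.shape != xi_pred.shape:
        raise ValueError(f"shape mismatch: {xi_true.shape} vs {xi_pred.shape}")
    t = np.abs(xi_true) > INCLUSION_TOL
    p = np.abs(xi_pred) > INCLUSION_TOL
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    tn = int(np.sum(~t & ~p))
    fn = int(np.sum(t & ~p))
    return tp, fp, tn, fn


def smae(xi_true: np.ndarray, xi_pred: np.ndarray) -> float:
    """L1 coefficient error scaled by the L1 norm of the true coefficients."""
    xi_true = np.asarray(xi_true, dtype=float)
    xi_pred = np.asarray(xi_pred, dtype=float)
    if xi_true.shape != xi_pred.shape:
        raise ValueError(f"shape mismatch: {xi_true.shape} vs {xi_pred.shape}")
    denom = np.abs(xi_true).sum()
    if denom == 0:
        raise ValueError("true coefficient matrix is all zero; SMAE undefined")
    return float(np.abs(xi_true - xi_pred).sum() / denom)


def _single_report(xi_true: np.ndarray, xi_pred: np.ndarray) -> MetricsReport:
    tp, fp, tn, fn = classify_support(xi_true, xi_pred)
    total = tp + fp + tn + fn
    undefined = (fp + tn) == 0
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / total,
        fpr=0.0 if undefined else fp / (fp + tn),
        smae=smae(xi_true, xi_pred),
        fpr_undefined=undefined,
    )


def batch_metrics(
    xi_true: np.ndarray,
    xi_preds: list[np.ndarray],
) -> MetricsReport:
    """Average per-replicate metrics over noise instantiations."""
    if len(xi_preds) < 1:
        raise ValueError("need at least one replicate")
    reports = [_single_report(xi_true, xp) for xp in xi_preds]
    return MetricsReport(
        tp=sum(r.tp for r in reports),
        fp=sum(r.fp for r in reports),
        tn=sum(r.tn for r in reports),
        fn=sum(r.fn for r in reports),
        accuracy=float(np.mean([r.accuracy for r in reports])),
        fpr=float(np.mean([r.fpr for r in reports])),
        smae=float(np.mean([r.smae for r in reports])),
        replicates=len(reports),
        fpr_undefined=any(r.fpr_undefined for r in reports),
    )
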