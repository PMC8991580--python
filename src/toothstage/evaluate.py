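"""Agreement and learning-curve evaluation for six-stage classification.

Confusion matrices are 6x6 integer count grids with rows = reference
(ground-truth) stage and columns = predicted stage, both in the fixed order
C, D, E, F, G, H. Reports follow the display convention of the source
cross-tabulations: row-normalized proportions to two decimals, overall
accuracy = trace/total, and unweighted Cohen's kappa

    kappa = (p_o - p_e) / (1 - p_e),
    p_o = trace/total,  p_e = sum_k row_k * col_k / total^2.
"""

from __future__ import annotations

import numpy as np

from toothstage.classifier import STAGES, stage_index
from toothstage.classifier import TrainHistory


def confusion(true_labels, pred_labels) -> np.ndarray:
    """6x6 count matrix: counts[i, j] = #(true = stage i, predicted = stage j)."""
    t = [stage_index(s) for s in true_labels]
    p = [stage_index(s) for s in pred_labels]
    if len(t) != len(p):
        raise ValueError(f"label lists differ in length: {len(t)} vs {len(p)}")
    m = np.zeros((6, 6), dtype=np.int64)
    np.add.at(m, (t, p), 1)
    return m


def _check_matrix(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"confusion matrix must be square, got shape {m.shape}")
    if (m < 0).any():
        raise ValueError("confusion matrix has negative counts")
    return m


def row_normalize(m: np.ndarray) -> np.ndarray:
    """Rows as proportions; nonzero rows sum to 1, all-zero rows stay zero."""
    m = _check_matrix(m).astype(float)
    sums = m.sum(axis=1, keepdims=True)
    return np.divide(m, sums, out=np.zeros_like(m), where=sums > 0)


def overall_accuracy(m: np.ndarray) -> float:
    """trace / total; rejects an empty matrix."""
    m = _check_matrix(m)
    total = m.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(m) / total)


def cohen_kappa(m: np.ndarray) -> float:
    """Unweighted Cohen's kappa from a count matrix.

    When the expected agreement p_e degenerates to 1 (all mass in one cell),
    kappa is 1 for perfect agreement and undefined otherwise.
    """
    m = _check_matrix(m).astype(float)
    total = m.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(m) / total
    p_e = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / total**2
    if np.isclose(p_e, 1.0):
        if np.isclose(p_o, 1.0):
            return 1.0
        raise ValueError("degenerate margins: expected agreement is 1 but observed is not")
    return float((p_o - p_e) / (1.0 - p_e))


def per_stage_recall(m: np.ndarray) -> np.ndarray:
    """Diagonal of the row-normalized matrix: recall per reference stage."""
    return np.diag(row_normalize(m))


def agreement_report(true_labels, pred_labels) -> dict:
    """Counts, two-decimal proportions, accuracy, kappa and per-stage recall."""
    m = confusion(true_labels, pred_labels)
    return {
        "stages": list(STAGES),
        "counts": m.tolist(),
        "proportions": np.round(row_normalize(m), 2).tolist(),
        "overall_accuracy": overall_accuracy(m),
        "kappa": cohen_kappa(m),
        "per_stage_recall": per_stage_recall(m).tolist(),
    }


def summarize_history(h: TrainHistory) -> dict:
    """Best epoch (1-based argmin of validation loss), its loss, and the
    overfitting onset: the first epoch whose validation loss exceeds the
    running minimum for at least two consecutive epochs (None if absent)."""
    vl = list(h.val_loss)
    if not vl:
        raise ValueError("empty history")
    best = int(np.argmin(vl))
    onset = None
    run_min = vl[0]
    streak = 0
    for i in range(1, len(vl)):
        if vl[i] > run_min:
            streak += 1
            if streak >= 2 and onset is None:
                onset = i - streak + 2  # 1-based epoch where the rise began
        else:
            streak = 0
        run_min = min(run_min, vl[i])
    return {
        "best_epoch": best + 1,
        "min_val_loss": float(vl[best]),
        "overfit_onset": onset,
        "final_train_acc": float(h.train_acc[-1]) if h.train_acc else None,
        "final_val_acc": float(h.val_acc[-1]) if h.val_acc else None,
    }
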