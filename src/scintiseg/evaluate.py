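"""Segmentation metrics, cross-validation and paired comparison.

Per-class metrics are pixel-level one-vs-rest: precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 = 2PR/(P+R), and the Dice similarity coefficient
DSC = 2|G∩H| / (|G|+|H|) between ground-truth and predicted binary masks
(for one-vs-rest masks, DSC computed from the same counts equals F1).
"Overall" metrics micro-average the pooled confusion counts of the three
classes.  Generalisation is assessed with seeded k-fold cross-validation
(default k = 5) and differences between paired metric sequences with a
classical two-tailed paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

__all__ = ["EvalReport", "per_class_counts", "precision_recall_f1", "dsc",
           "evaluate_segmentation", "kfold_split", "crossval", "paired_ttest",
           "CLASS_NAMES"]

CLASS_NAMES = {0: "background", 1: "mLN", 2: "remnant"}


@dataclass
class EvalReport:
    """Per-class and overall metrics (percent) with the underlying counts."""

    counts: dict[int, tuple[int, int, int, int]]          # cls -> (TP, FP, FN, TN)
    per_class: dict[int, dict[str, float]]                # cls -> metric% dict
    overall: dict[str, float]                             # micro-averaged %
    n_pixels: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls, m in self.per_class.items():
            rows.append({"region": CLASS_NAMES.get(cls, str(cls)), **m})
        rows.append({"region": "overall", **self.overall})
        return pd.DataFrame(rows)


def per_class_counts(pred: np.ndarray, truth: np.ndarray,
                     cls: int) -> tuple[int, int, int, int]:
    """One-vs-rest pixelwise confusion counts (TP, FP, FN, TN)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred == cls
    t = truth == cls
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    return tp, fp, fn, tn


def precision_recall_f1(counts: tuple[int, int, int, int]) -> tuple[float, float, float]:
    """Metrics on [0, 1] with degenerate-denominator conventions.

    An empty denominator yields 0, except when both prediction and truth are
    empty for the class (TP = FP = FN = 0), which counts as a perfect 1 —
    unavoidable on scans without the class.
    """
    tp, fp, fn, _ = counts
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    if tp == 0 and fp == 0 and fn == 0:
        return 1.0, 1.0, 1.0
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f1


def dsc(G: np.ndarray, H: np.ndarray) -> float:
    """Dice similarity coefficient 2|G∩H|/(|G|+|H|); both-empty -> 1."""
    G = np.asarray(G, dtype=bool)
    H = np.asarray(H, dtype=bool)
    if G.shape != H.shape:
        raise ValueError(f"shape mismatch: {G.shape} vs {H.shape}")
    denom = int(G.sum()) + int(H.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((G & H).sum()) / denom


def evaluate_segmentation(pred: np.ndarray | Sequence[np.ndarray],
                          truth: np.ndarray | Sequence[np.ndarray],
                          classes: tuple[int, ...] = (0, 1, 2)) -> EvalReport:
    """Full report for one map pair or pooled over a sequence of pairs."""
    if isinstance(pred, np.ndarray) and pred.ndim == 2:
        pred, truth = [pred], [truth]
    counts = {cls: np.zeros(4, dtype=np.int64) for cls in classes}
    n_pixels = 0
    dice_num = {cls: 0 for cls in classes}
    dice_den = {cls: 0 for cls in classes}
    for p, t in zip(pred, truth, strict=True):
        n_pixels += np.asarray(p).size
        for cls in classes:
            c = per_class_counts(p, t, cls)
            counts[cls] += c
            dice_num[cls] += 2 * c[0]
            dice_den[cls] += 2 * c[0] + c[1] + c[2]
    per_class = {}
    for cls in classes:
        tp, fp, fn, tn = (int(v) for v in counts[cls])
        pr, rc, f1 = precision_recall_f1((tp, fp, fn, tn))
        d = dice_num[cls] / dice_den[cls] if dice_den[cls] > 0 else 1.0
        per_class[cls] = {"precision": 100 * pr, "recall": 100 * rc,
                          "f1": 100 * f1, "dsc": 100 * d}
    pooled = tuple(int(sum(counts[cls][j] for cls in classes)) for j in range(4))
    pr, rc, f1 = precision_recall_f1(pooled)
    dnum = sum(dice_num.values())
    dden = sum(dice_den.values())
    overall = {"precision": 100 * pr, "recall": 100 * rc, "f1": 100 * f1,
               "dsc": 100 * (dnum / dden if dden > 0 else 1.0)}
    return EvalReport(counts={c: tuple(int(v) for v in counts[c]) for c in classes},
                      per_class=per_class, overall=overall, n_pixels=n_pixels)


def kfold_split(items: Sequence, k: int = 5, seed: int = 0) -> list[tuple[list[int], list[int]]]:
    """Seeded shuffled k-fold partition of item indices.

    Test folds are disjoint, cover all items, and differ in size by at most
    one; the same seed reproduces the same partition.
    """
    n = len(items)
    if k > n:
        raise ValueError(f"k={k} exceeds item count {n}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(list(tr), list(te)) for tr, te in kf.split(np.arange(n))]


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Classical two-tailed paired t-test on the differences a - b.

    Conventions for degenerate inputs: all differences zero -> (0, 1); zero
    variance with nonzero mean -> (signed inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def crossval(dataset: Sequence[tuple[np.ndarray, np.ndarray]],
             *, k: int = 5, seed: int = 0,
             pipeline_config=None) -> dict:
    """k-fold cross-validation of the full pipeline on (scan, labels) pairs.

    Per fold: pixel-position priors are re-estimated from the training fold
    only, the classifier is retrained from scratch, and the held-out fold is
    evaluated.  Folds whose test items lack any foreground class are recorded
    as degenerate rather than skipped.  Returns per-fold reports, the pooled
    report, and per-fold generalisation error (final validation loss).
    """
    from .config import RunConfig
    from .pipeline import train_pipeline, predict_pipeline

    cfg = pipeline_config if pipeline_config is not None else RunConfig()
    folds = kfold_split(dataset, k=k, seed=seed)
    fold_reports: list[EvalReport] = []
    gen_errors: list[float] = []
    degenerate: list[int] = []
    all_preds: list[np.ndarray] = []
    all_truths: list[np.ndarray] = []
    for fold_idx, (train_idx, test_idx) in enumerate(folds):
        train_items = [dataset[i] for i in train_idx]
        test_items = [dataset[i] for i in test_idx]
        fitted = train_pipeline(train_items, cfg, seed=seed + fold_idx)
        preds = [predict_pipeline(fitted, scan).labels for scan, _ in test_items]
        truths = [lab for _, lab in test_items]
        if not any((t > 0).any() for t in truths):
            degenerate.append(fold_idx)
        fold_reports.append(evaluate_segmentation(preds, truths))
        gen_errors.append(fitted.final_val_loss)
        all_preds.extend(preds)
        all_truths.extend(truths)
    return {"folds": fold_reports,
            "pooled": evaluate_segmentation(all_preds, all_truths),
            "generalization_error": gen_errors,
            "degenerate_folds": degenerate,
            "splits": folds}
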