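"""Classification and segmentation agreement metrics.

One-vs-rest confusion counts; accuracy, sensitivity, specificity and
precision as percentages; rank-based ROC AUC; and the Jaccard
(intersection-over-union) coefficient for binary masks.

An undefined quotient (zero denominator, e.g. precision with no positive
predictions) is reported as ``None`` rather than coerced to 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "metrics_from_counts",
    "multiclass_report",
    "roc_auc",
    "jaccard_index",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest tally for a single positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    """Per-class and averaged percentages for a multi-class evaluation."""

    class_names: list
    per_class: dict  # class -> {"Ac": .., "Sn": .., "Sp": .., "Pr": ..}
    macro: dict
    micro: dict
    n_samples: int
    per_class_auc: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def confusion(
    y_true: Sequence, y_pred: Sequence, positive_class
) -> ConfusionCounts:
    """Count TP/FP/TN/FN treating ``positive_class`` against the rest."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"label vectors differ in length: {y_true.shape} vs {y_pred.shape}"
        )
    t = y_true == positive_class
    p = y_pred == positive_class
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def metrics_from_counts(counts: ConfusionCounts) -> dict:
    """Accuracy, sensitivity, specificity, precision (percent).

    Ac = (TP+TN)/total, Sn = TP/(TP+FN), Sp = TN/(TN+FP), Pr = TP/(TP+FP),
    each scaled by 100.  A zero denominator yields ``None``.
    """
    if counts.total == 0:
        raise ValueError("all-zero confusion counts")
    return {
        "Ac": _pct(counts.tp + counts.tn, counts.total),
        "Sn": _pct(counts.tp, counts.tp + counts.fn),
        "Sp": _pct(counts.tn, counts.tn + counts.fp),
        "Pr": _pct(counts.tp, counts.tp + counts.fp),
    }


def multiclass_report(
    y_true: Sequence,
    y_pred: Sequence,
    class_names: Sequence | None = None,
    scores: np.ndarray | None = None,
) -> MetricReport:
    """One-vs-rest Table-style report with macro and micro averages.

    Macro averages are unweighted means over classes (undefined entries
    skipped); micro averages pool the one-vs-rest counts over classes.
    ``scores`` (samples x classes), when given, adds per-class AUC.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("cannot evaluate an empty label set")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    if class_names is not None and len(class_names) != classes.size:
        # fall back to positional naming over observed classes
        class_names = None
    names = (
        list(class_names)
        if class_names is not None
        else [str(c) for c in classes]
    )

    per_class = {}
    pooled = dict(tp=0, fp=0, tn=0, fn=0)
    per_auc: dict | None = {} if scores is not None else None
    for j, (c, name) in enumerate(zip(classes, names)):
        cnt = confusion(y_true, y_pred, c)
        per_class[name] = metrics_from_counts(cnt)
        pooled["tp"] += cnt.tp
        pooled["fp"] += cnt.fp
        pooled["tn"] += cnt.tn
        pooled["fn"] += cnt.fn
        if scores is not None:
            binary = (y_true == c).astype(int)
            if 0 < binary.sum() < binary.size:
                per_auc[name] = roc_auc(scores[:, j], binary)
            else:
                per_auc[name] = None

    macro = {}
    for key in ("Ac", "Sn", "Sp", "Pr"):
        vals = [m[key] for m in per_class.values() if m[key] is not None]
        macro[key] = float(np.mean(vals)) if vals else None
    micro_counts = ConfusionCounts(**pooled)
    micro = metrics_from_counts(micro_counts)
    # pooled accuracy over one-vs-rest tallies equals plain accuracy only
    # after rescaling; report plain accuracy for the micro Ac
    micro["Ac"] = 100.0 * float(np.mean(y_true == y_pred))

    return MetricReport(
        class_names=names,
        per_class=per_class,
        macro=macro,
        micro=micro,
        n_samples=int(y_true.size),
        per_class_auc=per_auc,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random positive outscores a random negative (ties half).

    Computed from midranks (equivalent to the Mann-Whitney U statistic).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for AUC")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def jaccard_index(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two binary masks; both empty -> 1.0."""
    mask_a = np.asarray(mask_a).astype(bool)
    mask_b = np.asarray(mask_b).astype(bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError(
            f"mask shape mismatch: {mask_a.shape} vs {mask_b.shape}"
        )
    union = int(np.sum(mask_a | mask_b))
    if union == 0:
        return 1.0
    return float(np.sum(mask_a & mask_b) / union)
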