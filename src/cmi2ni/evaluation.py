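"""Confusion-matrix metrics and ROC/AUC against a gold-standard network.

Evaluation is undirected: gold-standard edge lists may be directed, but
directions are collapsed to unordered pairs before counting, matching the
undirected output of the inference engine.  Two counting modes are
offered: ``unordered-pairs`` counts each of the n(n-1)/2 gene pairs once;
``symmetric-matrix`` counts each ordered off-diagonal cell of the
adjacency matrix, exactly doubling all four confusion counts (a
convention common in benchmark tables where TP + FN equals twice the
edge count).  All five ratio metrics are identical between modes.

Metrics with a zero denominator are reported as ``None`` (undefined),
never silently 0 — small networks hit these cases routinely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.metrics import roc_curve

from .errors import InputError
from .io import GoldStandard

__all__ = ["ConfusionCounts", "MetricSet", "confusion", "metrics", "roc_auc", "evaluate"]

COUNTING_MODES = ("unordered-pairs", "symmetric-matrix")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    counting_mode: str = "unordered-pairs"

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be nonnegative")
        if self.counting_mode not in COUNTING_MODES:
            raise InputError(f"counting_mode must be one of {COUNTING_MODES}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """TPR/FPR/PPV/ACC/MCC (plus AUC when a ranking was supplied); any
    metric whose defining ratio has denominator 0 is ``None``."""

    tpr: float | None = None
    fpr: float | None = None
    ppv: float | None = None
    acc: float | None = None
    mcc: float | None = None
    auc: float | None = None

    def as_dict(self) -> dict:
        return {
            "tpr": self.tpr,
            "fpr": self.fpr,
            "ppv": self.ppv,
            "acc": self.acc,
            "mcc": self.mcc,
            "auc": self.auc,
        }


def _as_gold(gold) -> GoldStandard:
    if isinstance(gold, GoldStandard):
        return gold
    return GoldStandard(frozenset(frozenset(p) for p in gold), frozenset())


def confusion(predicted, gold, mode: str = "unordered-pairs") -> ConfusionCounts:
    """Count TP/FP/TN/FN of a predicted network against a gold standard.

    ``predicted`` is a :class:`~cmi2ni.inference.Network`; ``gold`` is a
    :class:`~cmi2ni.io.GoldStandard` or a plain collection of unordered
    pairs.  Every gene pair of the prediction universe is evaluated;
    pairs not listed as gold positives are negatives.
    """
    if mode not in COUNTING_MODES:
        raise InputError(f"mode must be one of {COUNTING_MODES}")
    gold = _as_gold(gold)
    universe = set(predicted.genes)
    missing = sorted(gold.genes - universe)
    if missing:
        raise InputError(f"gold-standard genes absent from prediction universe: {missing}")
    tp = fp = tn = fn = 0
    for a, b in combinations(predicted.genes, 2):
        pair = frozenset((a, b))
        is_edge = predicted.has_edge(a, b)
        is_true = pair in gold.positives
        if is_edge and is_true:
            tp += 1
        elif is_edge:
            fp += 1
        elif is_true:
            fn += 1
        else:
            tn += 1
    if mode == "symmetric-matrix":
        tp, fp, tn, fn = 2 * tp, 2 * fp, 2 * tn, 2 * fn
    return ConfusionCounts(tp, fp, tn, fn, counting_mode=mode)


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def metrics(c: ConfusionCounts) -> MetricSet:
    """The five standard confusion-matrix metrics:

    TPR = TP/(TP+FN), FPR = FP/(FP+TN), PPV = TP/(TP+FP),
    ACC = (TP+TN)/total,
    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    mcc_den = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    return MetricSet(
        tpr=_ratio(c.tp, c.tp + c.fn),
        fpr=_ratio(c.fp, c.fp + c.tn),
        ppv=_ratio(c.tp, c.tp + c.fp),
        acc=_ratio(c.tp + c.tn, c.total),
        mcc=None if mcc_den == 0 else (c.tp * c.tn - c.fp * c.fn) / mcc_den,
    )


def roc_auc(ranking, gold, mode: str = "unordered-pairs"):
    """ROC curve and AUC from a scored pair ranking.

    ``ranking`` is a list of (gene_a, gene_b, score) covering every
    evaluated pair (as produced by
    :func:`~cmi2ni.inference.edge_ranking`).  The curve sweeps a
    threshold over the distinct scores with ties grouped; AUC is the
    trapezoidal area, which for a grouped-tie sweep equals the normalized
    Mann–Whitney statistic of the scores.  Counting mode does not affect
    the rates.  Returns ``(metric_set, points)`` where ``points`` is the
    (fpr, tpr) polyline; AUC is ``None`` when the gold standard has no
    positives or no negatives among the evaluated pairs.
    """
    if mode not in COUNTING_MODES:
        raise InputError(f"mode must be one of {COUNTING_MODES}")
    gold = _as_gold(gold)
    if not ranking:
        raise InputError("empty ranking")
    y_true = np.array([frozenset((a, b)) in gold.positives for a, b, _ in ranking], bool)
    scores = np.array([s for _, _, s in ranking], float)
    if y_true.all() or not y_true.any():
        return MetricSet(auc=None), [(0.0, 0.0), (1.0, 1.0)]
    fpr, tpr, _ = roc_curve(y_true, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    points = list(zip(fpr.tolist(), tpr.tolist()))
    return MetricSet(auc=auc), points


def evaluate(predicted, gold, mode: str = "unordered-pairs", ranking=None) -> MetricSet:
    """Confusion metrics of a network, plus AUC when a ranking is given."""
    ms = metrics(confusion(predicted, gold, mode))
    if ranking is not None:
        auc_ms, _ = roc_auc(ranking, gold, mode)
        ms = MetricSet(**{**ms.as_dict(), "auc": auc_ms.auc})
    return ms
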