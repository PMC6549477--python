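"""Evaluation metrics: binary confusion metrics, PR curves, multi-label ranks.

Binary metrics (precision, accuracy, recall, specificity, Matthews
correlation coefficient) are exact transcriptions of their confusion-count
formulas; any metric whose denominator is zero returns NaN rather than
raising. AUPR is the step integral of the precision-recall curve over all
distinct thresholds. The multi-label metrics follow the MLKNN literature:
hamming loss at a 0.5 cutoff, one-error, coverage (0-based: steps beyond
the first), ranking loss and average precision, with within-instance score
ties resolved by the average-rank convention (coverage uses the guaranteed
depth, i.e. max-rank, so it stays an integer count).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import numpy.typing as npt
from sklearn.metrics import average_precision_score

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def binary_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Precision, accuracy, recall, specificity and MCC from confusion counts."""
    tp, fp, tn, fn = float(c.tp), float(c.fp), float(c.tn), float(c.fn)

    def _div(num: float, den: float) -> float:
        return num / den if den > 0 else math.nan

    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return {
        "precision": _div(tp, tp + fp),
        "acc": _div(tp + tn, tp + fn + tn + fp),
        "recall": _div(tp, tp + fn),
        "specificity": _div(tn, tn + fp),
        "mcc": (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else math.nan,
    }


def confusion_at_threshold(
    scores: npt.NDArray[np.float64], labels: npt.NDArray[np.int_], threshold: float = 0.5
) -> ConfusionCounts:
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=int).ravel()
    calls = s >= threshold
    return ConfusionCounts(
        tp=int((calls & (y == 1)).sum()),
        fp=int((calls & (y == 0)).sum()),
        tn=int((~calls & (y == 0)).sum()),
        fn=int((~calls & (y == 1)).sum()),
    )


def pr_curve_aupr(scores: npt.NDArray[np.float64], labels: npt.NDArray[np.int_]) -> float:
    """Area under the precision-recall curve (step integral over distinct thresholds)."""
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=int).ravel()
    if y.min() == y.max():
        raise ValueError("AUPR requires at least one positive and one negative label")
    return float(average_precision_score(y, s))


def roc_auc(scores: npt.NDArray[np.float64], labels: npt.NDArray[np.int_]) -> float:
    from sklearn.metrics import roc_auc_score

    y = np.asarray(labels, dtype=int).ravel()
    if y.min() == y.max():
        raise ValueError("AUC requires at least one positive and one negative label")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float).ravel()))


def _avg_ranks(scores_row: npt.NDArray[np.float64]) -> npt.NDArray[np.float64]:
    """Descending average ranks (1-based): rank = 1 + #higher + 0.5 * #tied-others."""
    s = scores_row[:, None]
    higher = (scores_row[None, :] > s).sum(axis=1)
    tied = (scores_row[None, :] == s).sum(axis=1) - 1
    return 1.0 + higher + 0.5 * tied


def multilabel_metrics(
    scores: npt.NDArray[np.float64], labels: npt.NDArray[np.int_]
) -> dict[str, float]:
    """The five rank-based multi-label metrics plus hamming loss.

    Instances with no relevant label are skipped for the rank-based metrics
    (with a logged count); instances with no irrelevant label are
    additionally skipped for ranking loss, whose pair universe is empty.
    """
    S = np.asarray(scores, dtype=float)
    Y = np.asarray(labels, dtype=int)
    if S.shape != Y.shape:
        raise ValueError("score and label matrices must have the same shape")
    n, q = S.shape

    hamming = float(((S >= 0.5).astype(int) != Y).mean())

    one_errors: list[float] = []
    coverages: list[float] = []
    rank_losses: list[float] = []
    avg_precisions: list[float] = []
    n_skipped = 0
    for i in range(n):
        rel = Y[i] == 1
        if not rel.any():
            n_skipped += 1
            continue
        s = S[i]
        # one-error: the top-ranked label is not relevant (tie at the top
        # counts as correct if any relevant label attains the maximum score)
        one_errors.append(0.0 if s[rel].max() == s.max() else 1.0)

        # coverage: guaranteed depth to reach all relevant labels, 0-based
        max_ranks = np.array([(s >= s[l]).sum() for l in range(q)])
        coverages.append(float(max_ranks[rel].max() - 1))

        if (~rel).any():
            srel = s[rel][:, None]
            sirr = s[~rel][None, :]
            bad = (srel < sirr).sum() + 0.5 * (srel == sirr).sum()
            rank_losses.append(float(bad) / (rel.sum() * (~rel).sum()))

        ranks = _avg_ranks(s)
        rel_idx = np.flatnonzero(rel)
        precs = []
        for l in rel_idx:
            rel_at_or_above = (
                1.0 + (s[rel_idx] > s[l]).sum() + 0.5 * ((s[rel_idx] == s[l]).sum() - 1)
            )
            precs.append(rel_at_or_above / ranks[l])
        avg_precisions.append(float(np.mean(precs)))

    if n_skipped:
        logger.info("multilabel_metrics: skipped %d instance(s) with no relevant label", n_skipped)

    def _mean(xs: list[float]) -> float:
        return float(np.mean(xs)) if xs else math.nan

    return {
        "hamming_loss": hamming,
        "one_error": _mean(one_errors),
        "coverage": _mean(coverages),
        "ranking_loss": _mean(rank_losses),
        "average_precision": _mean(avg_precisions),
    }


def report_tsv(metrics: dict[str, float], path) -> None:
    """Write one row per metric: name <tab> value."""
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for name, value in metrics.items():
            fh.write(f"{name}\t{value:.6g}\n")
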