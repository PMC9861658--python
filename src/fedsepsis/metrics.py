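"""Evaluation: confusion counts, AUROC, AUPRC, earliness, and report deltas.

Curve metrics are computed at the episode level on the sequence model's
episode score (the lock-window probability when the >0.5 lock fired, else the
maximum window probability).  *Earliness* is the median, over true-positive
episodes, of hours between the first positive window and the sepsis onset;
larger is earlier and therefore better.
"""

from __future__ import annotations

import dataclasses
import decimal
import math
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

POSITIVE_THRESHOLD = 0.5  # positive call iff score is strictly above


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else math.nan

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else math.nan


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    auprc: float
    auroc: float
    earliness_h: float | None
    counts: ConfusionCounts
    n_episodes: int


def _check_aligned(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-d arrays")
    return scores, labels


def confusion(
    scores, labels, threshold: float = POSITIVE_THRESHOLD
) -> ConfusionCounts:
    scores, labels = _check_aligned(scores, labels)
    calls = scores > threshold
    return ConfusionCounts(
        tp=int(np.sum(calls & labels)),
        fp=int(np.sum(calls & ~labels)),
        tn=int(np.sum(~calls & ~labels)),
        fn=int(np.sum(~calls & labels)),
    )


def auroc(scores, labels) -> float:
    """Trapezoidal ROC area; equals P(score_pos > score_neg) + 0.5 P(tie)."""
    scores, labels = _check_aligned(scores, labels)
    if labels.all() or not labels.any():
        raise ValueError("AUROC needs both classes")
    return float(roc_auc_score(labels, scores))


def auprc(scores, labels) -> float:
    """Area under the precision-recall step curve (ties grouped by threshold)."""
    scores, labels = _check_aligned(scores, labels)
    if not labels.any():
        raise ValueError("AUPRC needs at least one positive")
    return float(average_precision_score(labels, scores))


def earliness(traces: Sequence, labels, onsets) -> float | None:
    """Median lead time (onset window minus lock window, hours) over true positives.

    ``traces`` carry the lock windows, ``labels`` the episode truth, and
    ``onsets`` the per-episode onset window index (ignored for negatives).
    Returns None when there are no true positives.
    """
    leads = []
    for trace, label, onset in zip(traces, labels, onsets):
        if label and trace.lock_window is not None and onset is not None:
            leads.append(float(onset - trace.lock_window))
    if not leads:
        import warnings

        warnings.warn("earliness undefined: no true-positive episodes")
        return None
    return float(np.median(leads))


def report_from_traces(traces: Sequence, grids: Sequence) -> MetricsReport:
    """Episode-level report for a set of prediction traces."""
    labels = np.array([g.label for g in grids], dtype=bool)
    scores = np.array([t.episode_score for t in traces], dtype=float)
    onsets = [g.onset_window for g in grids]
    return MetricsReport(
        auprc=auprc(scores, labels),
        auroc=auroc(scores, labels),
        earliness_h=earliness(traces, labels, onsets),
        counts=confusion(scores, labels),
        n_episodes=len(grids),
    )


def _round_half_up(x: float, places: int = 2) -> float:
    q = decimal.Decimal(10) ** -places
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def compare_reports(a: MetricsReport, b: MetricsReport) -> dict[str, float]:
    """Improvement of ``a`` over ``b`` in percentage points, rounded to 2 decimals."""
    return {
        "auprc_pp": _round_half_up((a.auprc - b.auprc) * 100.0),
        "auroc_pp": _round_half_up((a.auroc - b.auroc) * 100.0),
    }


def report_row(report: MetricsReport, round_index: int | None = None) -> dict:
    """Flat row (round, AUPRC %, AUROC %, earliness h) for tabular output."""
    row = {
        "auprc_pct": report.auprc * 100.0,
        "auroc_pct": report.auroc * 100.0,
        "earliness_h": report.earliness_h,
        "n_episodes": report.n_episodes,
    }
    if round_index is not None:
        row = {"round": round_index, **row}
    return row
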