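"""Human-in-the-loop review: interaction scores, review queues and an
idealized (oracle) review simulation.

The interaction score of an epoch is |p_event - p_normal| = |2 p_event - 1|:
0 for a maximally ambiguous prediction, 1 for a maximally confident one.
Epochs whose score falls inside a chosen threshold interval are queued for
review; the oracle simulation replaces their predictions with ground truth
— the testable upper bound on what an expert reviewer could contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import ConfusionCounts, classification_metrics, confusion_counts

__all__ = [
    "interaction_score",
    "ReviewQueue",
    "select_review",
    "simulate_oracle_review",
]


def interaction_score(p_event: np.ndarray | float) -> np.ndarray | float:
    """|p_event - p_normal| in [0, 1]; 0 at p_event = 0.5."""
    p = np.asarray(p_event, dtype=np.float64)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p_event must lie in [0, 1]")
    out = np.abs(2.0 * p - 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class ReviewQueue:
    """Epoch indices flagged for review, most ambiguous first."""

    indices: np.ndarray
    interval: tuple[float, float]
    coverage: float


def select_review(scores: np.ndarray, interval: tuple[float, float]) -> ReviewQueue:
    """Flag exactly the epochs whose interaction score lies in the closed
    interval [lo, hi]; report the flagged fraction as coverage."""
    lo, hi = interval
    if lo > hi:
        raise ValueError(f"interval lower bound {lo} exceeds upper bound {hi}")
    if lo < 0 or hi > 1:
        raise ValueError("interval must lie within [0, 1]")
    scores = np.asarray(scores, dtype=np.float64)
    flagged = np.flatnonzero((scores >= lo) & (scores <= hi))
    order = np.argsort(scores[flagged], kind="stable")
    return ReviewQueue(indices=flagged[order], interval=(lo, hi),
                       coverage=len(flagged) / len(scores) if len(scores) else 0.0)


def simulate_oracle_review(p_event: np.ndarray, labels: np.ndarray,
                           queue: ReviewQueue, threshold: float = 0.5,
                           ) -> dict[str, float | dict]:
    """Replace flagged epochs' predictions with ground truth and recompute
    the binary metric suite.

    Returns coverage, metrics before/after and the deltas (ACC, SEN, SPE).
    Oracle correction can only fix errors, never introduce them, so the
    post-review metrics are non-decreasing in the flagged set.
    """
    p_event = np.asarray(p_event, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pred = (p_event >= threshold).astype(int)
    corrected = pred.copy()
    corrected[queue.indices] = labels[queue.indices]

    before = classification_metrics(confusion_counts(labels, pred))
    after = classification_metrics(confusion_counts(labels, corrected))
    deltas = {}
    for k in ("ACC", "SEN", "SPE"):
        b, a = before.get(k), after.get(k)
        deltas["d" + k] = (a - b) if (a is not None and b is not None) else None
    return {"coverage": queue.coverage, "before": before, "after": after,
            **deltas}
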