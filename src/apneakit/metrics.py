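"""Evaluation suite: confusion-matrix metrics, AUC, AHI-regression
agreement statistics (R², MAE±SD, ICC) and Bland–Altman summaries.

All metrics are returned as fractions; percent formatting belongs to the
reporting layer. A metric whose denominator is zero is reported as ``None``
(undefined), never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "classification_metrics",
    "macro_f1",
    "auc",
    "regression_metrics",
    "icc_absolute_agreement",
    "bland_altman",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def classification_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """ACC, SEN (recall), SPE, PPV (precision) and F1 from counts.

    F1 is the harmonic mean of SEN and PPV; any metric with a zero
    denominator is None.
    """
    acc = _ratio(c.tp + c.tn, c.total)
    sen = _ratio(c.tp, c.tp + c.fn)
    spe = _ratio(c.tn, c.tn + c.fp)
    ppv = _ratio(c.tp, c.tp + c.fp)
    if sen is None or ppv is None or sen + ppv == 0:
        f1 = None
    else:
        f1 = 2 * sen * ppv / (sen + ppv)
    return {"ACC": acc, "SEN": sen, "SPE": spe, "PPV": ppv, "F1": f1}


def macro_f1(y_true: np.ndarray, y_pred: np.ndarray,
             classes: tuple | None = None) -> float:
    """Unweighted mean of one-vs-rest per-class F1 scores.

    A class with undefined F1 (never present and never predicted)
    contributes 0, the conservative convention.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = tuple(np.unique(np.concatenate([y_true, y_pred])))
    scores = []
    for cls in classes:
        c = confusion_counts(y_true == cls, y_pred == cls)
        f1 = classification_metrics(c)["F1"]
        scores.append(0.0 if f1 is None else f1)
    return float(np.mean(scores))


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney U) statistic,
    with half credit for ties."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def icc_absolute_agreement(a: np.ndarray, b: np.ndarray) -> float:
    """ICC(A,1): two-way, single-rater, absolute-agreement intraclass
    correlation between paired measurements."""
    import warnings

    import pandas as pd
    import pingouin as pg

    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if np.array_equal(a, b):
        return 1.0
    n = len(a)
    df = pd.DataFrame({
        "subject": np.tile(np.arange(n), 2),
        "rater": np.repeat(["a", "b"], n),
        "score": np.concatenate([a, b]),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="score")
    row = res["Type"].isin(["ICC(A,1)", "ICC2"])
    return float(res.loc[row, "ICC"].iloc[0])


def regression_metrics(ahi_true: np.ndarray, ahi_pred: np.ndarray,
                       ) -> dict[str, float]:
    """R² (1 - SSE/SST against the mean of the true values), MAE with the SD
    of the absolute errors, and ICC(A,1)."""
    t = np.asarray(ahi_true, dtype=np.float64)
    p = np.asarray(ahi_pred, dtype=np.float64)
    if len(t) < 2:
        raise ValueError("need at least two subjects")
    sst = float(np.sum((t - t.mean()) ** 2))
    if sst == 0:
        raise ValueError("true AHI values have zero variance; R² undefined")
    sse = float(np.sum((t - p) ** 2))
    ae = np.abs(t - p)
    return {
        "R2": 1.0 - sse / sst,
        "MAE": float(ae.mean()),
        "MAE_SD": float(ae.std(ddof=1)),
        "ICC": icc_absolute_agreement(t, p),
    }


def bland_altman(ahi_true: np.ndarray, ahi_pred: np.ndarray) -> dict[str, float]:
    """Mean difference and 95% limits of agreement (mean ± 1.96 SD)."""
    t = np.asarray(ahi_true, dtype=np.float64)
    p = np.asarray(ahi_pred, dtype=np.float64)
    if len(t) < 2:
        raise ValueError("need at least two pairs")
    d = p - t
    sd = float(d.std(ddof=1))
    return {"mean_diff": float(d.mean()),
            "loa_low": float(d.mean() - 1.96 * sd),
            "loa_high": float(d.mean() + 1.96 * sd)}
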