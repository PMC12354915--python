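"""Overnight aggregation: probability sequences, AHI regression (Model 2),
the SARI risk index and AASM severity grading.

The per-epoch (p_normal, p_event) pairs from the event model are Fourier-
resampled to a fixed [2, 1024] sequence (1024 x 30 s ≈ 8.53 h), which a small
convolutional regressor maps to a predicted AHI. SARI — the mean respiratory
event probability over the standardized sequence — summarises both frequency
and duration of events in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import resample

from . import nn
from .nn import Tensor

__all__ = [
    "SEQUENCE_LEN",
    "NightProbability",
    "SubjectAssessment",
    "build_probability_sequence",
    "compute_sari",
    "classify_severity",
    "SEVERITY_GRADES",
    "AhiRegressor",
    "AhiTrainConfig",
    "fit_ahi_model",
    "predict_ahi",
    "train_predict_ahi",
]

SEQUENCE_LEN = 1024
SEVERITY_GRADES = ("healthy", "mild", "moderate", "severe")
# AASM cutoffs, boundary inclusive upward: <5, [5,15), [15,30), >=30
SEVERITY_CUTOFFS = (5.0, 15.0, 30.0)


@dataclass
class NightProbability:
    """Chronological per-epoch probability pairs and their standardized form."""

    raw: np.ndarray                       # [n_epochs, 2] (p_normal, p_event)
    source: str = "single-channel"
    resampled: np.ndarray = field(init=False)   # [2, 1024]

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=np.float64)
        if self.raw.ndim != 2 or self.raw.shape[1] != 2:
            raise ValueError("raw must be [n_epochs, 2]")
        if not np.allclose(self.raw.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")
        self.resampled = build_probability_sequence(self.raw)


def build_probability_sequence(raw: np.ndarray) -> np.ndarray:
    """Fourier-resample both probability tracks to length 1024, then clip
    to [0, 1]. Requires at least two epochs."""
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 2 or raw.shape[1] != 2 or raw.shape[0] < 2:
        raise ValueError(f"need an [n>=2, 2] probability array, got {raw.shape}")
    seq = resample(raw, SEQUENCE_LEN, axis=0).T        # [2, 1024]
    return np.clip(seq, 0.0, 1.0)


def compute_sari(seq: NightProbability | np.ndarray) -> float:
    """SA risk index: mean event probability over the standardized sequence."""
    arr = seq.resampled if isinstance(seq, NightProbability) else np.asarray(seq)
    if arr.shape[0] != 2:
        raise ValueError("expected a [2, L] probability sequence")
    return float(arr[1].mean())


def classify_severity(ahi: float) -> str:
    """AASM grade; boundary values belong to the higher grade."""
    if ahi < 0 or not np.isfinite(ahi):
        raise ValueError(f"AHI must be a non-negative number, got {ahi}")
    for grade, cut in zip(SEVERITY_GRADES, SEVERITY_CUTOFFS):
        if ahi < cut:
            return grade
    return SEVERITY_GRADES[-1]


@dataclass
class SubjectAssessment:
    """Per-subject overnight result."""

    ahi_pred: float
    sari: float
    severity: str
    ahi_true: float | None = None

    def __post_init__(self):
        if self.ahi_pred < 0:
            raise ValueError("predicted AHI must be >= 0")
        if classify_severity(self.ahi_pred) != self.severity:
            raise ValueError("severity inconsistent with predicted AHI")


# ---------------------------------------------------------------------------
# Model 2: AHI regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AhiTrainConfig:
    max_epochs: int = 100
    patience: int = 15
    batch: int = 512
    lr: float = 1e-3
    weight_decay: float = 0.0
    val_fraction: float = 0.2
    seed: int = 0


class AhiRegressor(nn.Module):
    """Three 1-D convolutions with decreasing kernels (5 -> 3 -> 1), widths
    16/32/64, stride-2 max pooling between, then two fully connected layers
    to a scalar AHI."""

    def __init__(self, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.c1 = nn.Conv1d(rng, 2, 16, 5, padding=2)
        self.c2 = nn.Conv1d(rng, 16, 32, 3, padding=1)
        self.c3 = nn.Conv1d(rng, 32, 64, 1)
        self.f1 = nn.Linear(rng, 64 * (SEQUENCE_LEN // 8), 64)
        self.f2 = nn.Linear(rng, 64, 1)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != 2 or x.shape[2] != SEQUENCE_LEN:
            raise ValueError(f"expected [B, 2, {SEQUENCE_LEN}], got {tuple(x.shape)}")
        h = nn.maxpool1d(nn.gelu(self.c1(x)))
        h = nn.maxpool1d(nn.gelu(self.c2(h)))
        h = nn.maxpool1d(nn.gelu(self.c3(h)))
        h = h.reshape(h.shape[0], -1)
        return self.f2(nn.gelu(self.f1(h))).reshape(h.shape[0])


def fit_ahi_model(sequences: np.ndarray, ahi_true: np.ndarray,
                  config: AhiTrainConfig = AhiTrainConfig(),
                  ) -> tuple[AhiRegressor, dict[str, list[float]]]:
    """Train Model 2 with MSE loss, AdamW (lr 1e-3), early stopping."""
    x = np.asarray(sequences, dtype=np.float64)
    y = np.asarray(ahi_true, dtype=np.float64)
    if len(x) < 10:
        raise ValueError("need at least 10 subjects to fit the AHI model")
    if np.ptp(y) == 0:
        raise ValueError("all AHI targets identical; regression undefined")

    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(y))
    n_val = max(1, int(round(config.val_fraction * len(y))))
    vi, ti = perm[:n_val], perm[n_val:]
    model = AhiRegressor(seed=int(rng.integers(2 ** 31)))
    opt = nn.AdamW(model.parameters(), lr=config.lr,
                   weight_decay=config.weight_decay)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best = np.inf
    best_state = None
    since = 0
    for epoch in range(config.max_epochs):
        model.train()
        order = rng.permutation(len(ti))
        tl = 0.0
        for i0 in range(0, len(order), config.batch):
            sel = ti[order[i0:i0 + config.batch]]
            pred = model(Tensor(x[sel]))
            loss = ((pred - Tensor(y[sel])).power(2)).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            tl += float(loss.data) * len(sel)
        model.eval()
        pv = predict_ahi(model, x[vi], batch=config.batch)
        vl = float(np.mean((pv - y[vi]) ** 2))
        history["train_loss"].append(tl / len(ti))
        history["val_loss"].append(vl)
        if vl < best - 1e-9:
            best, best_state, since = vl, model.state_dict(), 0
        else:
            since += 1
            if since >= config.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


def predict_ahi(model: AhiRegressor, sequences: np.ndarray,
                batch: int = 512) -> np.ndarray:
    """Predicted AHI, clamped to be non-negative."""
    x = np.asarray(sequences, dtype=np.float64)
    model.eval()
    out = np.empty(len(x))
    with nn.no_grad():
        for i0 in range(0, len(x), batch):
            out[i0:i0 + batch] = model(Tensor(x[i0:i0 + batch])).data
    return np.maximum(out, 0.0)


def train_predict_ahi(sequences: np.ndarray, ahi_true: np.ndarray,
                      config: AhiTrainConfig = AhiTrainConfig(),
                      ) -> np.ndarray:
    """Fit on the given nights and return their predictions (callers wanting
    held-out estimates should split, or use :func:`fit_ahi_model` directly)."""
    model, _ = fit_ahi_model(sequences, ahi_true, config)
    return predict_ahi(model, sequences)
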