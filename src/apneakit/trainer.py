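"""Training of the per-channel event model (Model 1).

A TSD-Net is trained per channel on labeled 30-s epochs with focal loss
(down-weighting the abundant normal class), light Gaussian augmentation of
the z-scored inputs, AdamW with cosine learning-rate annealing, and early
stopping on validation loss. Trained models emit per-epoch
(p_normal, p_event) pairs that form the overnight probability sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn
from .io import EpochSet
from .nn import Tensor
from .tsdnet import TSDNet, TSDNetConfig, tsdnet_reduced

__all__ = [
    "TrainConfig",
    "focal_loss",
    "augment_gaussian",
    "train_event_model",
    "predict_night",
    "predict_epoch_probs",
    "TrainedEventModel",
]

PROB_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings for the event model."""

    max_epochs: int = 100
    patience: int = 15
    batch: int = 512
    weight_decay: float = 0.05
    lr_max: float = 1e-4
    lr_min: float = 1e-5
    focal_gamma: float = 2.0
    focal_alpha_pos: float = 0.25     # positive-class weight; 1-alpha for negatives
    sigma_range: tuple[float, float] = (0.005, 0.01)
    val_fraction: float = 0.2
    grad_clip: float | None = 1.0     # global-norm clip; None disables
    seed: int = 0

    def __post_init__(self):
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if not (0 <= self.sigma_range[0] <= self.sigma_range[1] <= 0.05):
            raise ValueError("sigma_range must lie within [0, 0.05]")


def focal_loss(p, y, alpha_pos: float = 0.25, gamma: float = 2.0):
    """Focal loss ``-alpha_t (1 - p_t)^gamma log(p_t)`` averaged over a batch.

    ``p`` is the predicted event probability, ``y`` the binary label;
    ``p_t`` is ``p`` for events and ``1 - p`` for normals, clamped away from
    {0, 1} by 1e-7. ``alpha_t`` is ``alpha_pos`` for events and
    ``1 - alpha_pos`` for normals. With ``gamma = 0`` and ``alpha = 1`` the
    loss reduces to cross-entropy.

    Accepts numpy arrays (returns a float) or autograd Tensors (returns a
    scalar Tensor).
    """
    was_array = not isinstance(p, Tensor)
    pt_in = Tensor(np.asarray(p, dtype=np.float64)) if was_array else p
    yv = np.asarray(y.data if isinstance(y, Tensor) else y, dtype=np.float64)
    alpha_t = alpha_pos * yv + (1.0 - alpha_pos) * (1.0 - yv)
    p_t = pt_in * yv + (1.0 - pt_in) * (1.0 - yv)
    p_t = p_t.clamp(PROB_EPS, 1.0 - PROB_EPS)
    loss = ((1.0 - p_t).power(gamma) * p_t.log() * Tensor(-alpha_t)).mean()
    return float(loss.data) if was_array else loss


def augment_gaussian(x: np.ndarray, sigma_range: tuple[float, float],
                     rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian noise with a per-sample SD drawn uniformly from
    ``sigma_range``; intended for z-scored training copies only."""
    lo, hi = sigma_range
    sigma = rng.uniform(lo, hi, size=(len(x),) + (1,) * (x.ndim - 1))
    return x + rng.standard_normal(x.shape) * sigma


@dataclass
class TrainedEventModel:
    model: TSDNet
    channel: str
    history: dict[str, list[float]]
    best_epoch: int


def _epoch_matrix(es: EpochSet, channel: str) -> np.ndarray:
    if channel not in es.data:
        raise KeyError(f"channel {channel!r} not in epoch set {es.channel_types}")
    return es.data[channel][:, None, :]        # [n, 1, 256]


def _gather(epoch_sets: Sequence[EpochSet], channel: str,
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xs, ys, subj = [], [], []
    for i, es in enumerate(epoch_sets):
        xs.append(_epoch_matrix(es, channel))
        ys.append(np.asarray(es.labels, dtype=np.float64))
        subj.append(np.full(es.n_epochs, i))
    return np.concatenate(xs), np.concatenate(ys), np.concatenate(subj)


def train_event_model(epoch_sets: EpochSet | Sequence[EpochSet], channel: str,
                      config: TrainConfig = TrainConfig(),
                      model_config: TSDNetConfig | None = None,
                      ) -> TrainedEventModel:
    """Train a TSD-Net on one channel.

    When several epoch sets (recordings/subjects) are given, the validation
    split is subject-stratified: whole recordings go to one side, so no
    subject leaks across the split. A single epoch set is split at the epoch
    level.
    """
    if isinstance(epoch_sets, EpochSet):
        epoch_sets = [epoch_sets]
    x, y, subj = _gather(epoch_sets, channel)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")

    rng = np.random.default_rng(config.seed)
    if len(epoch_sets) > 1:
        subjects = rng.permutation(len(epoch_sets))
        n_val = max(1, int(round(config.val_fraction * len(epoch_sets))))
        val_subj = set(subjects[:n_val].tolist())
        val_idx = np.isin(subj, list(val_subj))
    else:
        perm = rng.permutation(len(y))
        n_val = max(1, int(round(config.val_fraction * len(y))))
        val_idx = np.zeros(len(y), dtype=bool)
        val_idx[perm[:n_val]] = True
    xt, yt = x[~val_idx], y[~val_idx]
    xv, yv = x[val_idx], y[val_idx]
    if len(np.unique(yt)) < 2:
        raise ValueError("training split contains a single class")

    model = TSDNet(model_config or tsdnet_reduced(),
                   seed=int(rng.integers(2 ** 31)))
    opt = nn.AdamW(model.parameters(), lr=config.lr_max,
                   weight_decay=config.weight_decay)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    best_state: dict | None = None
    best_epoch = -1
    since_best = 0

    for epoch in range(config.max_epochs):
        opt.lr = nn.cosine_lr(epoch, config.max_epochs, config.lr_max, config.lr_min)
        model.train()
        order = rng.permutation(len(yt))
        tl = 0.0
        for i0 in range(0, len(order), config.batch):
            sel = order[i0:i0 + config.batch]
            xb = augment_gaussian(xt[sel], config.sigma_range, rng)
            p = model(Tensor(xb))
            loss = focal_loss(p, yt[sel], config.focal_alpha_pos,
                              config.focal_gamma)
            opt.zero_grad()
            loss.backward()
            if config.grad_clip is not None:
                nn.clip_grad_norm(model.parameters(), config.grad_clip)
            opt.step()
            tl += float(loss.data) * len(sel)
        model.eval()
        pv = predict_epoch_probs(model, xv, batch=config.batch)
        vl = focal_loss(pv, yv, config.focal_alpha_pos, config.focal_gamma)
        history["train_loss"].append(tl / len(yt))
        history["val_loss"].append(vl)
        history["lr"].append(opt.lr)
        if vl < best_val - 1e-7:
            best_val = vl
            best_state = model.state_dict()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return TrainedEventModel(model=model, channel=channel, history=history,
                             best_epoch=best_epoch)


def predict_epoch_probs(model: TSDNet, x: np.ndarray, batch: int = 512) -> np.ndarray:
    """Event probabilities for [n, 1, 256] (or [n, 256]) epochs, batched."""
    if x.ndim == 2:
        x = x[:, None, :]
    model.eval()
    out = np.empty(len(x))
    with nn.no_grad():
        for i0 in range(0, len(x), batch):
            out[i0:i0 + batch] = model(Tensor(x[i0:i0 + batch])).data
    return out


def predict_night(trained: TrainedEventModel | TSDNet, epochs: EpochSet,
                  channel: str | None = None, batch: int = 512) -> np.ndarray:
    """Per-epoch (p_normal, p_event) pairs in chronological order.

    Rows sum to one by construction; epochs must be ordered by their start
    time (they are, as produced by :func:`apneakit.io.make_epochs`).
    """
    if isinstance(trained, TrainedEventModel):
        model = trained.model
        channel = channel or trained.channel
    else:
        model = trained
        if channel is None:
            raise ValueError("channel required when passing a bare model")
    if np.any(np.diff(epochs.epoch_start_s) < 0):
        raise ValueError("epochs must be ordered by epoch_start_s")
    p_event = predict_epoch_probs(model, _epoch_matrix(epochs, channel), batch)
    return np.column_stack([1.0 - p_event, p_event])
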