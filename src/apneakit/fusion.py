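"""Three-channel ("Gold") feature fusion.

Each per-channel TSD-Net acts as a frozen feature extractor: its stage-4
feature map [B, C4, 8] is averaged over channels to 8 pooled features per
epoch. The three channels' features are concatenated in the fixed order
(Flow, Chest, SpO2) into a 24-wide matrix and classified by a gradient
boosted decision-tree ensemble (LightGBM) with the pinned settings:
31 max leaves, learning rate 0.05, 0.9 feature subsampling, 100 rounds,
binary cross-entropy objective.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .io import EpochSet
from .nn import Tensor
from .tsdnet import TSDNet, extract_stage4_features
from .trainer import TrainedEventModel

__all__ = [
    "CHANNEL_ORDER",
    "FusionFeatures",
    "build_fusion_features",
    "fit_fusion",
    "fusion_predict",
    "fusion_train_predict",
]

CHANNEL_ORDER = ("Flow", "Chest", "SpO2")
FEATURES_PER_CHANNEL = 8


class FusionFeatures:
    """[n_epochs, 24] pooled-feature matrix with aligned labels.

    Column ``8*c + j`` is pooled feature ``j`` of channel ``CHANNEL_ORDER[c]``.
    """

    def __init__(self, matrix: np.ndarray, labels: np.ndarray):
        matrix = np.asarray(matrix)
        if matrix.ndim != 2 or matrix.shape[1] != FEATURES_PER_CHANNEL * len(CHANNEL_ORDER):
            raise ValueError(f"fusion features must be [n, 24], got {matrix.shape}")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("fusion features must be finite")
        self.matrix = matrix
        self.labels = np.asarray(labels)

    @property
    def column_names(self) -> list[str]:
        return [f"{ch}_f{j}" for ch in CHANNEL_ORDER
                for j in range(FEATURES_PER_CHANNEL)]


def _stage4(model: TSDNet, x: np.ndarray, batch: int = 512) -> np.ndarray:
    from . import nn

    model.eval()
    feats = []
    with nn.no_grad():
        for i0 in range(0, len(x), batch):
            _, _, s4 = model.forward_full(Tensor(x[i0:i0 + batch]))
            feats.append(extract_stage4_features(s4))
    return np.concatenate(feats)


def build_fusion_features(models: Mapping[str, TrainedEventModel | TSDNet],
                          epochs: EpochSet, batch: int = 512) -> FusionFeatures:
    """Pooled stage-4 features of all three channels, concatenated per epoch."""
    missing = [ch for ch in CHANNEL_ORDER
               if ch not in models or ch not in epochs.data]
    if missing:
        raise KeyError(
            f"fusion needs channels {CHANNEL_ORDER}; missing {missing}, "
            f"available epochs: {epochs.channel_types}, "
            f"models: {sorted(models)}")
    cols = []
    for ch in CHANNEL_ORDER:
        m = models[ch]
        net = m.model if isinstance(m, TrainedEventModel) else m
        cols.append(_stage4(net, epochs.data[ch][:, None, :], batch))
    return FusionFeatures(np.hstack(cols), np.asarray(epochs.labels))


def fit_fusion(features: FusionFeatures, seed: int = 0):
    """Train the boosted-tree fusion classifier on labeled features."""
    import lightgbm as lgb

    y = features.labels
    if len(np.unique(y)) < 2:
        raise ValueError("fusion training requires both classes")
    clf = lgb.LGBMClassifier(
        objective="binary",
        num_leaves=31,
        learning_rate=0.05,
        feature_fraction=0.9,
        n_estimators=100,
        random_state=seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbosity=-1,
    )
    clf.fit(features.matrix, y)
    return clf


def fusion_predict(clf, features: FusionFeatures) -> np.ndarray:
    """Per-epoch (p_normal, p_event), rows summing to one."""
    p_event = clf.predict_proba(features.matrix)[:, 1]
    return np.column_stack([1.0 - p_event, p_event])


def fusion_train_predict(features: FusionFeatures, seed: int = 0) -> np.ndarray:
    """Fit on the given features and return their (p_normal, p_event).

    In-pipeline use fits on training epochs and predicts held-out nights via
    :func:`fit_fusion` / :func:`fusion_predict`; this convenience form scores
    the training matrix itself.
    """
    return fusion_predict(fit_fusion(features, seed), features)
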