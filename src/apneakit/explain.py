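"""Transparent scale diffusion: per-stage attention rendered as heatmaps on
the 256-sample epoch grid, and IoU scoring against event annotations.

For convolutional-attention stages, the retained modulation branch M
([B, C, L]) is reduced over channels by its mean magnitude — M is signed,
and modulation strength lives in |M|; a signed mean lets opposite-sign
channels cancel. For self-attention stages, the attention *received* by
each token (column mean of the row-stochastic matrices, averaged over
heads) is used. The per-position track is linearly projected to 256
samples and min-max normalised per epoch; a degenerate (constant) map is
defined as all-zero heat.
"""

from __future__ import annotations

import numpy as np

from .io import CONTEXT_S, EPOCH_SAMPLES
from .simulate import RespiratoryEvent
from .tsdnet import AttentionStack

__all__ = [
    "scale_diffusion_map",
    "attention_iou",
    "epoch_event_mask",
]


def _project(track: np.ndarray, out_len: int, mode: str = "linear") -> np.ndarray:
    """Project [B, L] tracks to [B, out_len] (sample-center aligned)."""
    b, l = track.shape
    src = (np.arange(l) + 0.5) / l
    dst = (np.arange(out_len) + 0.5) / out_len
    if mode == "nearest":
        idx = np.clip(np.round(dst * l - 0.5).astype(int), 0, l - 1)
        return track[:, idx]
    return np.stack([np.interp(dst, src, row) for row in track])


def scale_diffusion_map(attn: AttentionStack, stage: int,
                        mode: str = "linear") -> np.ndarray:
    """Heat [B, 256] in [0, 1] for one stage (1-4) of an attention stack."""
    if not 1 <= stage <= 4:
        raise ValueError("stage must be in 1..4")
    m = attn.maps[stage - 1]
    kind = attn.kinds[stage - 1]
    if kind == "msca":
        track = np.abs(m).mean(axis=1)                # [B, L] mean magnitude
    else:
        track = m.mean(axis=2).mean(axis=1)           # column mean, head mean
    heat = _project(track, EPOCH_SAMPLES, mode)
    lo = heat.min(axis=1, keepdims=True)
    hi = heat.max(axis=1, keepdims=True)
    span = hi - lo
    flat = (span <= 1e-12).ravel()
    span = np.where(span <= 1e-12, 1.0, span)
    out = (heat - lo) / span
    out[flat] = 0.0
    return out


def attention_iou(heat: np.ndarray, event_mask: np.ndarray,
                  threshold: float = 0.5) -> float:
    """IoU between the thresholded high-confidence region {heat >= threshold}
    and a binary event mask on the same grid.

    Both sets empty -> 1.0; exactly one empty -> 0.0.
    """
    heat = np.asarray(heat, dtype=np.float64)
    mask = np.asarray(event_mask).astype(bool)
    if heat.shape != mask.shape:
        raise ValueError("heat and mask must share a shape")
    region = heat >= threshold
    inter = np.sum(region & mask)
    union = np.sum(region | mask)
    if union == 0:
        return 1.0
    return float(inter / union)


def epoch_event_mask(events: list[RespiratoryEvent], epoch_start_s: float,
                     n: int = EPOCH_SAMPLES) -> np.ndarray:
    """Binary mask on the n-sample context grid of an epoch: sample i covers
    time epoch_start - 120 s + (i + 0.5) * 270/n and is set when that time
    falls inside any annotated event."""
    t0 = epoch_start_s - (CONTEXT_S - 30.0) / 2.0
    times = t0 + (np.arange(n) + 0.5) * (CONTEXT_S / n)
    mask = np.zeros(n, dtype=bool)
    for e in events:
        mask |= (times >= e.onset_s) & (times < e.end_s)
    return mask
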