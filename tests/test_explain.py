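"""Scale-diffusion heatmaps and IoU scoring."""

import numpy as np
import pytest

from apneakit.explain import attention_iou, epoch_event_mask, scale_diffusion_map
from apneakit.simulate import RespiratoryEvent
from apneakit.tsdnet import AttentionStack


def _stack(stage4_map, kind="mhsa"):
    maps = [np.zeros((1, 4, 64)), np.zeros((1, 8, 32)), np.zeros((1, 16, 16)),
            stage4_map]
    return AttentionStack(maps=maps, kinds=["msca", "msca", "msca", kind])


def test_constant_attention_defined_as_zero_heat():
    stack = _stack(np.full((1, 2, 8, 8), 0.125))
    heat = scale_diffusion_map(stack, 4)
    np.testing.assert_array_equal(heat, np.zeros((1, 256)))


def test_single_spike_projects_to_matching_neighbourhood():
    m = np.zeros((1, 16, 8))       # msca map, stage-4 length 8
    m[0, :, 3] = 1.0
    stack = AttentionStack(maps=[np.zeros((1, 4, 64)), np.zeros((1, 8, 32)),
                                 np.zeros((1, 16, 16)), m],
                           kinds=["msca", "msca", "msca", "msca"])
    heat = scale_diffusion_map(stack, 4)
    # position 3 of 8 covers samples [96, 128) of 256
    assert heat[0, 96:128].max() == 1.0
    assert heat[0, 96:128].mean() > heat[0, :64].mean()


def test_heat_range_length_and_affine_invariance():
    rng = np.random.default_rng(0)
    m = rng.uniform(size=(3, 16, 16))
    stack = AttentionStack(maps=[None, None, m, None],
                           kinds=["msca", "msca", "msca", "mhsa"])
    heat = scale_diffusion_map(stack, 3)
    assert heat.shape == (3, 256)
    assert heat.min() >= 0.0 and heat.max() <= 1.0
    stack2 = AttentionStack(maps=[None, None, 5.0 * m + 2.0, None],
                            kinds=stack.kinds)
    np.testing.assert_allclose(scale_diffusion_map(stack2, 3), heat,
                               atol=1e-6)


def test_mhsa_reduction_uses_attention_received_per_token():
    attn = np.zeros((1, 2, 4, 4))
    attn[:, :, :, 2] = 1.0          # all tokens attend to position 2
    stack = _stack(attn)
    heat = scale_diffusion_map(stack, 4)
    # position 2 of 4 covers samples [128, 192)
    assert heat[0, 128:192].max() == 1.0
    assert heat[0, :96].max() == 0.0


def test_invalid_stage_rejected():
    with pytest.raises(ValueError):
        scale_diffusion_map(_stack(np.zeros((1, 2, 8, 8))), 5)


# ---------------------------------------------------------------------------
# IoU
# ---------------------------------------------------------------------------

def test_iou_identical_disjoint_and_arithmetic_cases():
    a = np.zeros(256)
    a[:128] = 1.0
    mask = np.zeros(256, dtype=bool)
    mask[:128] = True
    assert attention_iou(a, mask) == 1.0
    disjoint = np.zeros(256, dtype=bool)
    disjoint[128:] = True
    assert attention_iou(a, disjoint) == 0.0
    # A = 128 samples, mask = 128 samples, overlap 64 -> 64/192
    shifted = np.zeros(256, dtype=bool)
    shifted[64:192] = True
    assert attention_iou(a, shifted) == pytest.approx(64 / 192)


def test_iou_empty_set_conventions():
    empty_heat = np.zeros(256)
    empty_mask = np.zeros(256, dtype=bool)
    assert attention_iou(empty_heat, empty_mask) == 1.0
    full_mask = np.ones(256, dtype=bool)
    assert attention_iou(empty_heat, full_mask) == 0.0
    assert attention_iou(np.ones(256), empty_mask) == 0.0


def test_trained_stage3_heat_beats_permuted_baseline(trained_event_bundle):
    """On a trained model, stage-3 heat localises events better than a
    randomly permuted copy of itself (paired one-sided test, p < 0.01).

    The baseline IoU for each epoch is averaged over ten permutations so the
    comparison measures placement quality, not permutation noise.
    """
    from scipy.stats import ttest_rel

    from apneakit import nn
    from apneakit.nn import Tensor

    rec, es, p_event = trained_event_bundle["holdout"]
    trained = trained_event_bundle["trained"]
    pos = np.flatnonzero(es.labels == 1)
    rng = np.random.default_rng(0)
    ious, ious_perm = [], []
    for i0 in range(0, len(pos), 128):
        sel = pos[i0:i0 + 128]
        with nn.no_grad():
            _, stack, _ = trained.model.forward_full(
                Tensor(es.data["SpO2"][sel][:, None, :]))
        heat = scale_diffusion_map(stack, 3)
        for row, k in enumerate(sel):
            mask = epoch_event_mask(rec.events, es.epoch_start_s[k])
            ious.append(attention_iou(heat[row], mask))
            ious_perm.append(np.mean([
                attention_iou(rng.permutation(heat[row]), mask)
                for _ in range(10)]))
    ious = np.asarray(ious)
    ious_perm = np.asarray(ious_perm)
    assert ious.mean() > ious_perm.mean()
    assert ttest_rel(ious, ious_perm, alternative="greater").pvalue < 0.01


def test_epoch_event_mask_marks_context_samples():
    events = [RespiratoryEvent("apnea", 600.0, 30.0)]
    mask = epoch_event_mask(events, epoch_start_s=600.0)
    # context is [480, 750); the event [600, 630) occupies samples
    # ((600-480)/270)*256 .. ((630-480)/270)*256 ~ [114, 142)
    on = np.flatnonzero(mask)
    assert on.min() == pytest.approx(114, abs=1)
    assert on.max() == pytest.approx(141, abs=1)
    assert epoch_event_mask([], 0.0).sum() == 0
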