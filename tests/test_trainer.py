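"""Focal loss, augmentation and event-model training behaviour."""

import numpy as np
import pytest

import apneakit as ak
from apneakit.nn import Tensor
from apneakit.trainer import (TrainConfig, augment_gaussian, focal_loss,
                              predict_night, train_event_model)
from apneakit.tsdnet import TSDNetConfig

TINY = TSDNetConfig(stage_dims=(8, 16, 32, 64), stage3_blocks=(1, 1),
                    variant="tiny")


# ---------------------------------------------------------------------------
# Focal loss
# ---------------------------------------------------------------------------

def test_focal_loss_vanishes_for_perfect_predictions():
    assert focal_loss(np.array([1 - 1e-9]), np.array([1.0]),
                      alpha_pos=1.0) == pytest.approx(0.0, abs=1e-10)
    assert focal_loss(np.array([1e-9]), np.array([0.0]),
                      alpha_pos=0.0) == pytest.approx(0.0, abs=1e-10)


def test_focal_loss_gamma_zero_reduces_to_cross_entropy():
    rng = np.random.default_rng(0)
    p = rng.uniform(0.05, 0.95, 50)
    y = rng.integers(0, 2, 50).astype(float)
    fl = focal_loss(p, y, alpha_pos=1.0, gamma=0.0)
    # alpha_pos=1 puts weight 1 on positives and 0 on negatives, so compare
    # against the alpha-weighted cross-entropy under the same convention
    pt = np.where(y == 1, p, 1 - p)
    at = np.where(y == 1, 1.0, 0.0)
    # engine computes in single precision
    assert fl == pytest.approx(np.mean(-at * np.log(pt)), rel=1e-6)


def test_focal_loss_closed_form_value_at_09():
    # p_t = 0.9, gamma = 2, alpha_t = 1: (1-0.9)^2 * (-ln 0.9) = 1.0536e-3
    got = focal_loss(np.array([0.9]), np.array([1.0]), alpha_pos=1.0, gamma=2.0)
    assert got == pytest.approx(1.0536e-3, rel=1e-3)


def test_focal_loss_nonnegative_and_monotone_in_pt():
    p = np.linspace(0.01, 0.99, 99)
    losses = [focal_loss(np.array([v]), np.array([1.0])) for v in p]
    assert all(l >= 0 for l in losses)
    assert all(a > b for a, b in zip(losses, losses[1:]))


def test_focal_gradient_downweights_easy_examples():
    """At p_t = 0.99 the focal (gamma=2) gradient is < 1% of cross-entropy's."""
    def grad(gamma):
        p = Tensor(np.array([0.99]), requires_grad=True)
        focal_loss(p, np.array([1.0]), alpha_pos=1.0, gamma=gamma).backward()
        return abs(p.grad[0])

    assert grad(2.0) < 0.01 * grad(0.0)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def test_augment_zero_sigma_is_identity():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(10, 1, 256))
    np.testing.assert_array_equal(augment_gaussian(x, (0.0, 0.0), rng), x)


def test_augment_noise_sd_within_configured_envelope():
    rng = np.random.default_rng(2)
    x = np.zeros((400, 256))
    noise = augment_gaussian(x, (0.005, 0.01), rng) - x
    per_sample_sd = noise.std(axis=1)
    assert per_sample_sd.min() > 0.004 and per_sample_sd.max() < 0.011
    overall = noise.std()
    assert 0.005 <= overall <= 0.01


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(max_epochs=10, patience=10)
    with pytest.raises(ValueError):
        TrainConfig(sigma_range=(0.0, 0.2))


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _separable_epochset(n=160, seed=0):
    """Toy epochs where the class mean differs strongly; trivially learnable."""
    rng = np.random.default_rng(seed)
    y = np.tile([0, 1], n // 2)
    x = rng.normal(0, 1, size=(n, 256)).astype(np.float32)
    x[y == 1] += 3.0
    return ak.EpochSet(data={"SpO2": x}, labels=y.astype(np.int8),
                       epoch_start_s=np.arange(n) * 30.0,
                       channel_types=("SpO2",))


def test_training_loss_decreases_on_separable_data():
    es = _separable_epochset()
    tc = TrainConfig(max_epochs=5, patience=4, batch=64, lr_max=1e-3,
                     lr_min=1e-4, seed=0)
    tm = train_event_model(es, "SpO2", tc, TINY)
    tl = tm.history["train_loss"]
    assert tl[-1] < tl[0]
    assert len(tm.history["val_loss"]) == len(tl)


def test_early_stopping_on_unlearnable_labels():
    rng = np.random.default_rng(3)
    es = _separable_epochset(n=120, seed=3)
    es.labels = rng.integers(0, 2, 120).astype(np.int8)   # pure noise
    tc = TrainConfig(max_epochs=40, patience=3, batch=64, lr_max=1e-5,
                     lr_min=1e-6, seed=0)
    tm = train_event_model(es, "SpO2", tc, TINY)
    assert len(tm.history["val_loss"]) < 40


def test_single_class_data_rejected():
    es = _separable_epochset(n=64)
    es.labels[:] = 1
    with pytest.raises(ValueError, match="single class"):
        train_event_model(es, "SpO2", TrainConfig(max_epochs=2, patience=1),
                          TINY)


def test_subject_stratified_split_keeps_recordings_whole():
    sets = [_separable_epochset(n=40, seed=s) for s in range(5)]
    tc = TrainConfig(max_epochs=2, patience=1, batch=64, seed=1)
    tm = train_event_model(sets, "SpO2", tc, TINY)
    assert tm.best_epoch >= 0      # trained and validated without error


def test_predict_night_probability_pairs(sim_epochs_small):
    es = sim_epochs_small
    from apneakit.tsdnet import TSDNet

    net = TSDNet(TINY, seed=4)
    raw = predict_night(net, es, channel="SpO2")
    assert raw.shape == (es.n_epochs, 2)
    np.testing.assert_allclose(raw.sum(axis=1), 1.0, atol=1e-9)


@pytest.fixture(scope="module")
def sim_epochs_small():
    rec = ak.simulate_recording(ak.SimConfig(duration_h=0.5, target_ahi=20.0,
                                             sleep_fraction=1.0, seed=8))
    return ak.make_epochs(rec)
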