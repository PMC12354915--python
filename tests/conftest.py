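"""Shared fixtures.

The expensive fixtures (trained event models and a scored cohort of
simulated nights) are session-scoped and shared by the acceptance tests;
unit tests use only small, fast objects.

Problem sizes are chosen so the whole suite runs on one CPU well inside half
an hour: ~3,000 training epochs from four overnight recordings for the event
model, and 60 nights spanning AHI 0-60 for the overnight studies.
"""

from __future__ import annotations

import numpy as np
import pytest

import apneakit as ak
from apneakit.trainer import predict_epoch_probs

TRAIN_NIGHT_AHIS = (8, 16, 24, 32, 40, 48, 56)
TRAIN_NIGHT_HOURS = 5.0
HOLDOUT_NIGHT_HOURS = 6.5
N_COHORT_NIGHTS = 60
COHORT_NIGHT_HOURS = 4.5

# scaled-down optimisation recipe for the width-reduced model (see
# docs/methods.md): cosine 3e-3 -> 3e-4, 12 epochs
STUDY_TRAIN = dict(max_epochs=12, patience=11, lr_max=3e-3, lr_min=3e-4)


def _night(ahi: float, seed: int, hours: float):
    cfg = ak.SimConfig(duration_h=hours, target_ahi=ahi, sleep_fraction=0.97,
                       seed=seed)
    rec = ak.simulate_recording(cfg)
    return rec, ak.make_epochs(rec, qc=ak.quality_control(rec))


@pytest.fixture(scope="session")
def sim_recording():
    """A clean 8-h recording with a moderate event load."""
    cfg = ak.SimConfig(duration_h=8.0, target_ahi=30.0, sleep_fraction=1.0,
                       seed=7)
    return ak.simulate_recording(cfg)


@pytest.fixture(scope="session")
def sim_epochs(sim_recording):
    qc = ak.quality_control(sim_recording)
    return ak.make_epochs(sim_recording, qc=qc)


@pytest.fixture(scope="session")
def train_sets():
    """Seven overnight recordings with clear events (~4,000 epochs)."""
    return [_night(a, 200 + i, TRAIN_NIGHT_HOURS)[1]
            for i, a in enumerate(TRAIN_NIGHT_AHIS)]


@pytest.fixture(scope="session")
def trained_event_bundle(train_sets):
    """Width-reduced TSD-Net trained on the SpO2 channel, plus a held-out
    night scored with it."""
    tc = ak.TrainConfig(seed=0, **STUDY_TRAIN)
    trained = ak.train_event_model(train_sets, "SpO2", tc)
    rec, es = _night(30.0, 999, HOLDOUT_NIGHT_HOURS)
    p_event = predict_epoch_probs(trained.model, es.data["SpO2"])
    return {"trained": trained, "train_sets": train_sets,
            "holdout": (rec, es, p_event)}


@pytest.fixture(scope="session")
def channel_models(train_sets, trained_event_bundle):
    """Per-channel event models for the Gold fusion pathway, trained with
    the same schedule as the SpO2 model."""
    models = {"SpO2": trained_event_bundle["trained"]}
    for ch, seed in (("Flow", 1), ("Chest", 2)):
        tc = ak.TrainConfig(seed=seed, **STUDY_TRAIN)
        models[ch] = ak.train_event_model(train_sets, ch, tc)
    return models


@pytest.fixture(scope="session")
def night_cohort(trained_event_bundle):
    """60 simulated nights spanning AHI 0-60, scored with the trained event
    model: probability sequences, SARI and true AHI per night."""
    trained = trained_event_bundle["trained"]
    seqs, saris, ahis = [], [], []
    for i in range(N_COHORT_NIGHTS):
        target = float(i) / (N_COHORT_NIGHTS - 1) * 60.0
        rec, es = _night(target, 3000 + i, COHORT_NIGHT_HOURS)
        raw = ak.predict_night(trained, es)
        night = ak.NightProbability(raw, source="SpO2")
        seqs.append(night.resampled)
        saris.append(ak.compute_sari(night))
        ahis.append(ak.true_ahi(rec))
    return {"sequences": np.stack(seqs), "saris": np.asarray(saris),
            "true_ahi": np.asarray(ahis)}
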