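"""Synthetic overnight polysomnography generator.

Produces annotated multichannel recordings (nasal airflow ``Flow``, thoracic
effort ``Chest``, oximetry ``SpO2``) with the event semantics used for scoring
sleep apnea: an apnea is a ≥90% reduction of the Flow envelope, a hypopnea a
30-89% reduction, both lasting ≥10 s and accompanied by a ≥3% oxygen
desaturation. The generator is the test bed for every downstream stage —
quality control, epoching, event detection, AHI regression — so its contract
is statistical structure, not physiological realism: quasi-sinusoidal
breathing at a configurable respiratory frequency, envelope drops for events,
lagged desaturation dips with exponential recovery, optional SpO2 dropout
artifacts and flat-line pads for QC testing.

Everything is driven by a single integer seed; identical configurations give
bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "SimConfig",
    "RespiratoryEvent",
    "Recording",
    "simulate_recording",
    "true_ahi",
    "AhiInfeasibleError",
]

EPOCH_S = 30.0
MIN_EVENT_GAP_S = 5.0
SPO2_RECOVERY_TAU_S = 15.0
APNEA_RESIDUAL = (0.0, 0.10)      # surviving envelope fraction during apnea
HYPOPNEA_RESIDUAL = (0.11, 0.70)  # 30-89% reduction


class AhiInfeasibleError(ValueError):
    """Requested AHI cannot be placed inside the available sleep time."""


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults describe a realistic clinical overnight
    recording with a moderate event load."""

    duration_h: float = 8.0
    target_ahi: float = 15.0
    sleep_fraction: float = 0.95
    event_dur_s: tuple[float, float] = (10.0, 40.0)
    hypopnea_fraction: float = 0.5
    resp_freq_hz: float = 0.27
    desat_depth_pct: tuple[float, float] = (3.0, 10.0)
    desat_lag_s: float = 10.0
    artifact_rate: float = 0.0          # SpO2 dropout segments per hour
    flatline_pad_s: float = 0.0
    noise_sd: float = 0.05
    rates_hz: Mapping[str, float] = field(
        default_factory=lambda: {"Flow": 10.0, "Chest": 10.0, "SpO2": 1.0})
    seed: int = 0

    def __post_init__(self):
        if self.duration_h <= 0:
            raise ValueError("duration_h must be positive")
        if self.target_ahi < 0:
            raise ValueError("target_ahi must be >= 0")
        if not 0 < self.sleep_fraction <= 1:
            raise ValueError("sleep_fraction must be in (0, 1]")
        if self.event_dur_s[0] < 10:
            raise ValueError("event durations must be >= 10 s")
        if self.event_dur_s[1] < self.event_dur_s[0]:
            raise ValueError("event_dur_s must be (min, max)")
        if not 0 <= self.hypopnea_fraction <= 1:
            raise ValueError("hypopnea_fraction must be in [0, 1]")
        if not 0.2 <= self.resp_freq_hz <= 0.33:
            raise ValueError("resp_freq_hz outside the 0.2-0.33 Hz sleep range")
        if self.desat_depth_pct[0] < 3:
            raise ValueError("desaturation depth must be >= 3%")
        if self.desat_lag_s < 0 or self.artifact_rate < 0 or self.noise_sd < 0:
            raise ValueError("desat_lag_s, artifact_rate, noise_sd must be >= 0")
        if self.flatline_pad_s < 0:
            raise ValueError("flatline_pad_s must be >= 0")
        for name, r in self.rates_hz.items():
            if r <= 0:
                raise ValueError(f"rate for {name} must be positive")


@dataclass(frozen=True)
class RespiratoryEvent:
    type: str            # "apnea" | "hypopnea"
    onset_s: float
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class Recording:
    """An overnight recording: per-channel signals at native rates, scored
    respiratory events, a per-30-s sleep mask and generator metadata."""

    channels: dict[str, tuple[np.ndarray, float]]
    events: list[RespiratoryEvent]
    sleep_mask: np.ndarray               # bool per 30-s epoch
    true_ahi: float | None = None
    subject_meta: dict = field(default_factory=dict)
    aux: dict = field(default_factory=dict)   # debug arrays (not serialised)

    @property
    def duration_s(self) -> float:
        name, (sig, rate) = next(iter(self.channels.items()))
        return len(sig) / rate

    def sleep_seconds(self) -> float:
        return float(self.sleep_mask.sum() * EPOCH_S)


def true_ahi(rec: Recording) -> float:
    """Events per hour of sleep, from the recording's own annotations."""
    sleep_h = rec.sleep_seconds() / 3600.0
    if sleep_h <= 0:
        raise ValueError("recording has no sleep time; AHI undefined")
    return len(rec.events) / sleep_h


# ---------------------------------------------------------------------------
# Event placement
# ---------------------------------------------------------------------------

def _sleep_regions(mask: np.ndarray) -> list[tuple[float, float]]:
    """Contiguous sleep runs as (start_s, end_s)."""
    regions = []
    start = None
    for i, asleep in enumerate(mask):
        if asleep and start is None:
            start = i
        elif not asleep and start is not None:
            regions.append((start * EPOCH_S, i * EPOCH_S))
            start = None
    if start is not None:
        regions.append((start * EPOCH_S, len(mask) * EPOCH_S))
    return regions


def _place_events(rng: np.random.Generator, cfg: SimConfig,
                  mask: np.ndarray) -> list[RespiratoryEvent]:
    sleep_s = mask.sum() * EPOCH_S
    sleep_h = sleep_s / 3600.0
    n = int(round(cfg.target_ahi * sleep_h))
    if n == 0:
        return []
    dmin, dmax = cfg.event_dur_s
    max_n = int(sleep_s // (dmin + MIN_EVENT_GAP_S))
    if n > max_n:
        raise AhiInfeasibleError(
            f"target AHI {cfg.target_ahi:g} needs {n} events but at most "
            f"{max_n} fit in {sleep_h:.2f} h of sleep; maximum feasible AHI "
            f"is {max_n / sleep_h:.1f}")

    regions = _sleep_regions(mask)
    lengths = np.array([e - s for s, e in regions])
    # events per region, proportional to length, capped by feasibility
    counts = np.zeros(len(regions), dtype=int)
    order = np.argsort(-lengths)
    remaining = n
    quota = (lengths / lengths.sum() * n)
    for i in order:
        counts[i] = min(int(round(quota[i])),
                        int(lengths[i] // (dmin + MIN_EVENT_GAP_S)), remaining)
        remaining -= counts[i]
    while remaining > 0:   # distribute leftovers to regions with headroom
        placed = False
        for i in order:
            cap = int(lengths[i] // (dmin + MIN_EVENT_GAP_S))
            if counts[i] < cap and remaining > 0:
                counts[i] += 1
                remaining -= 1
                placed = True
        if not placed:  # pragma: no cover - guarded by max_n above
            raise AhiInfeasibleError("event placement overflow")

    events: list[RespiratoryEvent] = []
    for (rs, re_), k in zip(regions, counts):
        if k == 0:
            continue
        span = re_ - rs
        for _ in range(200):  # redraw durations if the draw cannot fit
            durs = rng.uniform(dmin, dmax, size=k)
            slack = span - durs.sum() - k * MIN_EVENT_GAP_S
            if slack >= 0:
                break
            durs = None
        if durs is None:
            durs = np.full(k, dmin)
            slack = span - durs.sum() - k * MIN_EVENT_GAP_S
        # uniform placement with guaranteed >= MIN_EVENT_GAP_S spacing:
        # onset_j = region_start + cut_j + sum of earlier durations + j gaps
        cuts = np.sort(rng.uniform(0.0, slack, size=k))
        prior = np.concatenate([[0.0], np.cumsum(durs[:-1])])
        onsets = rs + cuts + prior + np.arange(k) * MIN_EVENT_GAP_S
        for onset, dur in zip(onsets, durs):
            events.append(RespiratoryEvent("", float(onset), float(dur)))

    events.sort(key=lambda e: e.onset_s)
    n_hyp = int(round(cfg.hypopnea_fraction * len(events)))
    kinds = np.array(["hypopnea"] * n_hyp + ["apnea"] * (len(events) - n_hyp))
    rng.shuffle(kinds)
    return [RespiratoryEvent(k, e.onset_s, e.duration_s)
            for k, e in zip(kinds, events)]


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _respiratory_channel(rng: np.random.Generator, cfg: SimConfig, rate: float,
                         total_s: float, events: list[RespiratoryEvent],
                         residuals: np.ndarray, amplitude: float,
                         ) -> tuple[np.ndarray, np.ndarray]:
    n = int(round(total_s * rate))
    t = np.arange(n) / rate
    envelope = np.full(n, amplitude)
    for ev, res in zip(events, residuals):
        i0, i1 = int(ev.onset_s * rate), int(ev.end_s * rate)
        envelope[i0:i1] = amplitude * res
    phase = rng.uniform(0, 2 * np.pi)
    sig = envelope * np.sin(2 * np.pi * cfg.resp_freq_hz * t + phase)
    sig += rng.normal(0, cfg.noise_sd, size=n)
    return sig.astype(np.float32), envelope.astype(np.float32)


def _spo2_channel(rng: np.random.Generator, cfg: SimConfig, rate: float,
                  total_s: float, events: list[RespiratoryEvent],
                  ) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float]]]:
    n = int(round(total_s * rate))
    t = np.arange(n) / rate
    baseline = rng.uniform(95.0, 98.0)
    # physiological baseline wander: slow oscillations (~30 min and ~7 min
    # components) present on every night; this is the variance floor that
    # makes whole-night z-scoring meaningful even for event-free records
    wander = (0.4 * np.sin(2 * np.pi * t / 1800.0 + rng.uniform(0, 2 * np.pi))
              + 0.25 * np.sin(2 * np.pi * t / 420.0 + rng.uniform(0, 2 * np.pi)))
    baseline_trace = baseline + wander
    dip = np.zeros(n)
    depths = rng.uniform(*cfg.desat_depth_pct, size=len(events))
    lag = max(cfg.desat_lag_s, 1.0 / rate)
    for ev, depth in zip(events, depths):
        nadir_t = ev.onset_s + lag
        shape = np.zeros(n)
        rise = (t >= ev.onset_s) & (t < nadir_t)
        shape[rise] = depth * (t[rise] - ev.onset_s) / lag
        fall = t >= nadir_t
        # hold the nadir until the event ends, then recover exponentially
        hold_end = max(nadir_t, ev.end_s)
        held = fall & (t < hold_end)
        shape[held] = depth
        rec = t >= hold_end
        shape[rec] = depth * np.exp(-(t[rec] - hold_end) / SPO2_RECOVERY_TAU_S)
        np.maximum(dip, shape, out=dip)
    sig = baseline_trace - dip + rng.normal(0, 0.1, size=n)

    artifacts: list[tuple[float, float]] = []
    n_art = rng.poisson(cfg.artifact_rate * total_s / 3600.0)
    for _ in range(n_art):
        dur = rng.uniform(2.0, 10.0)
        onset = rng.uniform(0.0, max(total_s - dur, 0.0))
        i0, i1 = int(onset * rate), max(int((onset + dur) * rate), int(onset * rate) + 1)
        sig[i0:i1] = rng.uniform(30.0, 50.0, size=i1 - i0)
        artifacts.append((float(onset), float(dur)))
    return (np.clip(sig, 20.0, 100.0).astype(np.float32),
            (baseline_trace - dip).astype(np.float32), artifacts)


def _sleep_mask(rng: np.random.Generator, cfg: SimConfig, n_epochs: int) -> np.ndarray:
    """One contiguous sleep block; wake split between the record edges."""
    n_sleep = int(round(cfg.sleep_fraction * n_epochs))
    n_sleep = max(min(n_sleep, n_epochs), 1)
    lead = int(rng.integers(0, n_epochs - n_sleep + 1))
    mask = np.zeros(n_epochs, dtype=bool)
    mask[lead:lead + n_sleep] = True
    return mask


def simulate_recording(config: SimConfig) -> Recording:
    """Generate one annotated overnight recording.

    Deterministic for a fixed config (including seed). Raises
    :class:`AhiInfeasibleError` if the requested AHI cannot be scheduled
    without overlapping events.
    """
    rng = np.random.default_rng(config.seed)
    total_s = config.duration_h * 3600.0
    n_epochs = int(total_s // EPOCH_S)
    mask = _sleep_mask(rng, config, n_epochs)
    events = _place_events(rng, config, mask)

    residuals = np.array([
        rng.uniform(*(APNEA_RESIDUAL if e.type == "apnea" else HYPOPNEA_RESIDUAL))
        for e in events])

    channels: dict[str, tuple[np.ndarray, float]] = {}
    aux: dict = {}
    flow_rate = float(config.rates_hz.get("Flow", 10.0))
    chest_rate = float(config.rates_hz.get("Chest", flow_rate))
    spo2_rate = float(config.rates_hz.get("SpO2", 1.0))

    flow, flow_env = _respiratory_channel(rng, config, flow_rate, total_s,
                                          events, residuals, amplitude=1.0)
    chest, chest_env = _respiratory_channel(rng, config, chest_rate, total_s,
                                            events, residuals, amplitude=0.8)
    spo2, spo2_clean, artifacts = _spo2_channel(rng, config, spo2_rate,
                                                total_s, events)

    pad = config.flatline_pad_s
    if pad > 0:
        for sig, rate in ((flow, flow_rate), (chest, chest_rate)):
            k = int(pad * rate)
            sig[:k] = 0.0
            sig[len(sig) - k:] = 0.0

    channels["Flow"] = (flow, flow_rate)
    channels["Chest"] = (chest, chest_rate)
    channels["SpO2"] = (spo2, spo2_rate)
    aux["flow_envelope"] = flow_env
    aux["chest_envelope"] = chest_env
    aux["spo2_clean"] = spo2_clean

    sleep_h = mask.sum() * EPOCH_S / 3600.0
    rec = Recording(
        channels=channels,
        events=events,
        sleep_mask=mask,
        true_ahi=len(events) / sleep_h,
        subject_meta={
            "generator": "apneakit.simulate",
            "seed": config.seed,
            "target_ahi": config.target_ahi,
            "spo2_artifacts": artifacts,
            "flatline_pad_s": pad,
            "baseline_envelope": 1.0,
        },
        aux=aux,
    )
    return rec
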