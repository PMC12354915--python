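"""Reading, writing and preparing overnight recordings.

Covers the full ingestion path: EDF signal files (a compact reader/writer for
standard 16-bit EDF with 1-s data records), event annotations in either a
Profusion-style XML dialect or a plain ``type,onset_s,duration_s`` CSV,
signal quality control (flat-line and oximetry-artifact exclusion, 4-h valid
sleep rule) and conversion of a recording into fixed-length labeled epochs:
30-s central windows with 120 s of context on both sides, Fourier-resampled
to 256 samples and z-scored per channel.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import resample

from .simulate import EPOCH_S, Recording, RespiratoryEvent

__all__ = [
    "AnnotationSet",
    "QCReport",
    "EpochSet",
    "MissingChannelError",
    "write_edf",
    "read_edf",
    "write_annotations_csv",
    "read_annotations",
    "save_recording",
    "load_recording",
    "read_recording",
    "quality_control",
    "make_epochs",
    "CONTEXT_S",
    "EPOCH_SAMPLES",
    "CHANNEL_ALIASES",
]

CONTEXT_S = 270.0          # 30-s target window plus 120 s on each side
EPOCH_SAMPLES = 256        # fixed post-resampling epoch length
FLATLINE_SD_THRESHOLD = 1e-4
MIN_VALID_SLEEP_H = 4.0

CHANNEL_ALIASES: dict[str, tuple[str, ...]] = {
    "Flow": ("flow", "new air", "airflow", "nasal", "cannula"),
    "Chest": ("chest", "thor", "effort", "abdo"),
    "SpO2": ("spo2", "sao2", "osat", "o2 sat", "oximetry"),
}


class MissingChannelError(KeyError):
    """A required channel could not be resolved in the source file."""

    def __init__(self, channel: str, available: list[str]):
        super().__init__(channel)
        self.channel = channel
        self.available = available

    def __str__(self) -> str:
        return (f"required channel {self.channel!r} not found; "
                f"available: {self.available}")


@dataclass
class AnnotationSet:
    events: list[RespiratoryEvent] = field(default_factory=list)
    stages: np.ndarray | None = None           # per-30-s integer stages
    artifacts: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self):
        for e in self.events:
            if e.onset_s < 0 or e.duration_s <= 0:
                raise ValueError(f"invalid event geometry: {e}")
        self.events = sorted(self.events, key=lambda e: e.onset_s)


@dataclass
class QCReport:
    excluded_intervals: list[tuple[str, float, float, str]]
    valid_sleep_h: float
    passed: bool
    missing_channels: list[str] = field(default_factory=list)


@dataclass
class EpochSet:
    """Fixed-length labeled context windows.

    ``data[ch]`` has shape [n_epochs, 256]; ``labels[i] = 1`` iff a
    respiratory event overlaps the i-th central 30-s window by at least the
    configured overlap.
    """

    data: dict[str, np.ndarray]
    labels: np.ndarray
    epoch_start_s: np.ndarray           # onset of each central 30-s window
    channel_types: tuple[str, ...]

    @property
    def n_epochs(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write channels to a standard EDF file (16-bit, 1-s data records).

    Channel tails are padded by repeating the final sample so every signal
    fills an integer number of records.
    """
    path = Path(path)
    names = list(rec.channels)
    n_records = int(math.ceil(max(len(s) / r for s, r in rec.channels.values())))
    spr = [int(round(r)) for _, r in rec.channels.values()]
    if any(abs(r - int(round(r))) > 1e-9 for _, r in rec.channels.values()):
        raise ValueError("EDF writer requires integer sampling rates")

    digmin, digmax = -32768, 32767
    phys: list[tuple[float, float]] = []
    digital: list[np.ndarray] = []
    for (sig, rate), k in zip(rec.channels.values(), spr):
        need = n_records * k
        if len(sig) < need:
            sig = np.concatenate([sig, np.repeat(sig[-1], need - len(sig))])
        lo, hi = float(np.min(sig)), float(np.max(sig))
        if hi - lo < 1e-6:
            hi = lo + 1.0
        span = hi - lo
        lo, hi = lo - 0.001 * span, hi + 0.001 * span
        lo, hi = round(lo, 4), round(hi, 4)
        d = np.round((sig - lo) / (hi - lo) * (digmax - digmin) + digmin)
        digital.append(d.astype("<i2"))
        phys.append((lo, hi))

    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad("X X X X", 80))
        f.write(_pad("Startdate X X X X", 80))
        f.write(_pad("01.01.00", 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(256 * (1 + len(names))), 8))
        f.write(_pad("", 44))
        f.write(_pad(str(n_records), 8))
        f.write(_pad("1", 8))
        f.write(_pad(str(len(names)), 4))
        for n in names:
            f.write(_pad(n, 16))
        for _ in names:
            f.write(_pad("", 80))
        for _ in names:
            f.write(_pad("", 8))
        for lo, hi in phys:
            f.write(_pad(f"{lo:.4f}"[:8], 8))
        for lo, hi in phys:
            f.write(_pad(f"{hi:.4f}"[:8], 8))
        for _ in names:
            f.write(_pad(str(digmin), 8))
        for _ in names:
            f.write(_pad(str(digmax), 8))
        for _ in names:
            f.write(_pad("", 80))
        for k in spr:
            f.write(_pad(str(k), 8))
        for _ in names:
            f.write(_pad("", 32))
        for r in range(n_records):
            for d, k in zip(digital, spr):
                f.write(d[r * k:(r + 1) * k].tobytes())


def read_edf(path: str | Path) -> dict[str, tuple[np.ndarray, float]]:
    """Read an EDF file into {channel: (samples, rate_hz)}."""
    with open(path, "rb") as f:
        head = f.read(256)
        n_records = int(head[236:244].decode().strip())
        rec_dur = float(head[244:252].decode().strip())
        ns = int(head[252:256].decode().strip())
        sub = f.read(256 * ns)

        def fields(offset: int, width: int) -> list[str]:
            base = offset * ns
            return [sub[base + i * width: base + (i + 1) * width].decode().strip()
                    for i in range(ns)]

        labels = fields(0, 16)
        pmin = [float(v) for v in fields(16 + 80 + 8, 8)]
        pmax = [float(v) for v in fields(16 + 80 + 16, 8)]
        dmin = [float(v) for v in fields(16 + 80 + 24, 8)]
        dmax = [float(v) for v in fields(16 + 80 + 32, 8)]
        spr = [int(v) for v in fields(16 + 80 + 40 + 80, 8)]
        raw = np.frombuffer(f.read(), dtype="<i2")

    per_rec = sum(spr)
    raw = raw[:n_records * per_rec].reshape(n_records, per_rec)
    out: dict[str, tuple[np.ndarray, float]] = {}
    col = 0
    for i, name in enumerate(labels):
        block = raw[:, col:col + spr[i]].reshape(-1).astype(np.float64)
        col += spr[i]
        scale = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        sig = (block - dmin[i]) * scale + pmin[i]
        out[name] = (sig.astype(np.float32), spr[i] / rec_dur)
    return out


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def write_annotations_csv(rec: Recording, path: str | Path) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["type", "onset_s", "duration_s"])
        for e in rec.events:
            w.writerow([e.type, f"{e.onset_s:.3f}", f"{e.duration_s:.3f}"])


def _classify_event_name(name: str) -> str | None:
    low = name.lower()
    if "hypopnea" in low:
        return "hypopnea"
    if "apnea" in low or "apnoea" in low:
        return "apnea"     # obstructive / central / mixed all map here
    return None


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read events from Profusion-style XML or the CSV dialect."""
    path = Path(path)
    if path.suffix.lower() == ".xml":
        return _read_annotations_xml(path)
    events: list[RespiratoryEvent] = []
    with open(path) as f:
        for row in csv.DictReader(f):
            events.append(RespiratoryEvent(row["type"].strip(),
                                           float(row["onset_s"]),
                                           float(row["duration_s"])))
    return AnnotationSet(events=events)


def _read_annotations_xml(path: Path) -> AnnotationSet:
    from lxml import etree

    tree = etree.parse(str(path))
    events: list[RespiratoryEvent] = []
    artifacts: list[tuple[str, float, float]] = []
    for ev in tree.iter("ScoredEvent"):
        name = ev.findtext("Name") or ev.findtext("EventConcept") or ""
        start = ev.findtext("Start")
        dur = ev.findtext("Duration")
        if start is None or dur is None:
            continue
        kind = _classify_event_name(name)
        if kind is not None:
            events.append(RespiratoryEvent(kind, float(start), float(dur)))
        elif "artifact" in name.lower():
            ch = "SpO2" if "spo2" in name.lower() or "sao2" in name.lower() else "any"
            artifacts.append((ch, float(start), float(dur)))
    stages_el = [int(s.text) for s in tree.iter("SleepStage") if s.text is not None]
    stages = np.array(stages_el) if stages_el else None
    return AnnotationSet(events=events, stages=stages, artifacts=artifacts)


# ---------------------------------------------------------------------------
# Recording round-trip (EDF + CSV + JSON sidecar)
# ---------------------------------------------------------------------------

def save_recording(rec: Recording, directory: str | Path, stem: str = "recording",
                   ) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "edf": directory / f"{stem}.edf",
        "annotations": directory / f"{stem}_events.csv",
        "sidecar": directory / f"{stem}.json",
    }
    write_edf(rec, paths["edf"])
    write_annotations_csv(rec, paths["annotations"])
    sidecar = {
        "true_ahi": rec.true_ahi,
        "sleep_mask": rec.sleep_mask.astype(int).tolist(),
        "subject_meta": {k: v for k, v in rec.subject_meta.items()
                         if isinstance(v, (int, float, str, list, tuple))},
    }
    paths["sidecar"].write_text(json.dumps(sidecar))
    return paths


def load_recording(directory: str | Path, stem: str = "recording") -> Recording:
    directory = Path(directory)
    channels = read_edf(directory / f"{stem}.edf")
    ann = read_annotations(directory / f"{stem}_events.csv")
    sidecar = json.loads((directory / f"{stem}.json").read_text())
    return Recording(
        channels=channels,
        events=ann.events,
        sleep_mask=np.array(sidecar["sleep_mask"], dtype=bool),
        true_ahi=sidecar.get("true_ahi"),
        subject_meta=sidecar.get("subject_meta", {}),
    )


def resolve_channels(raw: dict[str, tuple[np.ndarray, float]],
                     required: tuple[str, ...],
                     aliases: dict[str, tuple[str, ...]] | None = None,
                     ) -> dict[str, tuple[np.ndarray, float]]:
    """Map heterogeneous channel labels onto canonical names."""
    aliases = aliases or CHANNEL_ALIASES
    out: dict[str, tuple[np.ndarray, float]] = {}
    for canon in required:
        found = None
        for label in raw:
            low = label.lower()
            if low == canon.lower() or any(a in low for a in aliases.get(canon, ())):
                found = label
                break
        if found is None:
            raise MissingChannelError(canon, list(raw))
        out[canon] = raw[found]
    return out


def read_recording(edf_path: str | Path, annotation_path: str | Path | None = None,
                   required: tuple[str, ...] = ("Flow", "Chest", "SpO2"),
                   aliases: dict[str, tuple[str, ...]] | None = None,
                   ) -> tuple[Recording, AnnotationSet]:
    """Read an EDF recording and its annotations.

    Channels are resolved through configurable name aliases; a missing
    required channel raises :class:`MissingChannelError` (the record is to be
    excluded). Events are normalised to (type, onset_s, duration_s) with all
    apnea subtypes and hypopneas mapped to the positive class, sorted by
    onset.
    """
    raw = read_edf(edf_path)
    channels = resolve_channels(raw, required, aliases)
    ann = (read_annotations(annotation_path) if annotation_path is not None
           else AnnotationSet())
    name, (sig, rate) = next(iter(channels.items()))
    n_epochs = int(len(sig) / rate // EPOCH_S)
    if ann.stages is not None:
        mask = np.zeros(n_epochs, dtype=bool)
        k = min(n_epochs, len(ann.stages))
        mask[:k] = ann.stages[:k] > 0
    else:
        mask = np.ones(n_epochs, dtype=bool)
    rec = Recording(channels=channels, events=ann.events, sleep_mask=mask,
                    true_ahi=None, subject_meta={"source": str(edf_path)})
    return rec, ann


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def _merge_intervals(marks: np.ndarray, window_s: float) -> list[tuple[float, float]]:
    """Adjacent flagged windows -> (onset_s, duration_s) intervals."""
    out: list[tuple[float, float]] = []
    start = None
    for i, bad in enumerate(marks):
        if bad and start is None:
            start = i
        elif not bad and start is not None:
            out.append((start * window_s, (i - start) * window_s))
            start = None
    if start is not None:
        out.append((start * window_s, (len(marks) - start) * window_s))
    return out


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def quality_control(rec: Recording, window_s: float = 30.0,
                    sd_threshold: float = FLATLINE_SD_THRESHOLD,
                    required: tuple[str, ...] = ("Flow", "Chest", "SpO2"),
                    annotations: AnnotationSet | None = None) -> QCReport:
    """Flag flat-line windows and oximetry artifacts; apply the 4-h rule.

    Flat-line detection: any ``window_s`` window of a respiratory channel
    whose standard deviation falls below ``sd_threshold``. SpO2 artifacts:
    annotated intervals plus a physiological detector (values outside
    50-100% or jumps faster than 4%/s). ``passed`` requires all ``required``
    channels present and at least 4 h of sleep outside excluded intervals.
    """
    if not rec.channels:
        raise ValueError("recording has no channels")
    excluded: list[tuple[str, float, float, str]] = []
    missing = [ch for ch in required if ch not in rec.channels]

    for ch in ("Flow", "Chest"):
        if ch not in rec.channels:
            continue
        sig, rate = rec.channels[ch]
        w = int(window_s * rate)
        n_win = len(sig) // w
        if n_win == 0:
            continue
        sds = sig[:n_win * w].reshape(n_win, w).std(axis=1)
        for onset, dur in _merge_intervals(sds < sd_threshold, window_s):
            excluded.append((ch, onset, dur, "flatline"))

    if "SpO2" in rec.channels:
        sig, rate = rec.channels["SpO2"]
        bad = (sig < 50.0) | (sig > 100.0)
        jump = np.abs(np.diff(sig)) * rate > 4.0
        bad[1:] |= jump
        bad[:-1] |= jump
        for onset, dur in _merge_intervals(bad, 1.0 / rate):
            excluded.append(("SpO2", onset, dur, "spo2_artifact"))
        if annotations is not None:
            for ch, onset, dur in annotations.artifacts:
                excluded.append(("SpO2" if ch == "any" else ch, onset, dur,
                                 "spo2_artifact"))

    # valid sleep = sleep epochs minus any-channel exclusions
    valid_s = 0.0
    for k, asleep in enumerate(rec.sleep_mask):
        if not asleep:
            continue
        t0, t1 = k * EPOCH_S, (k + 1) * EPOCH_S
        cut = 0.0
        for _, onset, dur, _ in excluded:
            cut = max(cut, _overlap(t0, t1, onset, onset + dur))
        valid_s += EPOCH_S - cut
    valid_h = valid_s / 3600.0
    passed = valid_h >= MIN_VALID_SLEEP_H and not missing
    return QCReport(excluded_intervals=excluded, valid_sleep_h=valid_h,
                    passed=passed, missing_channels=missing)


# ---------------------------------------------------------------------------
# Epoch extraction
# ---------------------------------------------------------------------------

def _context_row(signal: np.ndarray, rate: float, start_s: float) -> np.ndarray:
    """Extract a 270-s context window, zero-padding past record edges, and
    Fourier-resample it to 256 samples."""
    n_ctx = int(round(CONTEXT_S * rate))
    i0 = int(round(start_s * rate))
    seg = np.zeros(n_ctx, dtype=np.float64)
    lo, hi = max(i0, 0), min(i0 + n_ctx, len(signal))
    if hi > lo:
        seg[lo - i0:hi - i0] = signal[lo:hi]
    if n_ctx == EPOCH_SAMPLES:
        return seg.astype(np.float32)
    return resample(seg, EPOCH_SAMPLES).astype(np.float32)


# SpO2 is a calibrated percentage whose night statistics are dominated by
# the event load: per-night z-scoring maps the same physiological signal to
# different amplitudes and offsets depending on how many desaturations the
# night happens to contain (an event-free night even has its sensor noise
# amplified to unit variance). SpO2 is therefore normalised physiologically:
# centred at the night's baseline saturation (95th percentile) and scaled by
# a fixed 2% saturation, so baseline sits at 0 and desaturations reach
# -1.5..-5 on every night alike. Flow/Chest are in arbitrary sensor units
# with no physical scale and keep the per-night z-score.
FIXED_SCALES = {"SpO2": 2.0}
BASELINE_QUANTILES = {"SpO2": 0.95}


def make_epochs(rec: Recording, ann: AnnotationSet | None = None,
                qc: QCReport | None = None,
                channels: tuple[str, ...] | None = None,
                label_overlap_s: float = 1.0,
                per_epoch_norm: bool = False,
                scale_overrides: dict[str, float] | None = None) -> EpochSet:
    """Tile non-overlapping 30-s central windows over sleep and build
    [n_epochs, 256] context arrays per channel.

    Each central window carries 120 s of context on both sides (zero-padded
    at record edges), is resampled to 256 points in the Fourier domain and
    z-scored with whole-night per-channel statistics computed after QC
    exclusions. Label 1 means a respiratory event overlaps the central
    window by at least ``label_overlap_s`` seconds. Epochs whose central
    window intersects an excluded interval are dropped.
    """
    if qc is not None and not qc.passed:
        raise ValueError("recording failed quality control")
    channels = channels or tuple(rec.channels)
    events = ann.events if ann is not None else rec.events
    dur_s = rec.duration_s
    if dur_s < CONTEXT_S:
        raise ValueError(
            f"record ({dur_s:.0f} s) shorter than one context window "
            f"({CONTEXT_S:.0f} s)")
    excluded = qc.excluded_intervals if qc is not None else []

    n_slots = int(dur_s // EPOCH_S)
    mask = rec.sleep_mask
    keep: list[int] = []
    for k in range(n_slots):
        if k < len(mask) and not mask[k]:
            continue
        t0, t1 = k * EPOCH_S, (k + 1) * EPOCH_S
        if any(_overlap(t0, t1, o, o + d) > 0 for _, o, d, _ in excluded):
            continue
        keep.append(k)

    norm: dict[str, tuple[float, float]] = {}
    normalized: dict[str, tuple[np.ndarray, float]] = {}
    for ch in channels:
        if ch not in rec.channels:
            raise MissingChannelError(ch, list(rec.channels))
        sig, rate = rec.channels[ch]
        ok = np.ones(len(sig), dtype=bool)
        for ech, o, d, _ in excluded:
            if ech == ch:
                ok[int(o * rate):int((o + d) * rate)] = False
        base = sig[ok] if ok.any() else sig
        if ch in BASELINE_QUANTILES:
            mu = float(np.quantile(base, BASELINE_QUANTILES[ch]))
        else:
            mu = float(np.mean(base))
        sd = float(np.std(base))
        scales = FIXED_SCALES if scale_overrides is None else scale_overrides
        sd = scales.get(ch, sd)
        sd = sd if sd > 1e-12 else 1.0
        norm[ch] = (mu, sd)
        normalized[ch] = (((sig - mu) / sd).astype(np.float64), rate)

    data = {ch: np.empty((len(keep), EPOCH_SAMPLES), dtype=np.float32)
            for ch in channels}
    labels = np.zeros(len(keep), dtype=np.int8)
    starts = np.empty(len(keep))
    for row, k in enumerate(keep):
        t0 = k * EPOCH_S
        starts[row] = t0
        for ch in channels:
            sig, rate = normalized[ch]
            r = _context_row(sig, rate, t0 - 120.0)
            if per_epoch_norm:
                sd = r.std()
                r = (r - r.mean()) / (sd if sd > 1e-12 else 1.0)
            data[ch][row] = r
        for e in events:
            if _overlap(t0, t0 + EPOCH_S, e.onset_s, e.end_s) >= label_overlap_s:
                labels[row] = 1
                break
    return EpochSet(data=data, labels=labels, epoch_start_s=starts,
                    channel_types=tuple(channels))
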