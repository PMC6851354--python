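"""Recording container, EDF input/output, montage, resampling, epoch selection.

Time convention used throughout the package: seconds from recording
start, half-open intervals ``[start, end)``, 0-based sample indices.
Signals are stored in µV.

EDF notes: recordings are written as plain 16-bit EDF with a 1-second
record duration (the recording is truncated to whole seconds at write
time; pipeline durations are whole seconds by construction).  Reading
goes through :func:`mne.io.read_raw_edf`.  Annotations travel in a CSV
sidecar with columns ``label,start_s,end_s`` where label is
``sleep_nrem`` or ``artifact``.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from ._intervals import merge_intervals, subtract_intervals, validate_interval

__all__ = [
    "Recording",
    "MontagePair",
    "EpochSet",
    "read_recording",
    "write_recording",
    "read_annotations_csv",
    "write_annotations_csv",
    "to_bipolar",
    "resample_to",
    "clean_epochs",
]

Annotation = tuple[str, float, float]  # (label, start_s, end_s)


class ChannelNotFoundError(KeyError):
    pass


class FormatError(ValueError):
    pass


@dataclass
class Recording:
    """Multichannel time series in µV with sleep/artifact annotations."""

    samples: np.ndarray  # (n_channels, n_samples)
    fs_hz: float
    channel_labels: list[str]
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.channel_labels = list(self.channel_labels)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be > 0")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("samples row count must match channel_labels")
        for label, s, e in self.annotations:
            validate_interval(s, e)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.samples[self.channel_labels.index(label)]
        except ValueError:
            raise ChannelNotFoundError(f"channel {label!r} not in recording") from None


@dataclass(frozen=True)
class MontagePair:
    """Bipolar derivation anode - cathode (e.g. C4-P4)."""

    anode: str
    cathode: str

    def __post_init__(self) -> None:
        if self.anode == self.cathode:
            raise ValueError("anode and cathode must differ")

    @property
    def label(self) -> str:
        return f"{self.anode}-{self.cathode}"


@dataclass
class EpochSet:
    """Clean analysis epochs (≤ epoch_len each) and their exact total minutes."""

    epochs: list[tuple[float, float]]
    clean_minutes: float


# ---------------------------------------------------------------------------
# EDF writing (minimal plain-EDF, 16-bit) and mne-based reading
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_recording(rec: Recording, path) -> None:
    """Write a recording as 16-bit EDF (1 s data records, physical unit µV).

    The physical range covers the per-channel signal extrema; the
    worst-case roundtrip error is one 16-bit quantization step.  Only
    whole seconds are written.  Annotations are NOT embedded — use
    :func:`write_annotations_csv` for the sidecar.
    """
    if rec.n_channels == 0 or rec.n_samples == 0:
        raise FormatError("cannot write an empty recording")
    if abs(rec.fs_hz - round(rec.fs_hz)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    fs = int(round(rec.fs_hz))
    n_records = rec.n_samples // fs
    if n_records == 0:
        raise FormatError("recording shorter than one 1-s EDF record")
    ns = rec.n_channels
    header_bytes = 256 * (1 + ns)

    phys_min, phys_max = [], []
    for ch in rec.samples:
        lo, hi = float(np.min(ch)), float(np.max(ch))
        if hi <= lo:
            lo, hi = lo - 1.0, lo + 1.0
        pad = 0.001 * (hi - lo)
        phys_min.append(lo - pad)
        phys_max.append(hi + pad)

    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field("X X X X", 80))            # patient id (anonymous)
        fh.write(_edf_field("Startdate X X X X", 80))  # recording id
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(str(header_bytes), 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(str(n_records), 8))
        fh.write(_edf_field("1", 8))                    # record duration (s)
        fh.write(_edf_field(str(ns), 4))
        for lab in rec.channel_labels:
            fh.write(_edf_field(lab, 16))
        for _ in range(ns):
            fh.write(_edf_field("", 80))                # transducer
        for _ in range(ns):
            fh.write(_edf_field("uV", 8))
        for v in phys_min:
            fh.write(_edf_field(f"{v:.8g}"[:8], 8))
        for v in phys_max:
            fh.write(_edf_field(f"{v:.8g}"[:8], 8))
        for _ in range(ns):
            fh.write(_edf_field("-32768", 8))
        for _ in range(ns):
            fh.write(_edf_field("32767", 8))
        for _ in range(ns):
            fh.write(_edf_field("", 80))                # prefiltering
        for _ in range(ns):
            fh.write(_edf_field(str(fs), 8))
        for _ in range(ns):
            fh.write(_edf_field("", 32))

        dmin, dmax = -32768, 32767
        gains = [(pmx - pmn) / (dmax - dmin) for pmn, pmx in zip(phys_min, phys_max)]
        for r in range(n_records):
            sl = slice(r * fs, (r + 1) * fs)
            for ci in range(ns):
                dig = np.round(
                    (rec.samples[ci, sl] - phys_min[ci]) / gains[ci] + dmin
                ).astype("<i2")
                fh.write(dig.tobytes())


def read_recording(path, channel_subset: list[str] | None = None) -> Recording:
    """Read an EDF file (via mne) into a :class:`Recording` in µV.

    Annotations embedded in an EDF+ file are imported when present; a
    CSV sidecar ``<path>.annotations.csv`` is read in addition if it
    exists.  Requesting a channel absent from the file raises
    :class:`ChannelNotFoundError` naming the label.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - malformed files
        raise FormatError(f"could not parse EDF file {path}: {exc}") from exc
    labels = list(raw.ch_names)
    if channel_subset is not None:
        missing = [c for c in channel_subset if c not in labels]
        if missing:
            raise ChannelNotFoundError(f"channel {missing[0]!r} not in {path.name}")
        raw.pick(channel_subset)
        labels = list(raw.ch_names)
    data = raw.get_data() * 1e6  # mne loads EEG in volts
    annotations: list[Annotation] = [
        (desc, float(on), float(on + dur))
        for desc, on, dur in zip(
            raw.annotations.description, raw.annotations.onset, raw.annotations.duration
        )
        if dur > 0
    ]
    sidecar = path.with_suffix(path.suffix + ".annotations.csv")
    if sidecar.exists():
        annotations.extend(read_annotations_csv(sidecar))
    return Recording(
        samples=data, fs_hz=float(raw.info["sfreq"]),
        channel_labels=labels, annotations=annotations,
    )


def write_annotations_csv(annotations: list[Annotation], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "start_s", "end_s"])
        for label, s, e in annotations:
            w.writerow([label, f"{s:.6f}", f"{e:.6f}"])


def read_annotations_csv(path) -> list[Annotation]:
    out: list[Annotation] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append((row["label"], float(row["start_s"]), float(row["end_s"])))
    return out


# ---------------------------------------------------------------------------
# Montage, resampling, epoch selection
# ---------------------------------------------------------------------------

def to_bipolar(rec: Recording, pairs: list[MontagePair]) -> Recording:
    """Bipolar montage: each output channel is anode - cathode, samplewise."""
    rows = []
    labels = []
    for p in pairs:
        rows.append(rec.channel(p.anode) - rec.channel(p.cathode))
        labels.append(p.label)
    return Recording(
        samples=np.array(rows), fs_hz=rec.fs_hz,
        channel_labels=labels, annotations=list(rec.annotations),
    )


def resample_to(rec: Recording, target_fs_hz: float) -> Recording:
    """Anti-aliased downsampling to ``target_fs_hz`` (e.g. 10 kHz → 2 kHz).

    A zero-phase FIR low-pass at 0.4·target_fs is applied before
    decimation, protecting the upper edge of the fast-ripple band.
    Upsampling is not supported.
    """
    if target_fs_hz > rec.fs_hz:
        raise ValueError("upsampling is not supported")
    if target_fs_hz == rec.fs_hz:
        return rec
    ratio = rec.fs_hz / target_fs_hz
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9:
        raise ValueError("target_fs_hz must divide fs_hz evenly")
    cutoff = 0.4 * target_fs_hz
    numtaps = 10 * q + 1
    fir = sps.firwin(numtaps, cutoff, fs=rec.fs_hz)
    filtered = sps.filtfilt(fir, [1.0], rec.samples, axis=1, padlen=3 * numtaps)
    return Recording(
        samples=filtered[:, ::q], fs_hz=target_fs_hz,
        channel_labels=list(rec.channel_labels), annotations=list(rec.annotations),
    )


def clean_epochs(rec: Recording, epoch_len_s: float = 300.0) -> EpochSet:
    """Clean NREM analysis epochs: sleep intervals minus artifact intervals.

    The remaining time is tiled into epochs of at most ``epoch_len_s``
    (5 min by default); a final partial epoch is retained with its true
    duration so rate denominators stay exact.  With no NREM annotation
    the epoch set is empty and a warning is emitted (recordings need
    NREM sleep to be analysable).
    """
    nrem = [(s, e) for (label, s, e) in rec.annotations if label == "sleep_nrem"]
    if not nrem:
        warnings.warn("recording has no NREM sleep annotation; no clean epochs")
        return EpochSet(epochs=[], clean_minutes=0.0)
    artifact = [(s, e) for (label, s, e) in rec.annotations if label == "artifact"]
    nrem = [(max(0.0, s), min(rec.duration_s, e)) for s, e in nrem if e > 0 and s < rec.duration_s]
    clean = subtract_intervals(merge_intervals(nrem), artifact) if artifact else merge_intervals(nrem)
    epochs: list[tuple[float, float]] = []
    for s, e in clean:
        cur = s
        while cur < e - 1e-12:
            epochs.append((cur, min(cur + epoch_len_s, e)))
            cur += epoch_len_s
    minutes = sum(e - s for s, e in epochs) / 60.0
    return EpochSet(epochs=epochs, clean_minutes=minutes)
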