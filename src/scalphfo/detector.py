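"""Three-stage automated HFO detector.

Stage 1 — candidate detection: the channel is band-pass filtered
(ripple 80–250 Hz or fast ripple 250–500 Hz), an amplitude threshold
Th_amp characterising the background is derived from the analytic-signal
envelope over oscillation-free baseline segments, and maximal
supra-threshold envelope runs lasting at least ``min_cycles``
oscillation cycles become candidates.

Stage 2 — time-frequency validation: the Stockwell (S-) transform of the
unfiltered signal around each candidate must show an isolated spectral
peak inside the band, separated from the low-frequency background by a
power trough.  Sharp transients (spikes, muscle bursts) have
monotonically decaying spectra and are rejected here — they produce
"false ripples" after filtering but carry no isolated oscillation.

Stage 3 — cross-channel rejection: events co-occurring on more than a
configurable fraction of channels are flagged as widespread artifacts.

Baseline identification uses the spectral entropy of Stockwell columns:
background (no oscillation) has a flat in-band spectrum and hence high
entropy; Th_amp is mean + k·SD of the envelope over those columns.
The concrete stage rules and all constants are this package's own
definitions, exposed in :class:`DetectorConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import signal as sps

from ._intervals import overlaps
from .io import EpochSet, Recording, clean_epochs

__all__ = [
    "Band",
    "RIPPLE",
    "FAST_RIPPLE",
    "DetectorConfig",
    "TimeFrequencyMap",
    "HfoEvent",
    "bandpass_filter",
    "stockwell_transform",
    "estimate_baseline_threshold",
    "detect_candidates",
    "validate_time_frequency",
    "reject_cross_channel",
    "detect",
]


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class Band:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not self.lo_hz < self.hi_hz:
            raise ValueError("band must satisfy lo < hi")


RIPPLE = Band("ripple", 80.0, 250.0)
FAST_RIPPLE = Band("fast_ripple", 250.0, 500.0)
BANDS = {b.name: b for b in (RIPPLE, FAST_RIPPLE)}


@dataclass
class DetectorConfig:
    """Tunable detector constants (package defaults, not published values).

    threshold_factor
        Th_amp = baseline envelope mean + this many baseline SDs.
    min_cycles
        Minimum event duration expressed in cycles of the event's
        dominant frequency.
    min_gap_ms
        Supra-threshold runs closer than this are merged before the
        duration test.
    tf_trough_ratio
        Required relative depth (0–1) of the spectral trough separating
        the in-band peak from lower-frequency power.
    cross_channel_fraction
        Events co-occurring on more than this fraction of channels are
        rejected as widespread artifacts.
    baseline_entropy_quantile
        Stockwell-column entropy quantile above which a column counts as
        oscillation-free baseline.
    """

    band: Band = field(default_factory=lambda: RIPPLE)
    threshold_factor: float = 3.0
    min_cycles: int = 4
    min_gap_ms: float = 10.0
    tf_trough_ratio: float = 0.5
    cross_channel_fraction: float = 0.8
    baseline_entropy_quantile: float = 0.5

    def __post_init__(self) -> None:
        if isinstance(self.band, str):
            self.band = BANDS[self.band]
        if self.threshold_factor <= 0:
            raise ValueError("threshold_factor must be > 0")
        if self.min_cycles < 1:
            raise ValueError("min_cycles must be >= 1")
        if not 0 < self.cross_channel_fraction <= 1:
            raise ValueError("cross_channel_fraction must be in (0, 1]")
        if not 0 <= self.baseline_entropy_quantile < 1:
            raise ValueError("baseline_entropy_quantile must be in [0, 1)")


@dataclass
class TimeFrequencyMap:
    power: np.ndarray  # (n_freqs, n_times), |S|^2
    freqs_hz: np.ndarray
    times_s: np.ndarray


Status = Literal["accepted", "rejected_tf", "rejected_cross_channel", "rejected_review"]


@dataclass
class HfoEvent:
    channel: str
    band: str
    start_s: float
    end_s: float
    peak_freq_hz: float
    peak_amp_uv: float
    status: Status = "accepted"
    review_note: str = ""

    @property
    def interval(self) -> tuple[float, float]:
        return (self.start_s, self.end_s)


# ---------------------------------------------------------------------------
# Stage primitives
# ---------------------------------------------------------------------------

def bandpass_filter(x: np.ndarray, band: Band, fs_hz: float) -> np.ndarray:
    """Zero-phase Butterworth band-pass for the HFO band.

    An order-4 Butterworth applied forward-backward keeps the passband
    flat (<1 dB ripple) while attenuating one octave outside the band by
    well over 40 dB.
    """
    if fs_hz <= 2 * band.hi_hz:
        raise ValueError("sampling rate must exceed twice the band's upper edge")
    sos = sps.butter(4, [band.lo_hz, band.hi_hz], btype="bandpass", fs=fs_hz, output="sos")
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x
    return sps.sosfiltfilt(sos, x, axis=-1)


def envelope(x: np.ndarray) -> np.ndarray:
    """Analytic-signal (Hilbert) amplitude envelope."""
    return np.abs(sps.hilbert(np.asarray(x, dtype=float)))


def _stockwell_bins(n: int, fs_hz: float, fmin_hz: float, fmax_hz: float,
                    step_bins: int = 1) -> np.ndarray:
    k_lo = max(1, int(np.ceil(fmin_hz * n / fs_hz)))
    k_hi = int(np.floor(fmax_hz * n / fs_hz))
    if k_hi < k_lo:
        raise ValueError("frequency range contains no FFT bins for this segment length")
    return np.arange(k_lo, k_hi + 1, step_bins)


def stockwell_transform(
    segment: np.ndarray,
    fs_hz: float,
    fmin_hz: float,
    fmax_hz: float,
    freq_step_bins: int = 1,
) -> TimeFrequencyMap:
    """Discrete Stockwell transform of a 1-D segment.

    For frequency bin k the S-transform voice is the inverse FFT of the
    shifted spectrum X[m+k] multiplied by the Gaussian localisation
    window G(m) = exp(-2π²m²/k²) — i.e. a Fourier-domain Gaussian of
    standard deviation k/(2π) bins, so the time window scales inversely
    with frequency.  Returned power is the squared magnitude.
    """
    x = np.asarray(segment, dtype=float)
    n = x.size
    if n < 64:
        raise ValueError("segment must contain at least 64 samples")
    if fmax_hz > fs_hz / 2:
        raise ValueError("fmax above Nyquist")
    ks = _stockwell_bins(n, fs_hz, fmin_hz, fmax_hz, freq_step_bins)
    X = np.fft.fft(x)
    m = np.fft.fftfreq(n, d=1.0 / n)  # signed integer frequencies
    S = np.empty((ks.size, n), dtype=complex)
    for i, k in enumerate(ks):
        gauss = np.exp(-2.0 * np.pi**2 * m**2 / float(k) ** 2)
        S[i] = np.fft.ifft(np.roll(X, -int(k)) * gauss)
    return TimeFrequencyMap(
        power=np.abs(S) ** 2,
        freqs_hz=ks * fs_hz / n,
        times_s=np.arange(n) / fs_hz,
    )


def _column_entropy(power: np.ndarray) -> np.ndarray:
    """Spectral (Shannon) entropy of each time column of a TF power map."""
    tot = power.sum(axis=0)
    tot[tot == 0] = 1.0
    p = power / tot
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=0)
    return h


_CHUNK = 4096        # samples per Stockwell chunk for baseline analysis
_COL_STRIDE = 16     # entropy evaluated every this many samples


def estimate_baseline_threshold(
    band_signal: np.ndarray, fs_hz: float, config: DetectorConfig
) -> float:
    """Background-adaptive amplitude threshold Th_amp (µV).

    The epoch's band-limited signal is scanned in ~2 s chunks; Stockwell
    column entropy is evaluated on a coarse grid, and samples whose
    column entropy exceeds the ``baseline_entropy_quantile`` of the
    epoch's entropies count as oscillation-free baseline.  Th_amp is the
    baseline envelope mean plus ``threshold_factor`` baseline SDs.
    """
    x = np.asarray(band_signal, dtype=float)
    if x.size < 10 * fs_hz:
        raise InsufficientDataError("baseline estimation needs at least 10 s of signal")
    band = config.band
    step_bins = max(1, int(round((band.hi_hz - band.lo_hz) / 16.0 * _CHUNK / fs_hz)))
    n_chunks = x.size // _CHUNK
    ent = np.empty((n_chunks, _CHUNK // _COL_STRIDE))
    for c in range(n_chunks):
        tf = stockwell_transform(
            x[c * _CHUNK:(c + 1) * _CHUNK], fs_hz, band.lo_hz, band.hi_hz,
            freq_step_bins=step_bins,
        )
        ent[c] = _column_entropy(tf.power[:, ::_COL_STRIDE])
    ent = ent.ravel()
    cut = np.quantile(ent, config.baseline_entropy_quantile)
    mask_coarse = ent >= cut
    mask = np.repeat(mask_coarse, _COL_STRIDE)
    env = envelope(x[: n_chunks * _CHUNK])
    base = env[mask]
    th = float(base.mean() + config.threshold_factor * base.std())
    if th <= 0:
        raise InsufficientDataError("degenerate baseline (zero signal?)")
    return th


def _dominant_freq(seg: np.ndarray, fs_hz: float, band: Band) -> float:
    """FFT-argmax dominant frequency of a short band-limited segment."""
    n = max(256, int(2 ** np.ceil(np.log2(max(seg.size, 2)))))
    spec = np.abs(np.fft.rfft(seg * np.hanning(seg.size), n=n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    sel = (freqs >= band.lo_hz) & (freqs <= band.hi_hz)
    if not sel.any():
        return band.lo_hz
    return float(freqs[sel][np.argmax(spec[sel])])


def detect_candidates(
    band_signal: np.ndarray,
    fs_hz: float,
    th_amp: float,
    config: DetectorConfig,
) -> list[tuple[float, float]]:
    """Stage-1 candidates: supra-threshold envelope runs of sufficient length.

    Maximal runs with envelope > Th_amp are merged when separated by less
    than ``min_gap_ms`` and kept when they last at least ``min_cycles``
    cycles of the run's dominant frequency.
    """
    if th_amp <= 0:
        raise ValueError("th_amp must be > 0")
    x = np.asarray(band_signal, dtype=float)
    env = envelope(x)
    above = env > th_amp
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    # merge runs separated by less than min_gap_ms
    gap = int(round(config.min_gap_ms * 1e-3 * fs_hz))
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([int(s), int(e)])
    out: list[tuple[float, float]] = []
    for s, e in merged:
        dom = _dominant_freq(x[s:e], fs_hz, config.band)
        if (e - s) / fs_hz >= config.min_cycles / dom:
            out.append((s / fs_hz, e / fs_hz))
    return out


def validate_time_frequency(
    candidate: tuple[float, float],
    tf_map: TimeFrequencyMap,
    config: DetectorConfig,
) -> tuple[Status, float]:
    """Stage-2 validation: isolated spectral peak inside the band.

    The time-averaged Stockwell power over the candidate interval must
    peak inside the band, and the power trough between the
    low-frequency maximum and that peak must be at least
    ``tf_trough_ratio`` deep relative to the peak.  Filtered transients
    (monotone-decaying spectra) and below-band leakage both fail.
    Returns the status and the peak frequency.
    """
    lo, hi = config.band.lo_hz, config.band.hi_hz
    s, e = candidate
    cols = (tf_map.times_s >= s) & (tf_map.times_s < e)
    if not cols.any():
        raise ValueError("tf_map does not cover the candidate interval")
    spec = tf_map.power[:, cols].mean(axis=1)
    freqs = tf_map.freqs_hz
    in_band = (freqs >= lo) & (freqs <= hi)
    if not in_band.any():
        raise ValueError("tf_map does not cover the detection band")
    i_band = np.flatnonzero(in_band)
    i_peak = i_band[np.argmax(spec[i_band])]
    peak_freq = float(freqs[i_peak])
    p_peak = spec[i_peak]
    if p_peak <= 0:
        return "rejected_tf", peak_freq
    below = np.flatnonzero(freqs < lo)
    i0 = below[np.argmax(spec[below])] if below.size else 0
    trough = spec[i0:i_peak + 1].min()
    depth = 1.0 - trough / p_peak
    if depth >= config.tf_trough_ratio:
        return "accepted", peak_freq
    return "rejected_tf", peak_freq


def reject_cross_channel(
    events: list[HfoEvent], n_channels: int, config: DetectorConfig
) -> list[HfoEvent]:
    """Stage-3: flag events co-occurring on too many channels.

    An accepted event whose interval overlaps accepted events on more
    than ``cross_channel_fraction`` of the recording's channels
    (counting its own channel) is marked ``rejected_cross_channel`` —
    physiological HFO are focal, widespread synchronous events are
    artifacts.  Other statuses pass through unchanged.
    """
    if n_channels <= 1:
        return events
    acc = [ev for ev in events if ev.status == "accepted"]
    flag = np.zeros(len(acc), dtype=bool)
    order = sorted(range(len(acc)), key=lambda i: acc[i].start_s)
    for ii, i in enumerate(order):
        chans = {acc[i].channel}
        for j in order[ii + 1:]:
            if acc[j].start_s >= acc[i].end_s:
                break
            chans.add(acc[j].channel)
        for j in order[:ii][::-1]:
            if acc[j].end_s <= acc[i].start_s:
                continue
            chans.add(acc[j].channel)
        if len(chans) > config.cross_channel_fraction * n_channels:
            flag[i] = True
    out = []
    k = 0
    for ev in events:
        if ev.status == "accepted":
            if flag[k]:
                ev = replace(ev, status="rejected_cross_channel")
            k += 1
        out.append(ev)
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

#: neighbourhood (s) around a candidate used for Stockwell validation
_TF_PAD_S = 0.25


def detect(
    rec: Recording,
    band: Band | str = RIPPLE,
    config: DetectorConfig | None = None,
    epochs: EpochSet | None = None,
) -> list[HfoEvent]:
    """Run the full three-stage detector on a recording.

    Per clean epoch and channel: band-pass filter → baseline threshold
    Th_amp → candidate runs → Stockwell validation on the unfiltered
    signal → cross-channel rejection.  Deterministic for fixed input.
    Events carry absolute times (seconds from recording start).
    """
    if isinstance(band, str):
        band = BANDS[band]
    if config is None:
        config = DetectorConfig(band=band)
    elif config.band.name != band.name:
        config = replace(config, band=band)
    if rec.fs_hz <= 2 * band.hi_hz:
        raise ValueError("sampling rate too low for this band")
    if epochs is None:
        epochs = clean_epochs(rec)
    events: list[HfoEvent] = []
    filtered = bandpass_filter(rec.samples, band, rec.fs_hz)
    for ci, label in enumerate(rec.channel_labels):
        raw = rec.samples[ci]
        bnd = filtered[ci]
        for es, ee in epochs.epochs:
            i0, i1 = int(round(es * rec.fs_hz)), int(round(ee * rec.fs_hz))
            seg = bnd[i0:i1]
            try:
                th = estimate_baseline_threshold(seg, rec.fs_hz, config)
            except InsufficientDataError:
                continue
            env_seg = envelope(seg)
            for cs, ce in detect_candidates(seg, rec.fs_hz, th, config):
                a0, a1 = es + cs, es + ce  # absolute times
                j0 = max(0, int(round((a0 - _TF_PAD_S) * rec.fs_hz)))
                j1 = min(rec.n_samples, int(round((a1 + _TF_PAD_S) * rec.fs_hz)))
                tf = stockwell_transform(
                    raw[j0:j1], rec.fs_hz, band.lo_hz / 2.0, band.hi_hz
                )
                tf.times_s = tf.times_s + j0 / rec.fs_hz
                status, pk = validate_time_frequency((a0, a1), tf, config)
                k0, k1 = int(round(cs * rec.fs_hz)), int(round(ce * rec.fs_hz))
                events.append(HfoEvent(
                    channel=label, band=band.name, start_s=a0, end_s=a1,
                    peak_freq_hz=pk,
                    peak_amp_uv=float(env_seg[k0:k1].max()),
                    status=status,
                ))
    events = reject_cross_channel(events, rec.n_channels, config)
    events.sort(key=lambda ev: (ev.channel, ev.start_s))
    return events


def apply_review(events: list[HfoEvent], decisions: dict[int, tuple[bool, str]]) -> list[HfoEvent]:
    """Apply human review decisions (event index → (keep, note)).

    Review only rejects artifacts among accepted events; it never
    promotes a rejected event.
    """
    out = []
    for i, ev in enumerate(events):
        if i in decisions and ev.status == "accepted":
            keep, note = decisions[i]
            if not keep:
                ev = replace(ev, status="rejected_review", review_note=note)
        out.append(ev)
    return out
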