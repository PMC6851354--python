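"""Per-channel and per-hemisphere HFO rates, and clinical summary rows.

Rates are events per minute of clean NREM time.  Hemisphere aggregation
follows the two clinical conventions: the arithmetic mean over a
hemisphere's bipolar channels for scalp EEG, the channel maximum for
intraoperative ECoG.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .detector import HfoEvent

__all__ = ["ChannelRate", "RecordingSummary", "channel_rate", "aggregate_rate",
           "summarize_recording"]


@dataclass
class ChannelRate:
    channel: str
    band: str
    n_events: int
    clean_minutes: float
    rate: float  # events/min


@dataclass
class RecordingSummary:
    """One row of the clinical table."""

    patient_id: str
    stage: Literal["pre", "post"]
    modality: Literal["scalp", "ecog"] = "scalp"
    affected_rate: float = 0.0
    nonaffected_rate: float | None = None
    seizure_freq: float | None = None  # seizures/month
    ilae: int | None = None
    active: bool | None = None

    def __post_init__(self) -> None:
        if self.stage not in ("pre", "post"):
            raise ValueError("stage must be 'pre' or 'post'")
        if self.ilae is not None and not 1 <= self.ilae <= 6:
            raise ValueError("ilae must be in 1..6 when present")
        if self.affected_rate < 0:
            raise ValueError("rates must be >= 0")


def channel_rate(events: Iterable[HfoEvent], channel: str, clean_minutes: float,
                 band: str | None = None) -> ChannelRate:
    """Accepted-event rate for one channel: n_accepted / clean_minutes."""
    if clean_minutes <= 0:
        raise ValueError("clean_minutes must be > 0")
    kept = [
        ev for ev in events
        if ev.channel == channel and ev.status == "accepted"
        and (band is None or ev.band == band)
    ]
    band_name = band if band is not None else (kept[0].band if kept else "")
    return ChannelRate(
        channel=channel, band=band_name, n_events=len(kept),
        clean_minutes=clean_minutes, rate=len(kept) / clean_minutes,
    )


def aggregate_rate(
    channel_rates: Sequence[ChannelRate],
    channels_of_side: Sequence[str],
    method: Literal["mean", "max"] = "mean",
) -> float:
    """Hemisphere rate: mean (scalp convention) or max (ECoG convention)."""
    if not channels_of_side:
        raise ValueError("channels_of_side must be non-empty")
    rates = [cr.rate for cr in channel_rates if cr.channel in set(channels_of_side)]
    if not rates:
        raise ValueError("no channel rates for the requested side")
    if method == "mean":
        return sum(rates) / len(rates)
    if method == "max":
        return max(rates)
    raise ValueError(f"unknown aggregation method {method!r}")


def summarize_recording(
    patient_id: str,
    stage: str,
    modality: str,
    affected_channels: Sequence[str],
    nonaffected_channels: Sequence[str],
    channel_rates: Sequence[ChannelRate],
    seizure_freq: float | None = None,
    ilae: int | None = None,
) -> RecordingSummary:
    """Assemble a clinical-table row from per-channel rates.

    Scalp recordings aggregate each hemisphere by the mean; ECoG uses
    the channel maximum over the (affected-side) contacts and carries no
    non-affected rate.  The ``active`` flag is left unset — it is a
    clinical label filled in by the statistics layer.
    """
    both = set(affected_channels) & set(nonaffected_channels)
    if both:
        raise ValueError(f"channels on both sides: {sorted(both)}")
    method = "mean" if modality == "scalp" else "max"
    affected = aggregate_rate(channel_rates, affected_channels, method)
    nonaffected = (
        aggregate_rate(channel_rates, nonaffected_channels, method)
        if modality == "scalp" and nonaffected_channels else None
    )
    return RecordingSummary(
        patient_id=patient_id, stage=stage, modality=modality,
        affected_rate=affected, nonaffected_rate=nonaffected,
        seizure_freq=seizure_freq, ilae=ilae,
    )
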