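"""Scoring detected events against simulator ground truth."""

from __future__ import annotations

from dataclasses import dataclass

from ._intervals import jaccard, overlap_length
from .detector import HfoEvent
from .simulate import GroundTruth

__all__ = ["DetectionScore", "score_detection"]


@dataclass
class DetectionScore:
    n_truth: int
    n_detected: int
    n_matched: int

    @property
    def sensitivity(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else float("nan")

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else float("nan")


def score_detection(
    events: list[HfoEvent],
    truth: GroundTruth,
    band: str = "ripple",
    min_jaccard: float = 0.2,
) -> DetectionScore:
    """Greedy one-to-one matching of accepted events to injected HFO.

    A detected event matches a same-channel truth event when their
    interval Jaccard index reaches ``min_jaccard``; pairs are matched
    greedily by descending overlap length.  The default Jaccard of 0.2
    tolerates the detector marking only the supra-threshold core of a
    tapered burst.
    """
    accepted = [ev for ev in events if ev.status == "accepted" and ev.band == band]
    truths = truth.hfo_events(band)
    pairs = []
    for i, ev in enumerate(accepted):
        for j, tr in enumerate(truths):
            if ev.channel != tr.channel:
                continue
            ov = overlap_length(ev.interval, tr.interval)
            if ov > 0 and jaccard(ev.interval, tr.interval) >= min_jaccard:
                pairs.append((ov, i, j))
    pairs.sort(reverse=True)
    used_ev: set[int] = set()
    used_tr: set[int] = set()
    for _, i, j in pairs:
        if i in used_ev or j in used_tr:
            continue
        used_ev.add(i)
        used_tr.add(j)
    return DetectionScore(
        n_truth=len(truths), n_detected=len(accepted), n_matched=len(used_tr)
    )
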