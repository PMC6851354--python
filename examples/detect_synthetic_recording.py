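"""Simulate a low-noise scalp EEG recording and detect its ripples.

Builds a 5-minute, 4-channel recording with injected ripple-band bursts
(mean peak amplitude 3.89 µV) on a 1/f background with 2.3 nV/√Hz
amplifier noise, runs the three-stage detector, and scores the accepted
events against the known ground truth.
"""

import scalphfo as sh
from scalphfo.scoring import score_detection

spec = sh.RecordingSpec(
    duration_s=300.0,
    channel_labels=["C4", "P4", "C3", "P3"],
    event_rate_per_min=2.0,
    seed=1,
)
rec, truth = sh.make_recording(spec)
events = sh.detect(rec, band="ripple")
score = score_detection(events, truth)

print(f"injected ripples : {score.n_truth}")
print(f"accepted events  : {score.n_detected}")
print(f"sensitivity      : {score.sensitivity:.2f}")
print(f"precision        : {score.precision:.2f}")

epochs = sh.clean_epochs(rec)
for ch in rec.channel_labels:
    cr = sh.channel_rate(events, ch, epochs.clean_minutes, band="ripple")
    print(f"  {ch}: {cr.rate:.2f} HFO/min over {cr.clean_minutes:.0f} clean min")

# Sensitivity and precision near 1 mean the detector recovers essentially
# every injected burst without accepting background fluctuations; the
# per-channel rates are the clinical quantity fed to the statistics layer.
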