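# Methods

## Signal model and units

All signals are in µV; time is seconds from recording start; intervals are
half-open `[start, end)`; sample indices are 0-based. Rates are events per
minute of clean NREM time, with the denominator the exact summed epoch length
(partial trailing epochs keep their true duration — nothing is truncated, so
event-count conservation across epochs holds exactly).

## Synthetic recordings

A synthetic channel is the sum of three independent components:

1. **Background**: white Gaussian noise spectrally shaped by `1/f^(β/2)` above
   a 0.5 Hz corner (flat below, removing the DC divergence), rescaled to the
   requested RMS exactly. Defaults: RMS 15 µV, β = 2.5. These two numbers are
   a deliberate calibration: they put the ripple-band (80–250 Hz) background
   at σ ≈ 0.30 µV, so the detector's amplitude threshold
   Th_amp = mean + 3·SD of the Rayleigh-distributed envelope lands near
   1.0 µV with low-amplifier noise and near 1.3 µV with 21 nV/√Hz noise —
   the regime reported for low-noise scalp EEG versus a commercial device.
   β = 2.5 is within the 2–3 range typical of sleep scalp EEG spectra.
2. **Amplifier noise**: white Gaussian noise with one-sided PSD d² (nV)²/Hz
   for an input-noise density d nV/√Hz (σ = d·√(fs/2) after unit conversion).
   Defaults 2.3 (low-noise amplifier); 21 emulates a commercial device.
3. **Events**: oscillatory bursts `sin(2πft)` under a Tukey envelope with 25%
   ramps (no step-edge splatter), peak amplitude normalised exactly. Centre
   frequencies are uniform over the central 84% of the band (off the filter
   skirts), cycle counts uniform on 6–12 (25–130 ms at ripple frequencies),
   peak amplitudes normal (3.89, 2.41) µV truncated below at 1.0 µV. The
   truncation reflects that the quoted amplitude distribution describes
   *detected* events, whose support necessarily starts near the detection
   threshold. Event times follow a per-channel Poisson process (default
   2/min) with uniform non-overlapping placement (bounded retries, then a
   generation error); the timing distribution and cycle-count range are
   module choices — no published distribution exists for them. Spike
   artifacts are Gaussian-derivative biphasic transients (30–70 ms), muscle
   artifacts Hann-windowed broadband noise; both scale linearly in amplitude.

The whole duration is annotated as NREM sleep, so simulated recordings flow
directly into epoch selection. What the simulator does **not** emulate:
sleep-stage dynamics, electrode-impedance drift, line noise, breach rhythms,
spatially correlated backgrounds across channels, or volume conduction.
Passing detector tests on this generator therefore demonstrate correctness of
the detection logic under controlled SNR, not clinical performance on real
EEG.

## Cohort generator

`rate = a · SF^b · 10^N(0, σ)` with seizure-free recordings entering at the
0.05 seizures/month freedom proxy. Defaults (a = 0.6, b = 0.4, σ = 0.3
decades, seizure-frequency range 0.2–450/month log-uniform, freedom fraction
6/19) are the rounded log-log OLS fit of the packaged clinical table, so a
19-row draw typically lands near the observed R² ≈ 0.8 regime. The
non-affected hemisphere rate is the affected rate times a lognormal factor
(median 10^-0.6 ≈ 0.25).

## Preprocessing

EDF is the only on-disk signal format. Writing is plain 16-bit EDF with
1-second records and per-channel physical ranges covering the extrema
(worst-case roundtrip error: one quantization step); reading goes through
`mne.io.read_raw_edf`, which doubles as an independent decoder of the
hand-written files in the roundtrip tests. Annotations travel in a CSV
sidecar (`label,start_s,end_s`). Bipolar montages are simple samplewise
differences labelled `ANODE-CATHODE`; both scalp and ECoG analyses use
bipolar channels. Downsampling applies a zero-phase FIR low-pass at
0.4·target_fs before decimation, preserving in-band (≤500 Hz) amplitudes to
within 1%. Clean epochs are NREM minus artifact intervals tiled into ≤300 s
pieces.

## Detector

Stage 1 — an order-4 Butterworth band-pass applied forward-backward
(zero-phase; >40 dB attenuation one octave outside the band). Th_amp is
estimated per channel and 5-min epoch: the epoch is scanned in 4096-sample
chunks; each chunk's Stockwell power (in-band, ~16 voices) yields a spectral
entropy per time column (evaluated every 16 samples); columns with entropy
above the 0.5 quantile — flat-spectrum, oscillation-free background — are
baseline, and Th_amp = mean + 3·SD of the Hilbert envelope over them. On
band-limited Gaussian noise this reproduces the closed-form Rayleigh value
σ(√(π/2) + 3√(2−π/2)) within 5%. Candidates are maximal envelope runs above
Th_amp, merged across gaps < 10 ms, kept when they last ≥ 4 cycles of the
run's dominant (FFT-argmax) frequency.

Stage 2 — the Stockwell transform of the **unfiltered** signal over the
candidate ± 0.25 s, frequencies from half the band's lower edge to its upper
edge. The S-transform uses the standard frequency-scaled Gaussian window
(frequency-domain SD f/2π, i.e. voice k is the inverse FFT of
X[m+k]·exp(−2π²m²/k²)); computing it only on candidate neighbourhoods keeps
runtime desk-scale and is exact on the evaluated support. A candidate is
accepted iff the time-averaged spectrum has its in-band maximum separated
from the low-frequency power maximum by a trough of relative depth ≥ 0.5.
Spikes and below-band leakage have monotone or low-peaked spectra and fail
this test; the spike-rejection property is asserted against simulator
transients.

Stage 3 — accepted events overlapping accepted events on > 80% of channels
are re-flagged as widespread artifacts. A JSON review file can additionally
mark events `rejected_review` (emulating human artifact rejection); review
never promotes events.

All constants (threshold factor 3, 4 cycles, 10 ms merge gap, trough depth
0.5, 80% cross-channel fraction, 0.5 entropy quantile) are this package's own
definitions, chosen once for the default study conditions and exposed in
`DetectorConfig`; they are deliberately not presented as published values.

## Clinical statistics

- **Activity label**: presurgical recordings are active; postsurgical ILAE 1
  is seizure-free, ILAE > 1 active; with ILAE unavailable, active iff
  seizures persist (>0/month).
- **Classification** is strict: a recording shows HFO iff rate > threshold.
  Strictness matters at the boundary — a postsurgical rate exactly equal to
  the cutoff classifies negative.
- **ROC cutoff**: candidates are the observed rates; the accuracy-maximising
  candidate wins, ties resolved toward the **largest** candidate. On the
  packaged table accuracy 16/19 is attained at both 0.15 and 0.25 HFO/min;
  the larger, more specific cutoff is the one with clinical meaning (the
  highest rate that positives must exceed) and is the package's choice.
- **Wilson score intervals** for binomial proportions (statsmodels). Exact
  enumeration at n = 19, p = 0.84 puts the 95% interval's true coverage at
  97.7% — discreteness makes small-n coverage conservative.
- **Severity regression**: OLS of log10(affected rate) on log10(seizure
  frequency), seizure freedom at the 0.05/month proxy. The raw-scale fit is
  available behind `log_scale=False` as a sensitivity analysis because the
  published transform is ambiguous; the log-log form is primary (the
  relation is a power law and the clinical axes are logarithmic).
- **Wilcoxon tests**: signed-rank exact for ≤ 12 pairs, else normal
  approximation without continuity correction (the approximation, not the
  exact p ≈ 5e-5, reproduces the reported p ≈ 3e-4 at n = 19); rank-sum exact
  for combined n ≤ 12, else normal approximation. Identical paired vectors
  are the degenerate no-effect case and return p = 1.
- **Concordance χ²**: textbook 1-df statistic N(ad−bc)²/(margin product) on
  the 2×2 table of pre→post direction of change, no continuity correction;
  for a diagonal table [[a,0],[0,b]] it equals a + b. Zero margins leave it
  undefined.

## Numerical and testing choices

Problem sizes in the test suite are chosen to exercise the stated study
conditions at desk scale: detector sensitivity/precision and the
false-positive budget run on single 30-minute 8-channel recordings, the
amplifier-direction comparison on twenty 5-minute 4-channel seed pairs, and
cohort slope recovery on 100 replicates of n = 200. Scoring matches detected
to injected events greedily by interval overlap (Jaccard ≥ 0.2 by default,
tolerating that the detector marks only the supra-threshold core of a
tapered burst).

Known limitations: the detector's constants are tuned to the 2 kHz ripple-band
scalp setting and are not validated for ECoG fast-ripple data beyond the unit
level; the EDF writer emits plain EDF (no embedded EDF+ annotations); the
entropy-based baseline is slightly conservative (≈3% high) on pure white
noise; and clinical-table statistics at n = 19 inherit all small-sample
caveats (the accuracy CI spans 62–94%).
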