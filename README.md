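# notchcode

Temporal coding of echo spectral notches in a model tonotopic auditory
cortex.

Echolocating bats reconstruct the shape of a target from interference
patterns in returning echoes: an object with two reflecting surfaces
(glints) separated by a few millimetres returns two overlapping copies of
the emitted downward FM sweep, whose sum carries a comb-filter notch at
f = (2k+1)/(2τ) for inter-glint delay τ.  How can a cortex encode a
~30-dB, ~2-kHz-wide dip inside a 10-ms sound?  `notchcode` implements the
candidate answer — spike *timing*, not rate — as a tested, reproducible
simulation-plus-analysis pipeline for computational neuroscientists:

- **stimulus synthesis** — tones, flat downward FM sweeps (dFM,
  70→20 kHz / 10 ms, 250 kHz sampling), delayed-sum two-glint mimics, and
  spectral notch metrics;
- **synthetic cortex** — a generative tonotopic population (122 layer-IV-
  like units over ~2 mm, CF 15–70 kHz, thresholds 20–60 dB SPL, first-
  spike latencies 10–35 ms) with amplitude–latency trading (1/3 ms/dB),
  jitter, bursts and spontaneous firing;
- **receptive fields** — frequency response areas, CF/threshold
  extraction, PSTHs, and mean first-spike latency by the
  25%-of-PSTH-peak rule;
- **information coding** — plug-in mutual information
  I(R;S) = H(R) − H(R|S) in bits between stimuli and trial-by-trial
  responses under rate, latency (2-ms bins) and joint codes, with
  quadratic-extrapolation and shuffling bias corrections, and a
  bias-versus-trial-count simulation against exact model MI;
- **spike synchrony** — the SPIKE-synchronization index c ∈ [0, 1]
  (adaptive coincidence windows τ_ij = ½·min of local inter-spike
  intervals) and trial-averaged population matrices with CF-group block
  means;
- **population profiles** — tonotopic activation profiles, per-CF-group
  FSL summaries, tonotopy correlations and notch latency-shift reports
  with the standard group statistics.

The central claim the pipeline demonstrates end-to-end: a notch at a
neuron's CF lowers the effective level its cortical filter sees by
~28 dB, which through amplitude–latency trading delays its first spike by
~10 ms without changing its spike count — and that delay both carries far
more stimulus information than the rate and shifts the neuron into
synchrony with lower-CF, later-firing neurons, giving a population-level
signature of the glint geometry.

## Worked example

Two-glint stimuli and their notches (`examples/01_two_glint_stimuli.py`):

```
flat dFM: 2500 samples at 250000 Hz, RMS level 80 dB SPL
delay 16 us -> glint separation 2.72 mm, notch measured at 31.250 kHz (first in-band comb zero 31.250 kHz), depth 49.4 dB
delay 32 us -> glint separation 5.44 mm, notch measured at 46.879 kHz (first in-band comb zero 46.875 kHz), depth 47.5 dB
flat dFM in-band ripple: 0.12 dB (below the 10-dB notch-detection threshold: True)
```

The 16-µs delay (2.72 mm between glints) carves a ~49-dB notch exactly at
the analytic comb zero, 31.25 kHz; the flat sweep shows only 0.12 dB of
ripple.  Feeding these stimuli to the synthetic population and comparing
codes (`examples/05_information_codes.py`, neuron tuned to 31.4 kHz,
30 trials per stimulus):

```
  rate : raw 0.043  QE -0.012  corrected -0.012 bits
  fsl  : raw 1.000  QE 1.000  corrected 1.000 bits
  joint: raw 1.000  QE 1.000  corrected 1.000 bits
```

The first-spike-latency code identifies the notched echo perfectly
(1 bit for the binary flat-vs-notched decision); the spike count carries
essentially nothing, and combining both adds nothing beyond latency.  At
the population level (`examples/06_population_synchrony.py`):

```
flat dFM: mean within-CF-group sync 0.162 vs between-group 0.103
Notch30: sync(30 kHz x 20 kHz) = 0.094 (flat: 0.071)
Notch45: sync(45 kHz x 20 kHz) = 0.045 (flat: 0.026)
Notch45: sync(45 kHz x 25 kHz) = 0.127 (flat: 0.070)
```

For the flat sweep, same-CF neurons fire most synchronously; each notch
raises the synchronization between its notch-tuned group and the low-CF
groups the extra ~10 ms of latency pushes those neurons toward.

The other examples cover the tonotopic map statistics (CF vs position
R ≈ −0.88, FSL vs position R ≈ +0.61), single-neuron receptive-field
recovery, the notch latency-shift report (significant FSL shift,
non-significant count change), estimator-bias behaviour, and the full
YAML-configured pipeline (`examples/07_full_pipeline.py`), which writes
every table as TSV and reruns byte-identically under the same config.

See `docs/methods.md` for the models, estimator details and limitations.

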