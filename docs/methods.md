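# Methods

`notchcode` simulates and analyzes how a tonotopic primary-auditory-cortex
(A1) population encodes spectral notches in frequency-modulated echo
mimics.  This note documents the models, the estimators, the numerical
choices, and what the synthetic data can and cannot establish.

## Acoustic model

**Stimuli.** Pure tones (10 ms, 0.5-ms linear rise/fall) on a 15–70 kHz ×
20–80 dB SPL grid (5-kHz / 10-dB steps, 5 repetitions, pseudorandomized,
300-ms inter-trial interval); a flat-spectrum downward FM sweep (dFM,
70→20 kHz in 10 ms); and two-glint echo mimics built by summing the dFM
with a copy of itself delayed by τ = 16 or 32 µs.  All signals are
synthesized at 250 kHz.  The sweep law is linear in frequency (constant
5 kHz/ms); the instantaneous frequency crosses a neuron's CF at
t = (70 − CF)/5 ms.

**Two-glint interference.** Summing a signal with a delayed copy equals
convolution with a two-impulse reflector and imposes the comb filter
|1 + e^(−i2πfτ)|, with zeros at f = (2k+1)/(2τ): 31.25 kHz for 16 µs
(labelled "Notch30") and 46.875 kHz for 32 µs ("Notch45"; the 15.625-kHz
zero lies below the sweep band).  The glint separation is d = cτ/2 with
c = 340 m/s, giving 2.72 and 5.44 mm.

**Amplitude convention.** RMS amplitude 1.0 ≡ 80 dB SPL; levels are pure
dB offsets from that reference.  After summation the two-glint stimuli are
renormalized to the flat sweep's RMS, so all three dFMs are presented at
the same nominal level.

**Notch metrics.** The spectrum is a zero-padded periodogram
boxcar-averaged to 100-Hz resolution — the resolution any physical
analyzer of a 10-ms signal could honestly claim; without that averaging an
integer-sample delay places a machine-precision zero exactly on the FFT
grid and the "depth" becomes meaningless.  Depth = median in-band level −
in-band minimum over the 25–55 kHz analysis band (chosen inside the sweep
band, clear of edge roll-off).  A dip shallower than 10 dB is not reported
as a notch.  Measured depths are ≈49 dB (16 µs) and ≈48 dB (32 µs) at the
comb-zero frequencies.

## Population model

Each of n = 122 neurons (the default population size on a 2 × 1 mm sheet)
carries:

| parameter | default | meaning |
|---|---|---|
| `cf_khz` | log-linear in position + N(0, 0.35 oct), clipped 15–70 | characteristic frequency; anterior = high CF |
| `threshold_db_spl` | U(20, 60) | minimum threshold at CF |
| `base_latency_ms` | 10 + 8·log2(70/CF) + N(0, 5), clipped 10–35 | mean FSL at CF, 80 dB SPL |
| `tuning_slope_ms_per_oct` | 5 | latency cost per octave off CF |
| `bandwidth_oct` | 1.0 | scales the excitatory tuning width |
| `trading_ms_per_db` | 1/3 | amplitude–latency trading |
| `jitter_sd_ms` | 1.5 | Gaussian first-spike jitter |
| `spont_rate_hz` | 1.0 | homogeneous Poisson background |
| `burst_mean_spikes` | 2.0 | mean evoked spikes per trial |

The CF scatter (0.35 oct) makes a default population reproduce a CF-vs-
posterior-position Pearson R ≈ −0.87, and the latency scatter (5 ms) an
FSL-vs-position R ≈ +0.55–0.6 — the tonotopic-map statistics the model is
built to emulate.  The trading ratio of 1/3 ms/dB is calibrated so that a
~30-dB effective attenuation lengthens FSL by ~10 ms.

**Excitatory response area.** A rounded-tip V: tones within ±2.5 kHz of CF
are attenuated 0 dB, beyond that the flanks attenuate 5 dB/kHz (10-dB
bandwidth ≈ 9 kHz, Q10 ≈ 3–7, appropriate for sharply tuned high-frequency
A1 units).  The flat tip spans the half-gap of the 5-kHz stimulus grid, so
threshold is recoverable to one grid step; a pure V tip would push the
nearest grid tone several dB up the flank and bias measured thresholds
upward by more than one 10-dB step.

**Effective level at CF for broadband stimuli.** The mean spectral power
density over ±1 kHz around the CF, referenced to the stimulus's average
density over its occupied bandwidth (floored at the 2-kHz analysis band so
narrowband stimuli are not over-counted).  A flat dFM reads ≈80 dB SPL at
any in-band CF; a tone at CF reads its own level; a CF at the 16-µs comb
null reads ≈28 dB lower.  This band-limited attenuation — not the
point-null depth of the notch-metrics report — is what a ~2-kHz-wide
cortical filter integrates, and it is the quantity that amplitude–latency
trading acts on.  Consequently the predicted notch-at-CF latency shift is
trading × 28 dB ≈ 9.3 ms, consistent with the ~10-ms shift the analysis
recovers, while CF groups keyed to the 5-kHz grid show smaller median
shifts (the notch is only ~2 kHz wide, so half of a grid group sits partly
outside it).

**Spiking.** If the effective level clears threshold, each trial carries a
first spike at sweep-arrival + latency-model mean + jitter, followed by a
truncated-geometric burst (inter-spike intervals gamma-distributed around
2 ms), capped at 6 evoked spikes; burst size is level-independent, so
spike-count contrasts between dFMs are null by construction except for
threshold dropouts.  Spontaneous spikes cover a −50 to +250 ms epoch.
Neurons are simulated independently (the emulated recordings were not
simultaneous); each (neuron, stimulus) pair draws from its own
`SeedSequence`-derived stream, so datasets are reproducible and
insensitive to iteration order.

## Receptive-field analysis

FRAs count spikes in 0–50 ms per frequency–level cell, summed over
repetitions.  Threshold is the lowest level at which any frequency exceeds
the pre-stimulus baseline count by `min_spikes` (default 3 at the analysis
surface: with 1-Hz spontaneous firing and 84 grid cells, a criterion of 1
extra spike produces false sub-threshold cells in most neurons); CF is the
frequency with the highest count at that level, ties broken toward the
count-weighted centroid.  An all-zero FRA yields an explicit
"unresponsive" summary.

**Mean FSL (25% rule).** The PSTH (1-ms bins; 0–50 ms for tones, 0–80 ms
for sweeps) is scanned for the first bin reaching 25% of its peak; the
per-trial FSL is the first spike at or after that time, averaged over
trials that have one.  The rule is applied to the raw (unsmoothed) PSTH.
Two guards: trials with no qualifying spike are excluded, not imputed; and
a PSTH whose peak is below 10% of the trial count is treated as carrying
no evoked response — otherwise a single spontaneous spike would define a
vacuous 25% threshold and return a "latency" made of background spikes.

Parameter recovery: on low-noise settings (jitter ≤ 1 ms, spontaneous
≤ 1 Hz) the analysis returns each generator neuron's CF within one 5-kHz
step and threshold within one 10-dB step — except for long-latency,
low-threshold units whose near-threshold response falls beyond the 50-ms
counting window, where the threshold is over-estimated by construction
(a real analysis of such a neuron would do the same).

## Mutual information

Responses in 0–80 ms are discretized per trial: rate = spike count;
FSL = first-spike time in 2-ms bins with a distinct NO_SPIKE symbol;
joint = the (rate, FSL) pair.  I(R;S) = H(R) − H(R|S) is evaluated
plug-in on empirical probabilities, log base 2 (bits).  Default stimulus
set per neuron: the binary {flat dFM, dFM notched at the neuron's CF
group} with uniform priors; a ternary set is a parameter away.

**Bias corrections.**
*Quadratic extrapolation (QE):* plug-in MI at the full trial count N and
averaged over random disjoint subsamples at N/2 and N/4 (20 partitions);
I(N) = I∞ + a/N + b/N² is fit through the three points and I∞ returned.
*Shuffling (joint code only):* within each stimulus the pairing of rate
and FSL across trials is permuted, destroying the within-trial
rate–latency association while preserving both marginals; the mean
plug-in MI of 20 shuffled tables, minus the exactly computed MI of the
conditional-independence model P(rate|s)·P(fsl|s), estimates the sampling
bias carried by the cross-term, and is subtracted from the QE estimate.
This recipe is our interpretation of the standard shuffling correction;
single-dimension codes have no cross-term and are returned QE-corrected.

**Bias-versus-trials simulation.** `NotchResponseModel` is an explicit
single-neuron response distribution with the statistics of a notch-tuned
unit: respond-probability 0.95 (flat) vs 0.75 (notched), FSL Gaussian
with a 9.3-ms shift and 1.5-ms jitter, 0–6 spikes per trial.  Its exact
MI per code comes from enumeration over the 7 × 41 response alphabet, so
estimator bias is measured against ground truth.  Expected behaviour:
plug-in estimates are biased upward and the bias decays monotonically
with trial count; the QE-corrected latency and joint codes sit within a
few percent of their asymptote from ~16 trials.  A caveat the simulation
makes explicit: the QE residual at 16 trials is an *absolute* ~0.02–0.05
bits set by the alphabet, so for a code carrying only ~0.06 bits (the
rate code here, by design — the notch barely changes spike counts) the
*relative* error at 16 trials remains large no matter the estimator.

**Group comparison.** Per-neuron corrected MI per code, compared across
codes with a Kruskal–Wallis one-way ANOVA on ranks; the post hoc Tukey
HSD is applied to rank-transformed values (an interpretation: SciPy has
no native Tukey-on-ranks).  Groups smaller than 3 neurons skip the test
with a warning.

## Spike synchronization

The SPIKE-synchronization index c counts, for each spike, whether its
nearest partner in the other train lies within the adaptive window
τ = ½·min(local ISIs around both spikes); c = coincident spikes / total
spikes ∈ [0, 1], reaching 1 iff every spike has a partner and 0 iff there
are no coincidences.  Edge conventions: first/last spikes use their single
adjacent ISI; a singleton train borrows the partner's local ISI; two
singletons use a 5-ms fallback window; any empty train gives c = 0 (two
empty trains are defined as 0).  A brute-force reimplementation of the
definition (explicit loops, in the test suite) agrees with the vectorized
version to < 1e-12 on hundreds of random pairs.

Population matrices pair trains of different neurons by trial index
(pseudo-simultaneous, onset-aligned), compute all pairwise c per trial on
the 0–80 ms epoch, and average over trials; the diagonal is 1 by the
identical-train convention.  Block means over 5-kHz CF groups exclude the
diagonal within same-group blocks.

## Pipeline and reproducibility

`RunConfig` (flat YAML) fixes the seed, sizes, windows (FRA 50 ms, MI
80 ms, FSL bin 2 ms, PSTH bin 1 ms) and output directory.  Every stage
derives its stream from (seed, stage name) via `SeedSequence`, so the same
config reproduces every table byte-for-byte.  Default problem sizes —
122 neurons, 420-trial tone protocol, 3 × 30-trial dFM protocol — run the
whole pipeline in roughly two minutes on one CPU; the synchronization
matrices (≈7,400 pairs × 30 trials × 3 stimuli) and the per-neuron MI
corrections dominate.

## What the synthetic data does and does not show

The generator reproduces the *structure* the analyses target — tonotopy
with realistic scatter, V-shaped latency tuning, amplitude–latency
trading, low spike counts, spontaneous firing — so passing tests show the
pipeline recovers known ground truth through the full analysis chain
(spectrum → threshold crossing → latency → discretization → estimator).
It does not emulate: correlated variability across neurons (recordings
were pseudo-simultaneous), inhibitory sidebands or multipeaked tuning,
depth/laminar structure, adaptation across trials, or deviations from
Gaussian jitter.  Conclusions about real cortex rest on the original
recordings; this package establishes that the analysis methods, applied
to data with matching statistics, behave as claimed.

## Known limitations

- The comb notch is ~2 kHz wide at 16 µs, so "neurons tuned to the notch"
  is sharper than the 5-kHz CF grouping; group-median latency shifts are
  roughly half the at-notch shift.
- QE is reliable only when trials are several times the occupied response
  alphabet; quarter-subsamples of very sparse tables can extrapolate
  below zero.
- The 32-µs notch is narrower in Hz than the 16-µs one, giving ~23 dB
  band-limited attenuation and correspondingly smaller (~7–8 ms) at-notch
  latency shifts.
- Latency-based threshold recovery fails beyond the 50-ms FRA window (see
  above); widening the window would trade spontaneous-spike contamination
  for coverage.
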