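"""Frequency response areas, tuning extraction, PSTHs, and mean FSL.

Mean first-spike latency uses the 25%-of-PSTH-peak rule: spontaneous
spikes before the evoked response are ignored by taking, in each trial,
the first spike at or after the time the pooled PSTH first reaches a
quarter of its peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import Dataset

TONE_WINDOW_MS = (0.0, 50.0)
SWEEP_WINDOW_MS = (0.0, 80.0)
PSTH_BIN_MS = 1.0


@dataclass
class FRA:
    """Frequency response area: summed evoked spike counts on the tone grid."""

    counts: np.ndarray  # shape (n_freqs, n_levels)
    freqs_khz: np.ndarray
    levels_db: np.ndarray
    window_ms: float = 50.0
    n_reps: int = 5

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.freqs_khz), len(self.levels_db)):
            raise ValueError("counts shape must match (freqs, levels)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class TuningSummary:
    """CF, minimum threshold, and mean FSL at CF / 80 dB SPL.

    ``responsive`` is False when the FRA contained no above-baseline
    response; cf/threshold/FSL are then NaN.
    """

    cf_khz: float
    threshold_db: float
    mean_fsl_ms: float = float("nan")
    responsive: bool = True

    @classmethod
    def unresponsive(cls) -> "TuningSummary":
        return cls(float("nan"), float("nan"), float("nan"), responsive=False)


@dataclass
class PSTH:
    bin_edges_ms: np.ndarray
    counts: np.ndarray  # summed over trials
    n_trials: int

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.bin_edges_ms) - 1:
            raise ValueError("need one more bin edge than count")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def _tone_grid(dataset: Dataset) -> tuple[np.ndarray, np.ndarray, dict]:
    tones = {
        lab: s for lab, s in dataset.protocol.stimuli.items() if s.kind == "tone"
    }
    if not tones:
        raise ValueError("dataset contains no tone-protocol stimuli")
    freqs = np.array(sorted({s.freq_khz for s in tones.values()}))
    levels = np.array(sorted({s.level_db for s in tones.values()}))
    return freqs, levels, tones


def build_fra(dataset: Dataset, neuron_id: int, window_ms: float = 50.0) -> FRA:
    """Spike counts in [0, window_ms], summed over repetitions, for every
    frequency-level combination of the tone protocol."""
    freqs, levels, tones = _tone_grid(dataset)
    counts = np.zeros((len(freqs), len(levels)), dtype=int)
    n_reps = 0
    for lab, spec in tones.items():
        i = int(np.searchsorted(freqs, spec.freq_khz))
        j = int(np.searchsorted(levels, spec.level_db))
        trains = dataset.trains(neuron_id, lab)
        n_reps = len(trains)
        counts[i, j] = sum(
            int(np.sum((t >= 0) & (t < window_ms))) for t in trains
        )
    return FRA(counts, freqs, levels, window_ms, n_reps)


def baseline_count(
    dataset: Dataset, neuron_id: int, window_ms: float = 50.0
) -> float:
    """Mean pre-stimulus spike count per tone presentation, scaled to the
    FRA window, summed over the repetitions of one grid cell."""
    _, _, tones = _tone_grid(dataset)
    total, n = 0, 0
    for lab in tones:
        for t in dataset.trains(neuron_id, lab):
            total += int(np.sum((t >= -window_ms) & (t < 0)))
            n += 1
    n_reps = dataset.n_trials(next(iter(tones)))
    return total / n * n_reps if n else 0.0


def extract_cf_threshold(
    fra: FRA, min_spikes: int = 1, baseline: float = 0.0
) -> TuningSummary:
    """CF and minimum threshold from an FRA.

    Threshold is the lowest level at which any frequency exceeds the
    baseline count by ``min_spikes``; the CF is the frequency with the
    maximum count at that level, ties broken toward the count-weighted
    centroid frequency.  An FRA with no qualifying cell yields an explicit
    unresponsive summary rather than an exception.
    """
    if fra.counts.size == 0:
        raise ValueError("empty FRA")
    responsive = fra.counts >= baseline + min_spikes
    level_hit = responsive.any(axis=0)
    if not level_hit.any():
        return TuningSummary.unresponsive()
    j = int(np.argmax(level_hit))
    col = np.where(responsive[:, j], fra.counts[:, j], -1)
    best = col.max()
    tied = np.flatnonzero(col == best)
    if len(tied) > 1:
        w = fra.counts[:, j].astype(float)
        centroid = float(np.sum(w * fra.freqs_khz) / np.sum(w)) if w.sum() else 0.0
        tied = tied[np.argsort(np.abs(fra.freqs_khz[tied] - centroid), kind="stable")]
    return TuningSummary(float(fra.freqs_khz[tied[0]]), float(fra.levels_db[j]))


def compute_psth(
    trains: list[np.ndarray],
    bin_ms: float = PSTH_BIN_MS,
    window: tuple[float, float] = SWEEP_WINDOW_MS,
) -> PSTH:
    """Histogram of spike times pooled over trials."""
    edges = np.arange(window[0], window[1] + bin_ms / 2, bin_ms)
    if len(trains):
        pooled = np.concatenate([np.asarray(t, dtype=float) for t in trains])
    else:
        pooled = np.empty(0)
    counts, _ = np.histogram(pooled, edges)
    return PSTH(edges, counts, len(trains))


def mean_fsl(
    trains: list[np.ndarray], psth: PSTH, min_peak_fraction: float = 0.1
) -> float:
    """Mean first-spike latency by the 25%-of-PSTH-peak rule.

    t25 is the left edge of the first bin whose count reaches a quarter of
    the PSTH peak; the per-trial FSL is the first spike at or after t25
    (within the PSTH window), averaged over trials that have one.  Returns
    NaN (undefined FSL) when the PSTH has no peak or no trial qualifies.

    A PSTH whose peak falls below ``min_peak_fraction`` of the trial count
    (floored at one spike) is treated as carrying no evoked response --
    with sparse spontaneous firing a one-spike "peak" would otherwise make
    the 25% threshold vacuous and return a latency made of spontaneous
    spikes.
    """
    peak = psth.counts.max() if len(psth.counts) else 0
    if peak < max(1.0, min_peak_fraction * psth.n_trials):
        return float("nan")
    t25 = float(psth.bin_edges_ms[int(np.argmax(psth.counts >= 0.25 * peak))])
    t_end = float(psth.bin_edges_ms[-1])
    firsts = []
    for t in trains:
        t = np.asarray(t, dtype=float)
        sel = t[(t >= t25) & (t <= t_end)]
        if len(sel):
            firsts.append(sel[0])
    return float(np.mean(firsts)) if firsts else float("nan")


def mean_fsl_for(
    dataset: Dataset,
    neuron_id: int,
    stimulus_id: str,
    window: tuple[float, float] = SWEEP_WINDOW_MS,
    bin_ms: float = PSTH_BIN_MS,
) -> float:
    trains = dataset.trains(neuron_id, stimulus_id)
    return mean_fsl(trains, compute_psth(trains, bin_ms, window))


def tuning_summary(
    dataset: Dataset, neuron_id: int, min_spikes: int = 3
) -> TuningSummary:
    """Full tuning extraction for one neuron: FRA -> CF + threshold, then
    mean FSL at the CF tone at 80 dB SPL (tone analysis window)."""
    fra = build_fra(dataset, neuron_id)
    base = baseline_count(dataset, neuron_id, fra.window_ms)
    summ = extract_cf_threshold(fra, min_spikes, base)
    if not summ.responsive:
        return summ
    label = _cf_tone_label(dataset, summ.cf_khz)
    if label is not None:
        summ.mean_fsl_ms = mean_fsl_for(dataset, neuron_id, label, TONE_WINDOW_MS)
    return summ


def _cf_tone_label(dataset: Dataset, cf_khz: float, level_db: float = 80.0):
    best, best_d = None, np.inf
    for lab, s in dataset.protocol.stimuli.items():
        if s.kind == "tone" and s.level_db == level_db:
            d = abs(s.freq_khz - cf_khz)
            if d < best_d:
                best, best_d = lab, d
    return best


def tuning_table(dataset: Dataset, min_spikes: int = 3) -> pd.DataFrame:
    """Tuning summaries for every neuron in a tone-protocol dataset."""
    rows = []
    for nid in dataset.neuron_ids:
        s = tuning_summary(dataset, nid, min_spikes)
        rows.append(
            {
                "neuron_id": nid,
                "cf_khz": s.cf_khz,
                "threshold_db": s.threshold_db,
                "mean_fsl_ms": s.mean_fsl_ms,
                "responsive": s.responsive,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ResponseFunctions:
    """Iso-level (80 dB) and rate-level (at CF) curves of count and FSL."""

    iso_level: pd.DataFrame  # freq_khz, mean_count, mean_fsl_ms
    rate_level: pd.DataFrame  # level_db, mean_count, mean_fsl_ms
    cf_khz: float
    responsive: bool = True


def response_functions(dataset: Dataset, neuron_id: int) -> ResponseFunctions:
    """Count and mean-FSL curves vs frequency at 80 dB SPL and vs level at
    the CF.  For a well-tuned unit the count maximum and FSL minimum both
    sit at the CF, and FSL decreases monotonically with level."""
    freqs, levels, tones = _tone_grid(dataset)
    summ = tuning_summary(dataset, neuron_id)
    if not summ.responsive:
        empty = pd.DataFrame()
        return ResponseFunctions(empty, empty, float("nan"), responsive=False)

    def _curve(specs, key):
        rows = []
        for lab, s in specs:
            trains = dataset.trains(neuron_id, lab)
            n_spk = np.mean(
                [np.sum((t >= 0) & (t < TONE_WINDOW_MS[1])) for t in trains]
            )
            rows.append(
                {
                    key: s.freq_khz if key == "freq_khz" else s.level_db,
                    "mean_count": float(n_spk),
                    "mean_fsl_ms": mean_fsl_for(
                        dataset, neuron_id, lab, TONE_WINDOW_MS
                    ),
                }
            )
        return pd.DataFrame(rows).sort_values(key, ignore_index=True)

    iso = _curve(
        [(lab, s) for lab, s in tones.items() if s.level_db == 80.0], "freq_khz"
    )
    rate = _curve(
        [(lab, s) for lab, s in tones.items() if s.freq_khz == summ.cf_khz],
        "level_db",
    )
    return ResponseFunctions(iso, rate, summ.cf_khz)
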