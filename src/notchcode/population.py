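"""Synthetic tonotopic cortex: a generative model of layer-IV A1 units.

The generator stands in for the recorded bats.  It emulates, with
parameters stated in the field's units:

* a ~2 x 1 mm cortical sheet whose anterior-posterior axis carries a
  tonotopic gradient, characteristic frequencies (CF) 15-70 kHz, higher
  CFs anterior;
* minimum thresholds 20-60 dB SPL and V-shaped frequency tuning;
* first-spike latencies (FSL) at CF/80 dB SPL in the 10-35 ms range,
  lengthening off-CF and with decreasing level (amplitude-latency
  trading, default 1/3 ms/dB so a ~30-dB spectral notch lengthens FSL by
  ~10 ms);
* low spike counts (0-6 evoked spikes per stimulus), Gaussian first-spike
  jitter, a short burst after the first spike, and sparse spontaneous
  Poisson firing over a -50 to +250 ms epoch.

Neurons are generated independently; the recordings being emulated were
not simultaneous, so correlated noise across units is deliberately absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d

from .stimuli import (
    StimSpec,
    StimulusProtocol,
    Waveform,
    render_stimulus,
)

EPOCH_MS = (-50.0, 250.0)

CF_RANGE_KHZ = (15.0, 70.0)
THRESHOLD_RANGE_DB = (20.0, 60.0)
BASE_LATENCY_RANGE_MS = (10.0, 35.0)

#: Octave scatter of CF about the deterministic tonotopic map; sized so a
#: default population reproduces |R| ~ 0.87 for CF vs cortical position.
DEFAULT_CF_SCATTER_OCT = 0.35
#: ms scatter of base latency about its CF-dependent trend; sized so FSL vs
#: position correlates at roughly R ~ 0.55.
DEFAULT_LATENCY_SCATTER_MS = 5.0

#: Excitatory response area: a rounded tip (flat within +-2.5 kHz of CF at
#: the reference bandwidth) with steep flanks.  The resulting 10-dB
#: bandwidth of ~9 kHz matches sharply tuned bat A1 units (Q10 ~ 3-7).
TUNING_TIP_HALFWIDTH_KHZ = 2.5
TUNING_FLANK_DB_PER_KHZ = 5.0


@dataclass
class ModelNeuron:
    """Generative parameters of one tonotopic unit."""

    id: int
    pos_ap_mm: float  # anterior-posterior position, increasing anterior
    pos_ml_mm: float
    cf_khz: float
    threshold_db_spl: float
    base_latency_ms: float  # mean FSL at CF, 80 dB SPL
    tuning_slope_ms_per_oct: float = 5.0
    bandwidth_oct: float = 1.0
    trading_ms_per_db: float = 1.0 / 3.0
    jitter_sd_ms: float = 1.5
    spont_rate_hz: float = 1.0
    burst_mean_spikes: float = 2.0

    def __post_init__(self) -> None:
        lo, hi = CF_RANGE_KHZ
        if not lo <= self.cf_khz <= hi:
            raise ValueError(f"cf_khz {self.cf_khz} outside [{lo}, {hi}]")
        lo, hi = THRESHOLD_RANGE_DB
        if not lo <= self.threshold_db_spl <= hi:
            raise ValueError(f"threshold {self.threshold_db_spl} outside [{lo}, {hi}]")
        lo, hi = BASE_LATENCY_RANGE_MS
        if not lo <= self.base_latency_ms <= hi:
            raise ValueError(f"base latency {self.base_latency_ms} outside [{lo}, {hi}]")
        if self.trading_ms_per_db < 0:
            raise ValueError("trading_ms_per_db must be >= 0")


@dataclass
class PopulationModel:
    """A sampled sheet of model neurons."""

    neurons: list[ModelNeuron]
    extent_mm: float
    tonotopy_slope_khz_per_mm: float
    position_noise_sd: float  # CF scatter about the map, in octaves
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.neurons)

    def __iter__(self):
        return iter(self.neurons)

    def neuron(self, neuron_id: int) -> ModelNeuron:
        return self._by_id[neuron_id]

    def __post_init__(self) -> None:
        self._by_id = {n.id: n for n in self.neurons}

    def positions_posterior_mm(self) -> np.ndarray:
        """Distance from the anterior edge (the axis tonotopic maps are
        conventionally plotted on)."""
        return self.extent_mm - np.array([n.pos_ap_mm for n in self.neurons])

    def cfs_khz(self) -> np.ndarray:
        return np.array([n.cf_khz for n in self.neurons])


@dataclass
class SpikeTrain:
    """Sorted spike times (ms re stimulus onset) for one trial."""

    times_ms: np.ndarray
    neuron_id: int
    stimulus_id: str
    trial: int

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("spike times must be strictly sorted")
        if len(self.times_ms) and (
            self.times_ms[0] < EPOCH_MS[0] or self.times_ms[-1] > EPOCH_MS[1]
        ):
            raise ValueError(f"spike times outside the recorded epoch {EPOCH_MS}")


class Dataset:
    """Spike trains indexed by (neuron_id, stimulus_id, trial).

    The index is complete: every combination in the protocol exists, with
    an empty train where the neuron did not fire.
    """

    def __init__(
        self,
        trains: dict[tuple[int, str, int], np.ndarray],
        neuron_ids: list[int],
        protocol: StimulusProtocol,
        meta: dict | None = None,
    ):
        self.neuron_ids = list(neuron_ids)
        self.protocol = protocol
        self.meta = dict(meta or {})
        self._trains = {}
        for nid in self.neuron_ids:
            for label in protocol.stimuli:
                for trial in range(protocol.reps(label)):
                    key = (nid, label, trial)
                    self._trains[key] = np.asarray(
                        trains.get(key, ()), dtype=float
                    )

    @property
    def stimulus_ids(self) -> list[str]:
        return list(self.protocol.stimuli)

    def n_trials(self, stimulus_id: str) -> int:
        return self.protocol.reps(stimulus_id)

    def train(self, neuron_id: int, stimulus_id: str, trial: int) -> np.ndarray:
        return self._trains[(neuron_id, stimulus_id, trial)]

    def trains(self, neuron_id: int, stimulus_id: str) -> list[np.ndarray]:
        return [
            self._trains[(neuron_id, stimulus_id, t)]
            for t in range(self.n_trials(stimulus_id))
        ]

    def __len__(self) -> int:
        return len(self._trains)

    def items(self):
        return self._trains.items()

    def __eq__(self, other) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        if set(self._trains) != set(other._trains):
            return False
        return all(
            np.array_equal(v, other._trains[k]) for k, v in self._trains.items()
        )


def sample_population(
    n: int = 122,
    extent_mm: float = 2.0,
    cf_range_khz: tuple[float, float] = CF_RANGE_KHZ,
    seed: int | None = None,
    cf_scatter_oct: float = DEFAULT_CF_SCATTER_OCT,
    latency_scatter_ms: float = DEFAULT_LATENCY_SCATTER_MS,
    **neuron_defaults,
) -> PopulationModel:
    """Sample a tonotopic population over the cortical sheet.

    CF follows a log-linear map of anterior-posterior position (higher CF
    anterior) plus octave-scale scatter; base latency follows a decreasing
    trend with CF plus scatter; thresholds are uniform over 20-60 dB SPL.
    With zero scatter the CF-position map is strictly monotone.
    """
    if n < 1:
        raise ValueError("need at least one neuron")
    cf_lo, cf_hi = cf_range_khz
    if not (CF_RANGE_KHZ[0] <= cf_lo < cf_hi <= CF_RANGE_KHZ[1]):
        raise ValueError(f"cf_range_khz {cf_range_khz} outside {CF_RANGE_KHZ}")
    rng = np.random.default_rng(seed)
    pos_ap = np.sort(rng.uniform(0.0, extent_mm, n))[::-1]  # ids anterior-first
    pos_ml = rng.uniform(0.0, 1.0, n)
    span_oct = np.log2(cf_hi / cf_lo)
    log2cf = (
        np.log2(cf_lo)
        + (pos_ap / extent_mm) * span_oct
        + rng.normal(0.0, cf_scatter_oct, n)
    )
    cf = np.clip(2.0**log2cf, cf_lo, cf_hi)
    threshold = rng.uniform(*THRESHOLD_RANGE_DB, n)
    # FSL at CF lengthens toward low CFs (posterior), ~8 ms per octave below
    # the high-frequency edge, spanning the observed 10-35 ms range.
    base_latency = (
        10.0
        + 8.0 * np.log2(CF_RANGE_KHZ[1] / cf)
        + rng.normal(0.0, latency_scatter_ms, n)
    )
    base_latency = np.clip(base_latency, *BASE_LATENCY_RANGE_MS)
    neurons = [
        ModelNeuron(
            id=i,
            pos_ap_mm=float(pos_ap[i]),
            pos_ml_mm=float(pos_ml[i]),
            cf_khz=float(cf[i]),
            threshold_db_spl=float(threshold[i]),
            base_latency_ms=float(base_latency[i]),
            **neuron_defaults,
        )
        for i in range(n)
    ]
    slope = (cf_hi - cf_lo) / extent_mm
    return PopulationModel(neurons, extent_mm, slope, cf_scatter_oct, seed)


def sweep_arrival_time(spec: StimSpec, cf_khz: float) -> float | None:
    """Time (ms) at which a linear dFM's instantaneous frequency crosses CF.

    Returns None (flagged no-crossing) for CFs outside the sweep band.
    For the default 70->20 kHz, 10-ms sweep: t = (70 - cf) / 5 ms.
    """
    if spec.kind != "sweep":
        raise ValueError("sweep_arrival_time applies to sweep stimuli")
    if not spec.f_lo_khz <= cf_khz <= spec.f_hi_khz:
        return None
    rate_khz_per_ms = (spec.f_hi_khz - spec.f_lo_khz) / spec.dur_ms
    return (spec.f_hi_khz - cf_khz) / rate_khz_per_ms


class _SpectrumLevels:
    """Cached band-limited spectral levels of one stimulus.

    The level at a CF is the mean spectral power density over a +-1 kHz
    band around the CF, referenced to the stimulus's average density over
    its occupied bandwidth, and offset by the nominal level.  A flat dFM
    therefore reads ~80 dB SPL at any in-band CF; a CF inside a spectral
    notch reads lower by the band-limited notch attenuation (~28 dB for
    the 16-us two-glint stimulus at the comb null); a narrowband tone at
    the CF reads its own nominal level (the occupied-bandwidth reference
    is floored at the analysis band so concentrating all energy inside the
    band is not over-counted).
    """

    def __init__(self, w: Waveform, halfband_khz: float = 1.0):
        from scipy.ndimage import uniform_filter1d

        nfft = 1
        n = len(w.samples)
        while nfft < 64 * n:
            nfft *= 2
        power = np.abs(np.fft.rfft(w.samples, nfft)) ** 2
        self.freqs_khz = np.fft.rfftfreq(nfft, 1.0 / w.rate_hz) / 1e3
        df_khz = self.freqs_khz[1] - self.freqs_khz[0]
        # ~100-Hz spectral resolution, then +-halfband averaging
        power = uniform_filter1d(power, max(int(round(0.1 / df_khz)), 1))
        width = max(int(round(2 * halfband_khz / df_khz)), 1)
        self.band_density = uniform_filter1d(power, width)
        occupied_bins = int(np.sum(power >= power.max() / 100.0))
        self.ref_density = power.sum() / max(occupied_bins, width)
        self.level_db_spl = w.level_db_spl

    def level_at(self, freq_khz: float) -> float:
        idx = int(np.searchsorted(self.freqs_khz, freq_khz))
        idx = min(idx, len(self.freqs_khz) - 1)
        with np.errstate(divide="ignore"):
            rel = 10.0 * np.log10(self.band_density[idx] / self.ref_density)
        return self.level_db_spl + float(rel)


def effective_level_at_cf(
    neuron: ModelNeuron, stimulus: Waveform, halfband_khz: float = 1.0
) -> float:
    """Narrowband (+-1 kHz) spectral level of the stimulus at the neuron's
    CF, on the dB SPL scale of its nominal level."""
    return _SpectrumLevels(stimulus, halfband_khz).level_at(neuron.cf_khz)


def response_latency(
    neuron: ModelNeuron, freq_khz: float, level_db: float
) -> float:
    """Mean first-spike latency model (ms), before jitter.

    L = base + tuning_slope * |log2(f / CF)| + trading * (80 - level),
    clipped at zero: latency lengthens away from CF and as the effective
    level drops (amplitude-latency trading).
    """
    if not np.isfinite(level_db):
        raise ValueError("level must be finite")
    lat = (
        neuron.base_latency_ms
        + neuron.tuning_slope_ms_per_oct * abs(np.log2(freq_khz / neuron.cf_khz))
        + neuron.trading_ms_per_db * (80.0 - level_db)
    )
    return max(float(lat), 0.0)


def tone_drives_neuron(neuron: ModelNeuron, freq_khz: float, level_db: float) -> bool:
    """V-shaped excitatory response area with a rounded tip: a tone drives
    the neuron when its level clears threshold plus the off-CF flank
    attenuation.  ``bandwidth_oct`` scales the tuning width (1.0 = the
    reference ~9 kHz 10-dB bandwidth)."""
    excess_khz = max(
        abs(freq_khz - neuron.cf_khz)
        - TUNING_TIP_HALFWIDTH_KHZ * neuron.bandwidth_oct,
        0.0,
    )
    atten = TUNING_FLANK_DB_PER_KHZ / neuron.bandwidth_oct * excess_khz
    return level_db - atten >= neuron.threshold_db_spl


MAX_EVOKED_SPIKES = 6
_BURST_ISI_SHAPE = 4.0  # gamma shape for ~2 ms inter-spike intervals
_MIN_ISI_MS = 0.5


def _evoked_times(
    neuron: ModelNeuron, onset_ms: float, rng: np.random.Generator
) -> np.ndarray:
    first = onset_ms + rng.normal(0.0, neuron.jitter_sd_ms)
    # burst: 1 + truncated-geometric extra spikes, mean total ~burst_mean
    p = 1.0 / max(neuron.burst_mean_spikes, 1.0)
    n_extra = min(int(rng.geometric(p)) - 1, MAX_EVOKED_SPIKES - 1)
    isis = np.maximum(
        rng.gamma(_BURST_ISI_SHAPE, 2.0 / _BURST_ISI_SHAPE, n_extra), _MIN_ISI_MS
    )
    return first + np.concatenate(([0.0], np.cumsum(isis)))


def _spont_times(neuron: ModelNeuron, rng: np.random.Generator) -> np.ndarray:
    dur_s = (EPOCH_MS[1] - EPOCH_MS[0]) / 1e3
    n = rng.poisson(neuron.spont_rate_hz * dur_s)
    return rng.uniform(*EPOCH_MS, n)


def simulate_response(
    neuron: ModelNeuron,
    spec: StimSpec,
    n_trials: int,
    seed=None,
    effective_level_db: float | None = None,
) -> list[SpikeTrain]:
    """Simulate spike trains of one neuron to one stimulus.

    If the stimulus drives the neuron above threshold, each trial carries a
    first spike at (sweep arrival at CF) + latency-model mean + Gaussian
    jitter, followed by a short burst capped at 6 evoked spikes; spontaneous
    Poisson spikes cover the whole epoch in every trial.

    ``effective_level_db`` lets the caller supply a precomputed band-limited
    level for sweep stimuli (otherwise it is computed from the rendered
    waveform).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec.kind == "tone":
        onset = 0.0
        drives = tone_drives_neuron(neuron, spec.freq_khz, spec.level_db)
        mean_latency = response_latency(neuron, spec.freq_khz, spec.level_db)
    else:
        arrival = sweep_arrival_time(spec, neuron.cf_khz)
        if effective_level_db is None:
            effective_level_db = effective_level_at_cf(
                neuron, render_stimulus(spec)
            )
        drives = arrival is not None and effective_level_db >= neuron.threshold_db_spl
        onset = arrival if arrival is not None else 0.0
        mean_latency = response_latency(neuron, neuron.cf_khz, effective_level_db)
    out = []
    for trial in range(n_trials):
        parts = [_spont_times(neuron, rng)]
        if drives:
            parts.append(_evoked_times(neuron, onset + mean_latency, rng))
        times = np.concatenate(parts)
        times = np.unique(times[(times >= EPOCH_MS[0]) & (times <= EPOCH_MS[1])])
        out.append(SpikeTrain(times, neuron.id, spec.label, trial))
    return out


def simulate_dataset(
    model: PopulationModel, protocol: StimulusProtocol, seed: int | None = None
) -> Dataset:
    """Simulate the full population against a protocol.

    Reproducible under ``seed``: each (neuron, stimulus) pair draws from its
    own deterministic random stream, so results are independent of
    iteration order.
    """
    levels = {}
    for label, spec in protocol.stimuli.items():
        if spec.kind == "sweep":
            levels[label] = _SpectrumLevels(render_stimulus(spec))
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(model.neurons) * len(protocol.stimuli))
    trains: dict[tuple[int, str, int], np.ndarray] = {}
    k = 0
    for neuron in model.neurons:
        for label, spec in protocol.stimuli.items():
            rng = np.random.default_rng(streams[k])
            k += 1
            eff = levels[label].level_at(neuron.cf_khz) if label in levels else None
            for st in simulate_response(
                neuron, spec, protocol.reps(label), rng, effective_level_db=eff
            ):
                trains[(neuron.id, label, st.trial)] = st.times_ms
    meta = {
        "seed": seed,
        "n_neurons": len(model.neurons),
        "population_seed": model.seed,
    }
    return Dataset(trains, [n.id for n in model.neurons], protocol, meta)
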