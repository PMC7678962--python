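"""Delimited-text I/O for spike datasets and population tables.

Unit contract across all files: times in ms relative to stimulus onset,
positions in mm with anterior positive, frequencies in kHz, levels in
dB SPL.  Spike tables are TSV with header
``neuron_id  stimulus_id  trial  spike_time_ms``.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .population import Dataset, ModelNeuron, PopulationModel
from .stimuli import StimulusProtocol

SPIKE_COLUMNS = ["neuron_id", "stimulus_id", "trial", "spike_time_ms"]


def write_spike_table(dataset: Dataset, path: str | Path) -> None:
    path = Path(path)
    rows = []
    for (nid, sid, trial), times in sorted(dataset.items(), key=lambda kv: kv[0]):
        for t in times:
            rows.append((nid, sid, trial, t))
    df = pd.DataFrame(rows, columns=SPIKE_COLUMNS)
    # no float_format: shortest round-trip repr keeps read/write lossless
    df.to_csv(path, sep="\t", index=False)


def read_spike_table(
    path: str | Path, protocol: StimulusProtocol, neuron_ids: list[int] | None = None
) -> Dataset:
    """Read a spike table back into a validated Dataset.

    Malformed rows raise with the offending line number; unsorted spike
    times are sorted with a warning.  The protocol supplies the complete
    (stimulus, trial) index, so neurons silent for a stimulus still get
    their empty trains.
    """
    path = Path(path)
    groups: dict[tuple[int, str, int], list[float]] = {}
    seen_neurons = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != SPIKE_COLUMNS:
            raise ValueError(
                f"{path}:1: expected header {SPIKE_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            try:
                nid, trial, t = int(row[0]), int(row[2]), float(row[3])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
            sid = row[1]
            if sid not in protocol.stimuli:
                raise ValueError(f"{path}:{lineno}: unknown stimulus {sid!r}")
            groups.setdefault((nid, sid, trial), []).append(t)
            seen_neurons.add(nid)
    trains = {}
    for key, times in groups.items():
        arr = np.array(times)
        if np.any(np.diff(arr) < 0):
            warnings.warn(f"unsorted spike times for {key}; sorting", stacklevel=2)
            arr = np.sort(arr)
        trains[key] = arr
    if neuron_ids is None:
        neuron_ids = sorted(seen_neurons)
    return Dataset(trains, neuron_ids, protocol, {"source": str(path)})


POPULATION_COLUMNS = [
    "neuron_id", "pos_ap_mm", "pos_ml_mm", "cf_khz", "threshold_db",
    "base_latency_ms", "tuning_slope_ms_per_oct", "bandwidth_oct",
    "trading_ms_per_db", "jitter_sd_ms", "spont_rate_hz", "burst_mean_spikes",
]


def write_population_table(model: PopulationModel, path: str | Path) -> None:
    rows = [
        {
            "neuron_id": n.id,
            "pos_ap_mm": n.pos_ap_mm,
            "pos_ml_mm": n.pos_ml_mm,
            "cf_khz": n.cf_khz,
            "threshold_db": n.threshold_db_spl,
            "base_latency_ms": n.base_latency_ms,
            "tuning_slope_ms_per_oct": n.tuning_slope_ms_per_oct,
            "bandwidth_oct": n.bandwidth_oct,
            "trading_ms_per_db": n.trading_ms_per_db,
            "jitter_sd_ms": n.jitter_sd_ms,
            "spont_rate_hz": n.spont_rate_hz,
            "burst_mean_spikes": n.burst_mean_spikes,
        }
        for n in model
    ]
    df = pd.DataFrame(rows, columns=POPULATION_COLUMNS)
    header = (
        f"# extent_mm={model.extent_mm} "
        f"tonotopy_slope_khz_per_mm={model.tonotopy_slope_khz_per_mm} "
        f"position_noise_sd={model.position_noise_sd} seed={model.seed}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_population_table(path: str | Path) -> PopulationModel:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh, sep="\t")
    meta = dict(
        kv.split("=") for kv in header.lstrip("# ").split() if "=" in kv
    )
    neurons = [
        ModelNeuron(
            id=int(r.neuron_id),
            pos_ap_mm=r.pos_ap_mm,
            pos_ml_mm=r.pos_ml_mm,
            cf_khz=r.cf_khz,
            threshold_db_spl=r.threshold_db,
            base_latency_ms=r.base_latency_ms,
            tuning_slope_ms_per_oct=r.tuning_slope_ms_per_oct,
            bandwidth_oct=r.bandwidth_oct,
            trading_ms_per_db=r.trading_ms_per_db,
            jitter_sd_ms=r.jitter_sd_ms,
            spont_rate_hz=r.spont_rate_hz,
            burst_mean_spikes=r.burst_mean_spikes,
        )
        for r in df.itertuples()
    ]
    seed = meta.get("seed", "None")
    return PopulationModel(
        neurons,
        extent_mm=float(meta.get("extent_mm", 2.0)),
        tonotopy_slope_khz_per_mm=float(meta.get("tonotopy_slope_khz_per_mm", 27.5)),
        position_noise_sd=float(meta.get("position_noise_sd", 0.35)),
        seed=None if seed == "None" else int(seed),
    )
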