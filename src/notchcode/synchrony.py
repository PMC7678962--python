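"""SPIKE-synchronization between spike trains and population sync matrices.

The spike-synchronization index c counts, for every spike, whether it has a
quasi-simultaneous partner in the other train under an adaptive coincidence
window: for spike i of train A matched to its nearest spike j of train B,

    tau_ij = 0.5 * min(isi_A around i, isi_B around j)

where the local inter-spike interval of a spike is the smaller of its two
adjacent ISIs.  c is the number of coincident spikes in both trains divided
by the total number of spikes; it is 0 iff there are no coincidences and 1
iff every spike has a matching partner.

Edge conventions (the published definition delegates these to the cited
toolbox): a first/last spike uses its single available adjacent interval; a
single-spike train borrows the partner's local interval; two single-spike
trains fall back to a fixed 5-ms window; a pair with any empty train has
c = 0, and two empty trains are defined as c = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Coincidence window (ms) when both trains carry a single spike.
SINGLETON_FALLBACK_MS = 5.0

#: Analysis epoch for population synchrony, matching the MI window.
SYNC_WINDOW_MS = (0.0, 80.0)


def _local_intervals(t: np.ndarray) -> np.ndarray:
    """Per-spike local ISI: min of the adjacent intervals, the single
    available one at the edges, +inf for a singleton (resolved by caller)."""
    n = len(t)
    if n < 2:
        return np.full(n, np.inf)
    isi = np.diff(t)
    prev = np.concatenate(([np.inf], isi))
    nxt = np.concatenate((isi, [np.inf]))
    return np.minimum(prev, nxt)


def pairwise_spike_sync(
    train_a: np.ndarray,
    train_b: np.ndarray,
    fallback_ms: float = SINGLETON_FALLBACK_MS,
) -> float:
    """Spike-synchronization index c in [0, 1] between two sorted trains."""
    a = np.asarray(train_a, dtype=float)
    b = np.asarray(train_b, dtype=float)
    if len(a) + len(b) == 0:
        return 0.0  # both empty: no spikes, defined as zero synchrony
    if len(a) == 0 or len(b) == 0:
        return 0.0
    loc_a = _local_intervals(a)
    loc_b = _local_intervals(b)
    coincident = 0
    for t, loc_t, u, loc_u in ((a, loc_a, b, loc_b), (b, loc_b, a, loc_a)):
        j = np.clip(np.searchsorted(u, t), 1, len(u) - 1) if len(u) > 1 else np.zeros(
            len(t), dtype=int
        )
        if len(u) > 1:
            j = np.where(np.abs(u[j] - t) < np.abs(u[j - 1] - t), j, j - 1)
        dist = np.abs(u[j] - t)
        tau = 0.5 * np.minimum(loc_t, loc_u[j])
        tau = np.where(np.isinf(tau), 0.5 * fallback_ms, tau)
        coincident += int(np.sum(dist < tau))
    return coincident / (len(a) + len(b))


@dataclass
class SyncMatrix:
    """Trial-averaged pairwise spike-synchronization of a population.

    Symmetric, unit diagonal (a train is perfectly synchronous with
    itself), entries in [0, 1].  Neurons are ordered by descending CF then
    anterior position, matching the tonotopic display convention.
    """

    values: np.ndarray
    neuron_ids: list[int]
    stimulus_id: str
    n_trials: int

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.neuron_ids):
            raise ValueError("matrix must be square over the neuron order")
        if not np.allclose(v, v.T):
            raise ValueError("sync matrix must be symmetric")
        if np.any((v < 0) | (v > 1)):
            raise ValueError("sync values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.neuron_ids, columns=self.neuron_ids)


def _neuron_order(dataset, population) -> list[int]:
    if population is None:
        return list(dataset.neuron_ids)
    key = {n.id: (-n.cf_khz, -n.pos_ap_mm) for n in population}
    return sorted(dataset.neuron_ids, key=lambda nid: key[nid])


def sync_matrix(
    dataset,
    stimulus_id: str,
    population=None,
    window: tuple[float, float] = SYNC_WINDOW_MS,
    fallback_ms: float = SINGLETON_FALLBACK_MS,
) -> SyncMatrix:
    """Mean pairwise synchronization matrix for one stimulus.

    Trains of different neurons are paired by trial index (the recordings
    being emulated were aligned to stimulus onset, not simultaneous); a
    matrix is computed per trial and averaged over trials.
    """
    order = _neuron_order(dataset, population)
    n_trials = dataset.n_trials(stimulus_id)
    if n_trials < 1:
        raise ValueError(f"no trials recorded for stimulus {stimulus_id!r}")
    lo, hi = window
    clipped = {}
    for nid in order:
        for trial in range(n_trials):
            t = dataset.train(nid, stimulus_id, trial)
            clipped[(nid, trial)] = t[(t >= lo) & (t <= hi)]
    n = len(order)
    acc = np.zeros((n, n))
    for trial in range(n_trials):
        for i in range(n):
            ti = clipped[(order[i], trial)]
            for j in range(i + 1, n):
                c = pairwise_spike_sync(ti, clipped[(order[j], trial)], fallback_ms)
                acc[i, j] += c
                acc[j, i] += c
    values = acc / n_trials
    np.fill_diagonal(values, 1.0)
    return SyncMatrix(values, order, stimulus_id, n_trials)


def group_sync_by_cf(
    matrix: SyncMatrix, cf_labels: dict[int, float]
) -> pd.DataFrame:
    """Block means of the sync matrix over CF groups.

    Diagonal (within-group) blocks average the off-diagonal entries only,
    so self-synchrony does not inflate within-group values.
    """
    missing = set(matrix.neuron_ids) - set(cf_labels)
    if missing:
        raise ValueError(f"cf_labels missing neurons {sorted(missing)}")
    groups = sorted({cf_labels[nid] for nid in matrix.neuron_ids}, reverse=True)
    idx = {
        g: [i for i, nid in enumerate(matrix.neuron_ids) if cf_labels[nid] == g]
        for g in groups
    }
    out = pd.DataFrame(index=groups, columns=groups, dtype=float)
    for gi in groups:
        for gj in groups:
            block = matrix.values[np.ix_(idx[gi], idx[gj])]
            if gi == gj:
                mask = ~np.eye(len(idx[gi]), dtype=bool)
                out.loc[gi, gj] = (
                    float(block[mask].mean()) if mask.any() else float("nan")
                )
            else:
                out.loc[gi, gj] = float(block.mean())
    return out
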