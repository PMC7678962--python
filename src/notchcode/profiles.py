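"""Tonotopic activation profiles, per-CF FSL summaries, and notch reports.

A flat-spectrum dFM activates the tonotopic sheet sequentially: high-CF
(anterior) neurons fire first, both because the downward sweep reaches
their CF earlier and because their latencies are shorter.  A spectral
notch delays the neurons tuned to the notch frequency, breaking the
sequence; these functions quantify that disruption at the population
level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .population import Dataset, PopulationModel
from .receptive import SWEEP_WINDOW_MS, TONE_WINDOW_MS, mean_fsl_for

CF_GROUP_STEP_KHZ = 5.0


@dataclass
class ActivationProfile:
    """Per-neuron rasters ordered along the tonotopic axis (descending CF,
    then anterior position), aligned to stimulus onset."""

    neuron_ids: list[int]
    cfs_khz: list[float]
    rasters: list[list[np.ndarray]]  # per neuron: per trial spike times
    stimulus_id: str


def _tonotopic_order(dataset: Dataset, population: PopulationModel) -> list[int]:
    key = {n.id: (-n.cf_khz, -n.pos_ap_mm) for n in population}
    return sorted(dataset.neuron_ids, key=lambda nid: key[nid])


def activation_profile(
    dataset: Dataset, stimulus_id: str, population: PopulationModel
) -> ActivationProfile:
    """Tonotopically ordered raster structure for one stimulus.

    The ordering is deterministic and independent of dataset iteration
    order; an empty dataset yields an empty, valid profile.
    """
    order = _tonotopic_order(dataset, population)
    return ActivationProfile(
        neuron_ids=order,
        cfs_khz=[population.neuron(nid).cf_khz for nid in order],
        rasters=[dataset.trains(nid, stimulus_id) for nid in order],
        stimulus_id=stimulus_id,
    )


def cf_group(cf_khz: float, step: float = CF_GROUP_STEP_KHZ) -> float:
    """Nearest value on the 5-kHz stimulus grid (the Fig-style grouping)."""
    return float(np.round(cf_khz / step) * step)


def fsl_by_cf_group(
    dataset: Dataset,
    stimulus_id: str,
    population: PopulationModel,
    window: tuple[float, float] = SWEEP_WINDOW_MS,
) -> pd.DataFrame:
    """Median and quartiles of per-neuron mean FSL, grouped by CF grid value.

    Neurons whose FSL is undefined for the stimulus (no evoked response)
    are dropped; groups left empty are reported with NaN summaries.
    """
    rows = []
    for nid in dataset.neuron_ids:
        rows.append(
            {
                "neuron_id": nid,
                "cf_group_khz": cf_group(population.neuron(nid).cf_khz),
                "mean_fsl_ms": mean_fsl_for(dataset, nid, stimulus_id, window),
            }
        )
    per_neuron = pd.DataFrame(rows)
    out = []
    for g, sub in per_neuron.groupby("cf_group_khz"):
        fsl = sub["mean_fsl_ms"].dropna()
        out.append(
            {
                "cf_group_khz": g,
                "n_neurons": len(sub),
                "n_defined": len(fsl),
                "median_fsl_ms": float(fsl.median()) if len(fsl) else float("nan"),
                "q25_fsl_ms": float(fsl.quantile(0.25)) if len(fsl) else float("nan"),
                "q75_fsl_ms": float(fsl.quantile(0.75)) if len(fsl) else float("nan"),
            }
        )
    return (
        pd.DataFrame(out)
        .sort_values("cf_group_khz", ascending=False, ignore_index=True)
    )


def tonotopy_stats(
    population: PopulationModel, tuning: pd.DataFrame
) -> dict[str, float]:
    """Pearson correlations of measured CF and FSL against cortical
    position along the anterior-posterior axis (posterior distance
    increasing caudally, the axis the maps are plotted on).

    Expected signs for a tonotopic sheet: CF vs posterior strongly
    negative, FSL vs posterior positive.
    """
    if len(tuning) < 3:
        raise ValueError("need at least 3 neurons for correlation")
    pos = {
        n.id: population.extent_mm - n.pos_ap_mm for n in population
    }
    t = tuning[tuning["responsive"]].copy() if "responsive" in tuning else tuning.copy()
    t["pos_posterior_mm"] = t["neuron_id"].map(pos)
    if t["pos_posterior_mm"].nunique() < 2:
        return {"r_cf": float("nan"), "p_cf": float("nan"),
                "r_fsl": float("nan"), "p_fsl": float("nan"),
                "n": len(t), "degenerate": True}
    r_cf, p_cf = stats.pearsonr(t["pos_posterior_mm"], t["cf_khz"])
    fsl = t.dropna(subset=["mean_fsl_ms"])
    r_fsl, p_fsl = stats.pearsonr(fsl["pos_posterior_mm"], fsl["mean_fsl_ms"])
    return {
        "r_cf": float(r_cf),
        "p_cf": float(p_cf),
        "r_fsl": float(r_fsl),
        "p_fsl": float(p_fsl),
        "n": int(len(t)),
        "degenerate": False,
    }


def latency_shift_report(
    fm_dataset: Dataset,
    tone_dataset: Dataset,
    population: PopulationModel,
    tuning: pd.DataFrame,
    groups: tuple[float, ...] = (30.0, 45.0),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Per-neuron spike-count and FSL changes of each dFM relative to the
    CF-tone response, with group tests.

    For every neuron in a CF group, the reference is its response to the
    CF tone at 80 dB SPL (delta = 0 by construction); deltas are reported
    for each dFM.  Within each group, a one-way ANOVA across the three
    dFMs with a post hoc Tukey HSD is run separately for count and FSL
    deltas.  Spike counts are raw (no spontaneous-rate subtraction).
    Neurons with an undefined FSL in any condition are excluded from the
    FSL contrast (logged in the report), not from the count contrast.
    """
    from .receptive import _cf_tone_label

    dfms = list(fm_dataset.stimulus_ids)
    tuned = tuning.set_index("neuron_id")
    rows = []
    for nid in fm_dataset.neuron_ids:
        if nid not in tuned.index or not tuned.loc[nid, "responsive"]:
            continue
        cf = float(tuned.loc[nid, "cf_khz"])
        g = cf_group(cf)
        if g not in groups:
            continue
        ref_label = _cf_tone_label(tone_dataset, cf)
        ref_trains = tone_dataset.trains(nid, ref_label)
        ref_count = float(
            np.mean([np.sum((t >= 0) & (t < TONE_WINDOW_MS[1])) for t in ref_trains])
        )
        ref_fsl = mean_fsl_for(tone_dataset, nid, ref_label, TONE_WINDOW_MS)
        for sid in dfms:
            trains = fm_dataset.trains(nid, sid)
            count = float(
                np.mean(
                    [np.sum((t >= 0) & (t < SWEEP_WINDOW_MS[1])) for t in trains]
                )
            )
            fsl = mean_fsl_for(fm_dataset, nid, sid)
            rows.append(
                {
                    "neuron_id": nid,
                    "cf_group_khz": g,
                    "stimulus_id": sid,
                    "delta_count": count - ref_count,
                    "delta_fsl_ms": fsl - ref_fsl,
                }
            )
    table = pd.DataFrame(rows)
    report: dict = {"alpha": alpha, "groups": {}, "excluded_from_fsl": []}
    for g in groups:
        sub = table[table["cf_group_khz"] == g]
        neurons = sub["neuron_id"].unique()
        # FSL contrast excludes neurons undefined in any condition
        defined = [
            nid
            for nid in neurons
            if np.isfinite(sub.loc[sub.neuron_id == nid, "delta_fsl_ms"]).all()
        ]
        report["excluded_from_fsl"].extend(sorted(set(neurons) - set(defined)))
        gres: dict = {"n_neurons": int(len(neurons)), "n_fsl_defined": len(defined)}
        for metric, pool in (
            ("delta_count", sub),
            ("delta_fsl_ms", sub[sub.neuron_id.isin(defined)]),
        ):
            samples = [
                pool.loc[pool.stimulus_id == sid, metric].to_numpy() for sid in dfms
            ]
            entry: dict = {
                "means": {sid: float(np.mean(s)) if len(s) else float("nan")
                          for sid, s in zip(dfms, samples)}
            }
            if min(len(s) for s in samples) >= 3:
                f, p = stats.f_oneway(*samples)
                tk = stats.tukey_hsd(*samples)
                entry.update(
                    anova_F=float(f),
                    anova_p=float(p),
                    significant=bool(p < alpha),
                    tukey_p={
                        f"{dfms[i]}-vs-{dfms[j]}": float(tk.pvalue[i, j])
                        for i in range(len(dfms))
                        for j in range(i + 1, len(dfms))
                    },
                )
            else:
                entry["significant"] = None
            gres[metric] = entry
        report["groups"][g] = gres
    return table, report
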