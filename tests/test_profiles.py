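import numpy as np
import pandas as pd
import pytest

from notchcode import (
    activation_profile,
    build_fm_protocol,
    build_tone_protocol,
    cf_group,
    fsl_by_cf_group,
    latency_shift_report,
    sample_population,
    simulate_dataset,
    tonotopy_stats,
    tuning_table,
)
from notchcode.population import Dataset, ModelNeuron, PopulationModel


def linear_map_population(n=10, extent=2.0):
    """Hand-built population with CF exactly linear in position."""
    neurons = [
        ModelNeuron(
            id=i,
            pos_ap_mm=extent * i / (n - 1),
            pos_ml_mm=0.5,
            cf_khz=20.0 + 50.0 * i / (n - 1),
            threshold_db_spl=30.0,
            base_latency_ms=30.0 - 15.0 * i / (n - 1),
        )
        for i in range(n)
    ]
    return PopulationModel(neurons, extent, 25.0, 0.0, seed=None)


class TestActivationProfile:
    def test_ordering_deterministic_and_tonotopic(
        self, small_population, small_fm_dataset
    ):
        p1 = activation_profile(small_fm_dataset, "FM", small_population)
        p2 = activation_profile(small_fm_dataset, "FM", small_population)
        assert p1.neuron_ids == p2.neuron_ids
        assert p1.cfs_khz == sorted(p1.cfs_khz, reverse=True)
        assert len(p1.rasters) == len(small_population)

    def test_empty_dataset_valid_profile(self, small_population):
        ds = Dataset({}, [n.id for n in small_population], build_fm_protocol(seed=0))
        prof = activation_profile(ds, "FM", small_population)
        assert all(
            all(len(t) == 0 for t in trials) for trials in prof.rasters
        )

    def test_high_cf_groups_fire_first_for_flat_sweep(
        self, small_population, small_fm_dataset
    ):
        """Sequential activation: group-mean FSL increases from high-CF
        (anterior) to low-CF (posterior) groups."""
        prof = fsl_by_cf_group(small_fm_dataset, "FM", small_population)
        prof = prof.dropna(subset=["median_fsl_ms"])
        from scipy.stats import spearmanr

        rho, _ = spearmanr(prof["cf_group_khz"], prof["median_fsl_ms"])
        assert rho < -0.7


class TestFslByCfGroup:
    def test_single_neuron_group_median_is_its_fsl(self):
        from notchcode import mean_fsl_for

        pop = PopulationModel(
            [
                ModelNeuron(
                    id=0, pos_ap_mm=1.0, pos_ml_mm=0.5, cf_khz=40.0,
                    threshold_db_spl=30.0, base_latency_ms=15.0,
                    jitter_sd_ms=0.0, spont_rate_hz=0.0,
                )
            ],
            2.0, 25.0, 0.0, None,
        )
        ds = simulate_dataset(pop, build_fm_protocol(reps=10, seed=0), seed=1)
        out = fsl_by_cf_group(ds, "FM", pop)
        row = out[out.cf_group_khz == 40.0].iloc[0]
        assert row.median_fsl_ms == pytest.approx(mean_fsl_for(ds, 0, "FM"))

    def test_identical_fsls_zero_iqr(self):
        pop = PopulationModel(
            [
                ModelNeuron(
                    id=i, pos_ap_mm=1.0, pos_ml_mm=0.5, cf_khz=40.0,
                    threshold_db_spl=30.0, base_latency_ms=15.0,
                    jitter_sd_ms=0.0, spont_rate_hz=0.0,
                )
                for i in range(4)
            ],
            2.0, 25.0, 0.0, None,
        )
        ds = simulate_dataset(pop, build_fm_protocol(reps=5, seed=0), seed=1)
        out = fsl_by_cf_group(ds, "FM", pop)
        row = out[out.cf_group_khz == 40.0].iloc[0]
        assert row.q75_fsl_ms - row.q25_fsl_ms == pytest.approx(0.0)


class TestTonotopyStats:
    def test_perfect_linear_gradient(self):
        pop = linear_map_population()
        tuning = pd.DataFrame(
            {
                "neuron_id": [n.id for n in pop],
                "cf_khz": [n.cf_khz for n in pop],
                "mean_fsl_ms": [n.base_latency_ms for n in pop],
                "responsive": True,
            }
        )
        out = tonotopy_stats(pop, tuning)
        assert out["r_cf"] == pytest.approx(-1.0)
        assert out["r_fsl"] == pytest.approx(1.0)

    def test_permuted_positions_give_weak_correlation(self):
        rng = np.random.default_rng(0)
        pop = linear_map_population(40)
        perm = rng.permutation([n.pos_ap_mm for n in pop])
        for n, p in zip(pop, perm):
            n.pos_ap_mm = float(p)
        tuning = pd.DataFrame(
            {
                "neuron_id": [n.id for n in pop],
                "cf_khz": [n.cf_khz for n in pop],
                "mean_fsl_ms": [n.base_latency_ms for n in pop],
                "responsive": True,
            }
        )
        out = tonotopy_stats(pop, tuning)
        assert abs(out["r_cf"]) < 0.4

    def test_rejects_too_few_neurons(self):
        pop = linear_map_population(3)
        with pytest.raises(ValueError):
            tonotopy_stats(pop, pd.DataFrame({"neuron_id": [0]}))

    def test_constant_positions_flagged_degenerate(self):
        pop = linear_map_population(5)
        for n in pop:
            n.pos_ap_mm = 1.0
        tuning = pd.DataFrame(
            {
                "neuron_id": [n.id for n in pop],
                "cf_khz": [n.cf_khz for n in pop],
                "mean_fsl_ms": [n.base_latency_ms for n in pop],
                "responsive": True,
            }
        )
        assert tonotopy_stats(pop, tuning)["degenerate"]


class TestLatencyShiftReport:
    def test_flat_vs_flat_deltas_vanish(self):
        """All three 'dFMs' physically identical: the between-dFM FSL and
        count differences must be ~0 and non-significant."""
        pop = sample_population(
            30, seed=2, jitter_sd_ms=0.5, spont_rate_hz=0.0
        )
        protocol = build_fm_protocol(
            delays_us={"FM": 0.0, "Notch30": 0.0, "Notch45": 0.0},
            reps=15, seed=3,
        )
        fm_ds = simulate_dataset(pop, protocol, seed=4)
        tone_ds = simulate_dataset(pop, build_tone_protocol(seed=5), seed=6)
        tuning = tuning_table(tone_ds)
        table, report = latency_shift_report(
            fm_ds, tone_ds, pop, tuning, groups=tuple(
                sorted({cf_group(n.cf_khz) for n in pop})
            ),
        )
        checked = 0
        for g, rep in report["groups"].items():
            means = rep["delta_fsl_ms"]["means"]
            if rep["n_fsl_defined"] < 3 or any(
                np.isnan(v) for v in means.values()
            ):
                continue  # groups outside the sweep band never respond
            checked += 1
            spread = max(means.values()) - min(means.values())
            assert spread < 1.0
            if rep["delta_fsl_ms"].get("significant") is not None:
                assert not rep["delta_fsl_ms"]["significant"]
        assert checked >= 2

    def test_pure_function_of_inputs(self, small_population, small_fm_dataset):
        tone_ds = simulate_dataset(
            small_population, build_tone_protocol(seed=6), seed=7
        )
        tuning = tuning_table(tone_ds)
        t1, r1 = latency_shift_report(small_fm_dataset, tone_ds, small_population, tuning)
        t2, r2 = latency_shift_report(small_fm_dataset, tone_ds, small_population, tuning)
        pd.testing.assert_frame_equal(t1, t2)
        assert r1 == r2
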