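import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_

from notchcode import (
    NotchResponseModel,
    bias_vs_trials,
    compare_codes,
    discretize_responses,
    plugin_mi,
    qe_bias_correction,
    shuffle_correction,
)
from notchcode.information import NO_SPIKE, _independent_mi

from .oracles import brute_mi_bits


def table(stimuli, rates, fsl_bins):
    n = len(stimuli)
    return pd.DataFrame(
        {
            "stimulus_id": stimuli,
            "trial": list(range(n)),
            "rate": rates,
            "fsl_bin": fsl_bins,
        }
    )


def random_table(rng, n_trials=12, n_rates=4, n_bins=5):
    n = 2 * n_trials
    return table(
        np.repeat(["a", "b"], n_trials),
        rng.integers(0, n_rates, n),
        rng.integers(0, n_bins, n),
    )


class TestPluginMI:
    def test_noiseless_binary_mapping_is_one_bit(self):
        t = table(["a"] * 4 + ["b"] * 4, [1] * 4 + [3] * 4, [0] * 8)
        assert plugin_mi(t, "rate") == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_2x2_closed_form(self):
        # P(s,r) = {0.4, 0.1; 0.1, 0.4} -> I = 1 - H_b(0.2)
        t = table(
            ["a"] * 5 + ["b"] * 5, [0] * 4 + [1] + [0] + [1] * 4, [0] * 10
        )
        h_b = -(0.2 * math.log2(0.2) + 0.8 * math.log2(0.8))
        assert plugin_mi(t, "rate") == pytest.approx(1 - h_b, abs=1e-12)

    def test_stimulus_independent_response_is_zero(self):
        t = table(["a", "a", "b", "b"], [2, 3, 2, 3], [1, 4, 1, 4])
        for code in ("rate", "fsl", "joint"):
            assert plugin_mi(t, code) == pytest.approx(0.0, abs=1e-12)

    def test_rejects_single_stimulus(self):
        t = table(["a"] * 4, [0, 1, 0, 1], [0] * 4)
        with pytest.raises(ValueError):
            plugin_mi(t, "rate")

    @pytest.mark.parametrize("code", ["rate", "fsl", "joint"])
    def test_matches_direct_summation_oracle(self, rng, code):
        for _ in range(20):
            t = random_table(rng)
            if code == "rate":
                resp = t["rate"]
            elif code == "fsl":
                resp = t["fsl_bin"]
            else:
                resp = list(zip(t["rate"], t["fsl_bin"]))
            expected = brute_mi_bits(zip(t["stimulus_id"], resp))
            assert plugin_mi(t, code) == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_response_relabeling(self, rng):
        t = random_table(rng)
        relabeled = t.copy()
        relabeled["rate"] = 7 - t["rate"]  # bijective relabeling
        assert plugin_mi(t, "rate") == pytest.approx(
            plugin_mi(relabeled, "rate"), abs=1e-12
        )

    def test_joint_refines_single_codes(self, rng):
        # exact plug-in joint MI can never fall below either marginal code
        for _ in range(10):
            t = random_table(rng)
            j = plugin_mi(t, "joint")
            assert j >= plugin_mi(t, "rate") - 1e-12
            assert j >= plugin_mi(t, "fsl") - 1e-12


class TestDiscretize:
    def test_first_spike_bins_and_no_spike(self, small_fm_dataset):
        t = discretize_responses(
            small_fm_dataset, small_fm_dataset.neuron_ids[0], ["FM", "Notch30"]
        )
        assert len(t) == 60
        ds = small_fm_dataset
        nid = ds.neuron_ids[0]
        for row in t.itertuples():
            train = ds.train(nid, row.stimulus_id, row.trial)
            inwin = train[(train >= 0) & (train < 80.0)]
            assert row.rate == len(inwin)
            if len(inwin):
                assert row.fsl_bin == int(inwin[0] // 2)
            else:
                assert row.fsl_bin == NO_SPIKE

    def test_rejects_unknown_stimulus(self, small_fm_dataset):
        with pytest.raises(ValueError, match="unknown"):
            discretize_responses(
                small_fm_dataset, small_fm_dataset.neuron_ids[0], ["Notch99"]
            )


class TestQECorrection:
    def test_noiseless_mapping_needs_no_correction(self):
        t = table(
            np.repeat(["a", "b"], 16), [1] * 16 + [3] * 16, [2] * 16 + [9] * 16
        )
        raw = plugin_mi(t, "joint")
        assert qe_bias_correction(t, "joint") == pytest.approx(raw, abs=1e-9)

    def test_zero_information_corrected_toward_zero(self):
        model = NotchResponseModel(
            fsl_mean_ms=(18.0, 18.0), respond_prob=(0.9, 0.9)
        )
        rng = np.random.default_rng(3)
        raw, qe = [], []
        for k in range(10):
            t = model.sample(30, rng)
            raw.append(plugin_mi(t, "joint"))
            qe.append(qe_bias_correction(t, "joint", seed=k))
        assert abs(np.mean(qe)) < np.mean(raw)
        assert abs(np.mean(qe)) < 0.15

    def test_reproducible_under_seed(self, rng):
        t = random_table(rng, n_trials=20)
        a = qe_bias_correction(t, "joint", seed=42)
        b = qe_bias_correction(t, "joint", seed=42)
        assert a == b

    def test_rejects_insufficient_trials_naming_minimum(self):
        t = table(["a"] * 4 + ["b"] * 4, [0, 1] * 4, [0] * 8)
        with pytest.raises(ValueError, match="8 trials"):
            qe_bias_correction(t, "rate")


class TestShuffleCorrection:
    def test_single_dimension_codes_unchanged(self, rng):
        t = random_table(rng, n_trials=16)
        assert shuffle_correction(t, "rate", seed=1) == qe_bias_correction(
            t, "rate"
        )

    def test_zero_information_near_zero(self):
        model = NotchResponseModel(
            fsl_mean_ms=(18.0, 18.0), respond_prob=(0.9, 0.9)
        )
        rng = np.random.default_rng(4)
        vals = [
            shuffle_correction(model.sample(30, rng), seed=k) for k in range(8)
        ]
        assert abs(np.mean(vals)) < 0.2

    def test_rejects_too_few_shuffles(self, rng):
        with pytest.raises(ValueError):
            shuffle_correction(random_table(rng), n_shuffles=1)

    def test_independent_model_mi_bounded_by_joint(self, rng):
        t = random_table(rng, n_trials=20)
        assert 0 <= _independent_mi(t) <= math.log2(2) + 1e-12


class TestNotchResponseModel:
    def test_exact_mi_consistent_with_large_sample_plugin(self):
        model = NotchResponseModel()
        t = model.sample(20000, np.random.default_rng(5))
        for code in ("rate", "fsl", "joint"):
            assert plugin_mi(t, code) == pytest.approx(
                model.exact_mi(code), abs=0.02
            )

    def test_joint_at_least_each_marginal(self):
        model = NotchResponseModel()
        j = model.exact_mi("joint")
        assert j >= model.exact_mi("rate") - 1e-12
        assert j >= model.exact_mi("fsl") - 1e-12

    def test_pmf_normalized(self):
        model = NotchResponseModel()
        for s in (0, 1):
            assert sum(model.joint_pmf(s).values()) == pytest.approx(1.0)


class TestBiasVsTrials:
    def test_plugin_bias_magnitude_decays_with_trials(self):
        model = NotchResponseModel()
        out = bias_vs_trials(
            model, (4, 8), n_replicates=12, seed=0, codes=("fsl",)
        )
        b4 = out[(out.n_trials == 4)].iloc[0]
        b8 = out[(out.n_trials == 8)].iloc[0]
        assert abs(b8.mi_plugin - b8.mi_true) < abs(b4.mi_plugin - b4.mi_true)

    def test_reproducible_and_rejects_unordered(self):
        model = NotchResponseModel()
        a = bias_vs_trials(model, (4, 8), n_replicates=3, seed=1, codes=("rate",))
        b = bias_vs_trials(model, (4, 8), n_replicates=3, seed=1, codes=("rate",))
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            bias_vs_trials(model, (8, 4))


class TestCompareCodes:
    def test_small_group_skips_test(self, small_fm_dataset):
        ids = small_fm_dataset.neuron_ids[:2]
        pairs = {nid: ["FM", "Notch30"] for nid in ids}
        per_neuron, report = compare_codes(small_fm_dataset, ids, pairs)
        assert report["test"] == "skipped"
        assert set(per_neuron.code) == {"rate", "fsl", "joint"}

    def test_identical_code_values_not_significant(self):
        """Two physically identical stimuli: every code carries exactly
        zero information in every neuron, so the across-code comparison
        must come back non-significant."""
        from notchcode import build_fm_protocol, sample_population, simulate_dataset

        pop = sample_population(
            4, seed=9, jitter_sd_ms=0.0, spont_rate_hz=0.0, burst_mean_spikes=1.0
        )
        protocol = build_fm_protocol(
            delays_us={"FM": 0.0, "FMcopy": 0.0}, reps=10, seed=1
        )
        ds = simulate_dataset(pop, protocol, seed=2)
        ids = ds.neuron_ids
        pairs = {nid: ["FM", "FMcopy"] for nid in ids}
        per_neuron, report = compare_codes(ds, ids, pairs, seed=0)
        assert report["significant"] is False
        assert np.allclose(per_neuron["raw_bits"], 0.0)
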