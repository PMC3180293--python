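"""Tests of the synthetic-session generator against its stated statistics."""

import numpy as np
import pandas as pd
import pytest

import scpremo as sp
from scpremo.simulate import default_template, premovement_amplitude


class TestGenerateBehavior:
    def test_catch_fraction_within_binomial_noise(self, behavior_trials):
        n = len(behavior_trials)
        frac = (behavior_trials["modality"] == "catch").mean()
        sd = np.sqrt(0.167 * (1 - 0.167) / n)
        assert abs(frac - 0.167) < 3 * sd

    def test_empty_session(self):
        trials = sp.generate_behavior(sp.TaskConfig(n_trials=0))
        assert len(trials) == 0
        assert "rt_ms" in trials.columns

    def test_rt_means_match_configuration(self, behavior_trials):
        cfg = sp.TaskConfig()
        for m in ("V", "A", "AV"):
            rt = behavior_trials.loc[behavior_trials["modality"] == m, "rt_ms"]
            sem = cfg.rt_sd_ms[m] / np.sqrt(len(rt))
            assert abs(rt.mean() - cfg.rt_mean_ms[m]) < 3 * sem

    def test_modalities_equiprobable_and_sides_balanced(self, behavior_trials):
        noncatch = behavior_trials[behavior_trials["modality"] != "catch"]
        fr = noncatch["modality"].value_counts(normalize=True)
        assert np.allclose(fr[["V", "A", "AV"]], 1 / 3, atol=0.03)
        assert abs((noncatch["stimulus_side"] == "left").mean() - 0.5) < 0.03

    def test_errors_choose_opposite_side(self, behavior_trials):
        err = behavior_trials[~behavior_trials["correct"]]
        assert len(err) > 0
        assert (err["choice_side"] != err["stimulus_side"]).all()

    def test_correction_trials_repeat_stimulus(self):
        trials = sp.generate_behavior(sp.TaskConfig(n_trials=2000, seed=5,
                                                    error_rate=0.3))
        corr_idx = np.flatnonzero(trials["is_correction_trial"].to_numpy())
        assert corr_idx.size > 0
        for i in corr_idx:
            assert trials.loc[i, "modality"] == trials.loc[i - 1, "modality"]
            assert trials.loc[i, "stimulus_side"] == trials.loc[i - 1, "stimulus_side"]

    def test_event_time_invariants(self, behavior_trials):
        t = behavior_trials
        noncatch = t[t["modality"] != "catch"]
        fp = noncatch["cue_on_ms"] - noncatch["poke_in_ms"]
        assert ((fp >= 400) & (fp < 800)).all()
        rt = noncatch["withdrawal_ms"] - noncatch["cue_on_ms"]
        assert np.allclose(rt, noncatch["rt_ms"])
        assert (noncatch["rt_ms"] >= 0).all()
        catch = t[t["modality"] == "catch"]
        assert (catch["stimulus_side"] == "none").all()
        assert catch["cue_on_ms"].isna().all()

    def test_seed_reproducibility(self):
        cfg = sp.TaskConfig(n_trials=100, seed=7)
        pd.testing.assert_frame_equal(sp.generate_behavior(cfg),
                                      sp.generate_behavior(cfg))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            sp.TaskConfig(catch_fraction=1.5)
        with pytest.raises(ValueError):
            sp.TaskConfig(foreperiod_range_ms=(800, 400))
        with pytest.raises(ValueError):
            sp.TaskConfig(rt_mean_ms={"V": np.nan, "A": 390.0, "AV": 320.0})


class TestTrialRateFunction:
    def _trial(self, modality="V", rt=400.0, side="right"):
        return {"modality": modality, "rt_ms": rt, "choice_side": side,
                "cue_on_ms": 1000.0, "withdrawal_ms": 1000.0 + rt}

    def test_all_zero_amplitudes_is_constant_baseline(self):
        p = sp.NeuronParams(baseline_rate_sp_s=10.0)
        rate = sp.trial_rate_function(self._trial(), p, 400.0)
        t = np.linspace(0, 2500, 500)
        assert np.allclose(rate(t), 10.0)

    def test_zero_ipsi_gain_leaves_baseline_on_ipsiversive_trials(self):
        p = sp.NeuronParams(baseline_rate_sp_s=5.0, premove_amp_sp_s=20.0,
                            direction_gain_ipsi=0.0)
        rate = sp.trial_rate_function(self._trial(side="left"), p, 400.0,
                                      hemisphere="left")
        assert np.allclose(rate(np.linspace(0, 2500, 400)), 5.0)

    def test_negative_coupling_makes_amplitude_decrease_with_rt(self):
        p = sp.NeuronParams(premove_amp_sp_s=8.0, rt_coupling_beta=-0.05)
        amps = [premovement_amplitude(self._trial(rt=rt), p, 400.0)
                for rt in np.linspace(200, 700, 9)]
        assert np.all(np.diff(amps) < 0)

    def test_av_modulation_scales_premovement_only(self):
        p = sp.NeuronParams(premove_amp_sp_s=8.0, av_modulation_factor=1.5)
        a_uni = premovement_amplitude(self._trial("V"), p, 400.0)
        a_av = premovement_amplitude(self._trial("AV"), p, 400.0)
        assert a_av == pytest.approx(1.5 * a_uni)

    def test_rate_clamped_non_negative(self):
        p = sp.NeuronParams(baseline_rate_sp_s=2.0, premove_amp_sp_s=-30.0)
        rate = sp.trial_rate_function(self._trial(), p, 400.0)
        assert (rate(np.linspace(900, 1500, 300)) >= 0).all()


class TestGenerateSpikeTrains:
    def test_poisson_count_at_constant_rate(self):
        # one long pseudo-trial: constant 10 sp/s for ~1000 s
        trials = pd.DataFrame({
            "trial_id": [0], "session_id": "t", "stimulus_side": ["right"],
            "modality": ["V"], "poke_in_ms": [300.0], "cue_on_ms": [500.0],
            "withdrawal_ms": [999_600.0], "choice_side": ["right"],
            "correct": [True], "rt_ms": [999_100.0],
            "movement_time_ms": [300.0], "is_correction_trial": [False],
            "injection_condition": ["none"]})
        p = sp.NeuronParams(baseline_rate_sp_s=10.0)
        units = sp.generate_spike_trains(trials, [p], seed=2)
        n = units[0].spike_times_ms.size
        assert abs(n - 10_000) < 3 * np.sqrt(10_000)

    def test_zero_rate_neuron_is_silent(self, small_session):
        _, trials, _ = small_session
        p = sp.NeuronParams(baseline_rate_sp_s=0.0)
        units = sp.generate_spike_trains(trials, [p], seed=3)
        assert units[0].spike_times_ms.size == 0

    def test_same_seed_identical_spikes(self, small_session):
        _, trials, _ = small_session
        pop = sp.make_population(n_per_type=1)
        a = sp.generate_spike_trains(trials, pop, seed=9)
        b = sp.generate_spike_trains(trials, pop, seed=9)
        for ua, ub in zip(a, b):
            assert np.array_equal(ua.spike_times_ms, ub.spike_times_ms)

    def test_epoch_counts_poisson_dispersed(self):
        trials = sp.generate_behavior(sp.TaskConfig(n_trials=1500, seed=21))
        p = sp.NeuronParams(baseline_rate_sp_s=20.0)
        units = sp.generate_spike_trains(trials, [p], seed=4)
        neural = sp.filter_trials(trials, "neural")
        rates = sp.epoch_rate(units[0].spike_times_ms, neural,
                              sp.BASELINE_EPOCH)
        counts = rates * 0.1
        assert 0.8 < counts.var(ddof=1) / counts.mean() < 1.2


class TestSynthesizeWideband:
    def test_single_noiseless_spike_reproduces_template(self):
        u = sp.UnitSpikeData("u", np.array([50.0]))
        template = default_template(80.0)
        trace, idx = sp.synthesize_wideband([u], template, noise_sd_uv=0.0,
                                            duration_ms=100.0,
                                            channel_scales=np.ones(4))
        assert idx.size == 1
        start = idx[0] - int(np.argmin(template))
        assert np.allclose(trace[0, start:start + 32], template)
        mask = np.ones(trace.shape[1], bool)
        mask[start:start + 32] = False
        assert np.allclose(trace[:, mask], 0.0)

    def test_pure_noise_sd(self):
        trace, idx = sp.synthesize_wideband([], noise_sd_uv=12.0,
                                            duration_ms=10_000.0, seed=1)
        assert idx.size == 0
        assert abs(trace.std() - 12.0) / 12.0 < 0.05

    def test_linearity_for_disjoint_units(self):
        u1 = sp.UnitSpikeData("a", np.array([20.0, 60.0]))
        u2 = sp.UnitSpikeData("b", np.array([40.0]))
        kw = dict(noise_sd_uv=0.0, duration_ms=100.0, seed=0)
        t12, _ = sp.synthesize_wideband([u1, u2], **kw)
        t1, _ = sp.synthesize_wideband([u1], **kw)
        t2, _ = sp.synthesize_wideband([u2], **kw)
        assert np.allclose(t12, t1 + t2)


def test_round_trip_serialization(tmp_path, small_session):
    _, trials, units = small_session
    sp.simulate.write_trial_table(trials, tmp_path / "t.tsv")
    back = sp.simulate.read_trial_table(tmp_path / "t.tsv")
    assert np.allclose(back["withdrawal_ms"], trials["withdrawal_ms"])
    sp.simulate.write_spikes(units, tmp_path / "s.tsv")
    back_units = {u.unit_id: u for u in sp.simulate.read_spikes(tmp_path / "s.tsv")}
    for u in units:
        assert np.array_equal(back_units[u.unit_id].spike_times_ms,
                              u.spike_times_ms)
    trace, _ = sp.synthesize_wideband(units[:1], duration_ms=200.0, seed=5)
    sp.simulate.write_wideband(trace, tmp_path / "raw", uv_per_bit=0.1)
    back_trace, meta = sp.simulate.read_wideband(tmp_path / "raw")
    assert meta["n_channels"] == 4
    assert np.abs(back_trace - trace).max() <= 0.05 + 1e-9  # half a bit
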