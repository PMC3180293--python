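"""Tests of the wideband spike-detection front-end and quality metrics."""

import numpy as np
import pytest

import scpremo as sp
from scpremo.detect import DetectionConfig, spike_features, unit_quality
from scpremo.simulate import default_template


def synthetic_trace(n_spikes=100, snr=10.0, noise_sd=8.0, duration_ms=None,
                    seed=0, min_gap_ms=5.0):
    """Noisy tetrode trace with known, well-separated spike times."""
    rng = np.random.default_rng(seed)
    if duration_ms is None:
        duration_ms = n_spikes * 20.0 + 100.0
    t = np.sort(rng.uniform(10.0, duration_ms - 10.0, n_spikes * 3))
    keep = np.concatenate([[True], np.diff(t) > min_gap_ms])
    t = t[keep][:n_spikes]
    unit = sp.UnitSpikeData("u", t)
    trace, true_idx = sp.synthesize_wideband(
        [unit], default_template(snr * noise_sd), noise_sd_uv=noise_sd,
        duration_ms=duration_ms, seed=seed + 1)
    return trace, true_idx


def match_events(detected, truth, tol=16):
    """Greedy one-to-one matching within `tol` samples."""
    used = np.zeros(truth.size, bool)
    tp = 0
    for d in detected:
        j = np.argmin(np.abs(truth - d)) if truth.size else None
        if j is not None and not used[j] and abs(truth[j] - d) <= tol:
            used[j] = True
            tp += 1
    return tp


class TestBandpass:
    def _sine(self, freq, fs=25000.0, dur_s=0.5):
        t = np.arange(int(fs * dur_s)) / fs
        return np.sin(2 * np.pi * freq * t)

    def test_passband_tone_preserved(self):
        y = sp.bandpass(self._sine(2000.0))
        mid = y[2000:-2000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_tone_attenuated(self):
        y = sp.bandpass(self._sine(100.0))
        assert np.abs(y[2000:-2000]).max() < 10 ** (-20 / 20)

    def test_zero_trace_maps_to_zero(self):
        assert np.allclose(sp.bandpass(np.zeros(10_000)), 0.0)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError):
            DetectionConfig(bandpass_hz=(800.0, 15_000.0), fs_hz=25_000.0)


class TestDetectSpikes:
    def test_zero_trace_no_events(self):
        assert sp.detect_spikes(np.zeros((4, 10_000))).size == 0

    def test_recall_and_precision_on_synthetic_trace(self):
        trace, truth = synthetic_trace(n_spikes=200, snr=10.0, seed=3)
        events = sp.detect_spikes(sp.bandpass(trace))
        tp = match_events(events, truth)
        assert tp / truth.size >= 0.95       # recall
        assert tp / events.size >= 0.95      # precision

    def test_infinite_threshold_no_events(self):
        trace, _ = synthetic_trace(n_spikes=50, seed=4)
        cfg = DetectionConfig(threshold_k=1e9)
        assert sp.detect_spikes(sp.bandpass(trace), cfg).size == 0

    def test_recall_nonincreasing_in_threshold(self):
        trace, truth = synthetic_trace(n_spikes=100, snr=6.0, seed=5)
        filt = sp.bandpass(trace)
        recalls = []
        for k in (3.0, 5.0, 8.0, 12.0, 20.0):
            ev = sp.detect_spikes(filt, DetectionConfig(threshold_k=k))
            recalls.append(match_events(ev, truth) / truth.size)
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))

    def test_translation_equivariance(self):
        trace, _ = synthetic_trace(n_spikes=30, seed=6)
        shift = 1000
        shifted = np.roll(trace, shift, axis=-1)
        e1 = sp.detect_spikes(sp.bandpass(trace))
        e2 = sp.detect_spikes(sp.bandpass(shifted))
        interior = e1[(e1 > 2000) & (e1 < trace.shape[-1] - 2000)]
        assert np.isin(interior + shift, e2).mean() > 0.95

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            sp.detect_spikes(np.zeros((4, 2)))


class TestExtractWaveforms:
    def test_noiseless_template_recovered(self):
        unit = sp.UnitSpikeData("u", np.array([50.0]))
        template = default_template(100.0)
        trace, idx = sp.synthesize_wideband([unit], template, noise_sd_uv=0.0,
                                            duration_ms=100.0,
                                            channel_scales=np.ones(4))
        wf, kept, dropped = sp.extract_waveforms(trace, idx)
        assert dropped == 0 and wf.shape == (1, 4, 32)
        assert np.allclose(wf[0, 0], template)
        assert np.argmin(wf[0, 0]) == 10   # trough alignment

    def test_edge_event_dropped(self):
        trace = np.zeros((4, 1000))
        wf, kept, dropped = sp.extract_waveforms(trace, np.array([3]))
        assert dropped == 1 and wf.shape[0] == 0

    def test_row_count_matches_in_bounds_events(self):
        trace, truth = synthetic_trace(n_spikes=40, seed=7)
        filt = sp.bandpass(trace)
        events = sp.detect_spikes(filt)
        wf, kept, dropped = sp.extract_waveforms(filt, events)
        assert wf.shape[0] == events.size - dropped == kept.size


class TestRefractoryViolations:
    def test_clean_train_zero(self):
        assert sp.refractory_violation_fraction(np.arange(0, 1000, 10.0)) == 0.0

    def test_single_violation_fraction(self):
        t = np.concatenate([np.arange(0, 1000, 10.0), [991.0]])
        # 101 spikes, exactly one 1-ms ISI
        assert sp.refractory_violation_fraction(t) == pytest.approx(1 / 100)

    def test_poisson_train_matches_exponential_law(self):
        rng = np.random.default_rng(8)
        isi = rng.exponential(1000.0 / 20.0, 10_000)
        t = np.cumsum(isi)
        frac = sp.refractory_violation_fraction(t)
        expected = 1 - np.exp(-20 * 0.0015)
        sd = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(frac - expected) < 3 * sd

    def test_too_few_spikes_warns(self):
        with pytest.warns(UserWarning):
            assert sp.refractory_violation_fraction(np.array([1.0])) == 0.0


class TestIsolationDistance:
    def test_other_at_cluster_center_is_zero(self):
        rng = np.random.default_rng(9)
        cluster = rng.normal(0.0, 1.0, (200, 2))
        center = cluster.mean(axis=0)
        val, capped = sp.isolation_distance(cluster, np.tile(center, (300, 1)))
        assert val == pytest.approx(0.0, abs=1e-20)

    def test_well_separated_clusters_exceed_20(self):
        rng = np.random.default_rng(10)
        cluster = rng.normal(0.0, 1.0, (500, 2))
        other = rng.normal(10.0, 1.0, (500, 2))
        val, capped = sp.isolation_distance(cluster, other)
        assert not capped and val > 20.0
        # brute-force oracle on the same instance
        cov_inv = np.linalg.inv(np.cov(cluster, rowvar=False))
        d = other - cluster.mean(axis=0)
        d2 = np.sort([row @ cov_inv @ row for row in d])
        assert val == pytest.approx(d2[len(cluster) - 1])

    def test_same_distribution_stays_below_chi2_quantile(self):
        from scipy.stats import chi2
        rng = np.random.default_rng(11)
        q99 = chi2.ppf(0.99, df=2)
        # statistic = distance of the 100th closest of 2000 noise spikes,
        # i.e. roughly the chi2 5th percentile when nothing is separated
        below = sum(
            sp.isolation_distance(rng.normal(0, 1, (100, 2)),
                                  rng.normal(0, 1, (2000, 2)))[0] < q99
            for _ in range(100))
        assert below >= 90

    def test_capped_when_other_set_small(self):
        rng = np.random.default_rng(12)
        val, capped = sp.isolation_distance(rng.normal(0, 1, (100, 2)),
                                            rng.normal(5, 1, (10, 2)))
        assert capped

    def test_singular_covariance_rejected(self):
        cluster = np.tile([1.0, 2.0], (50, 1))
        with pytest.raises(ValueError, match="feature"):
            sp.isolation_distance(cluster, np.random.default_rng(0).normal(size=(50, 2)))


class TestQualityGate:
    def test_acceptance_rule(self):
        rng = np.random.default_rng(13)
        cluster = rng.normal(0.0, 1.0, (300, 2))
        far = rng.normal(12.0, 1.0, (300, 2))
        good = unit_quality(np.arange(0, 3000, 10.0), cluster, far)
        assert good.accepted
        bursty = np.sort(np.concatenate([np.arange(0, 3000, 10.0),
                                         np.arange(0.5, 3000, 10.0)]))
        bad = unit_quality(bursty, cluster, far)
        assert not bad.accepted

    def test_feature_matrix_shape(self):
        trace, truth = synthetic_trace(n_spikes=60, seed=14)
        filt = sp.bandpass(trace)
        wf, _, _ = sp.extract_waveforms(filt, sp.detect_spikes(filt))
        feats = spike_features(wf)
        assert feats.shape == (wf.shape[0], 4 * 5)
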