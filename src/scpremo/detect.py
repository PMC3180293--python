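"""Spike detection from wideband voltage and unit-quality metrics.

Detection follows the RMS-power scheme: the 0.8-5 kHz band-passed signal
is squared and averaged in a 0.2-ms sliding window; a channel's detection
threshold is the mean of that power trace plus five of its standard
deviations, and threshold crossings on any channel (merged within one
waveform span) become events.  32-sample waveforms are cut around each
event with the trough at sample 10.

Unit quality uses the two standard acceptance criteria: a refractory-
period violation fraction below 1% and an isolation distance (the
Mahalanobis distance, under the cluster's own covariance, of the n-th
closest non-cluster spike where n is the cluster size) above 20.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d


@dataclass(frozen=True)
class DetectionConfig:
    bandpass_hz: tuple[float, float] = (800.0, 5000.0)
    power_window_ms: float = 0.2
    threshold_k: float = 5.0
    waveform_samples: int = 32
    trough_sample: int = 10
    fs_hz: float = 25000.0
    filter_order: int = 3          # Butterworth order (zero-phase, applied twice)

    def __post_init__(self):
        lo, hi = self.bandpass_hz
        if not (0 < lo < hi):
            raise ValueError("bandpass must satisfy 0 < low < high")
        if hi >= self.fs_hz / 2:
            raise ValueError("bandpass high edge must be below Nyquist (fs/2)")
        if self.waveform_samples <= 0:
            raise ValueError("waveform_samples must be positive")


@dataclass
class QualityReport:
    refractory_violation_fraction: float
    isolation_distance: float
    n_spikes: int
    isolation_capped: bool = False

    @property
    def accepted(self) -> bool:
        """Single-unit acceptance: <1% violations and isolation distance >20."""
        return (self.refractory_violation_fraction < 0.01
                and self.isolation_distance > 20.0)


def _as_channels(trace: np.ndarray) -> np.ndarray:
    trace = np.asarray(trace, dtype=float)
    return trace[np.newaxis, :] if trace.ndim == 1 else trace


def bandpass(trace: np.ndarray, config: DetectionConfig = DetectionConfig()
             ) -> np.ndarray:
    """Zero-phase Butterworth band-pass, channel-wise, same length."""
    x = _as_channels(trace)
    sos = sps.butter(config.filter_order, config.bandpass_hz,
                     btype="bandpass", fs=config.fs_hz, output="sos")
    y = sps.sosfiltfilt(sos, x, axis=-1)
    return y[0] if np.asarray(trace).ndim == 1 else y


def sliding_rms(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Root-mean-square power in a centered sliding window."""
    return np.sqrt(uniform_filter1d(np.square(x), size=window_samples,
                                    axis=-1, mode="nearest"))


def detect_spikes(filtered: np.ndarray,
                  config: DetectionConfig = DetectionConfig()) -> np.ndarray:
    """Event indices from RMS-power threshold crossings.

    The per-channel threshold is ``mean(power) + k * SD(power)``; samples
    where any channel's power crosses its threshold are merged into
    events when closer than one waveform span, and each event is reported
    at the peak-power sample.
    """
    x = _as_channels(filtered)
    win = max(1, int(round(config.power_window_ms * config.fs_hz / 1000.0)))
    if x.shape[-1] < win:
        raise ValueError("trace shorter than the power window")
    power = sliding_rms(x, win)
    thresh = power.mean(axis=-1, keepdims=True) \
        + config.threshold_k * power.std(axis=-1, keepdims=True)
    above = (power > thresh).any(axis=0)
    if not above.any():
        return np.empty(0, dtype=int)
    total_power = power.max(axis=0)

    idx = np.flatnonzero(above)
    gaps = np.flatnonzero(np.diff(idx) > config.waveform_samples)
    groups = np.split(idx, gaps + 1)
    return np.array([g[np.argmax(total_power[g])] for g in groups], dtype=int)


def extract_waveforms(trace: np.ndarray, events: np.ndarray,
                      config: DetectionConfig = DetectionConfig()):
    """Cut trough-aligned waveforms around events.

    Each event is snapped to the local minimum (trough) on its strongest
    channel within +/-5 samples, then ``waveform_samples`` samples are cut
    with the trough at ``config.trough_sample``.  Events too close to the
    trace edges are dropped.

    Returns ``(waveforms, kept_events, n_dropped)`` with waveforms shaped
    ``(n_kept, n_channels, waveform_samples)``.
    """
    x = _as_channels(trace)
    n = x.shape[-1]
    pre = config.trough_sample
    post = config.waveform_samples - pre
    waveforms, kept = [], []
    n_dropped = 0
    for e in np.asarray(events, dtype=int):
        lo, hi = max(e - 5, 0), min(e + 6, n)
        if hi <= lo:
            n_dropped += 1
            continue
        seg = x[:, lo:hi]
        ch = np.argmin(seg.min(axis=1))
        t = lo + int(np.argmin(seg[ch]))
        if t - pre < 0 or t + post > n:
            n_dropped += 1
            continue
        waveforms.append(x[:, t - pre:t + post])
        kept.append(t)
    wf = (np.stack(waveforms) if waveforms
          else np.empty((0, x.shape[0], config.waveform_samples)))
    return wf, np.array(kept, dtype=int), n_dropped


def refractory_violation_fraction(spike_times_ms, refractory_ms: float = 1.5
                                  ) -> float:
    """Fraction of inter-spike intervals shorter than the refractory period."""
    t = np.asarray(spike_times_ms, dtype=float)
    if t.size < 2:
        warnings.warn("fewer than 2 spikes: violation fraction undefined, "
                      "returning 0", stacklevel=2)
        return 0.0
    isi = np.diff(t)
    if np.any(isi < 0):
        raise ValueError("spike times must be sorted")
    return float(np.count_nonzero(isi < refractory_ms) / isi.size)


def isolation_distance(cluster_features: np.ndarray,
                       other_features: np.ndarray) -> tuple[float, bool]:
    """Mahalanobis isolation distance of a cluster from all other spikes.

    Squared Mahalanobis distances of every non-cluster spike to the
    cluster mean, under the cluster's covariance; the statistic is the
    distance of the ``n_c``-th closest non-cluster spike (n_c = cluster
    size).  When fewer than ``n_c`` non-cluster spikes exist the maximum
    distance is returned with the ``capped`` flag set.

    Returns ``(value, capped)``.
    """
    c = np.atleast_2d(np.asarray(cluster_features, dtype=float))
    o = np.atleast_2d(np.asarray(other_features, dtype=float))
    n_c, d = c.shape
    if n_c < d + 1:
        raise ValueError("cluster must contain more spikes than feature "
                         "dimensions")
    if o.size == 0:
        raise ValueError("non-cluster spike set is empty")
    cov = np.cov(c, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular cluster covariance; reduce or decorrelate the feature "
            "set before computing isolation distance") from exc
    delta = o - c.mean(axis=0)
    d2 = np.sort(np.einsum("ij,jk,ik->i", delta, cov_inv, delta))
    if d2.size < n_c:
        return float(d2[-1]), True
    return float(d2[n_c - 1]), False


def spike_features(waveforms: np.ndarray, n_pcs: int = 2) -> np.ndarray:
    """Sorting feature set: energy, peak, valley and the first PCs per channel.

    Principal components are computed on the waveform set under analysis.
    Returns ``(n_spikes, n_channels * (3 + n_pcs))``.
    """
    n_spk, n_ch, _ = waveforms.shape
    feats = []
    for c in range(n_ch):
        w = waveforms[:, c, :]
        energy = np.sqrt(np.sum(w ** 2, axis=1))
        peak = w.max(axis=1)
        valley = w.min(axis=1)
        centered = w - w.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        pcs = centered @ vt[:n_pcs].T
        feats.append(np.column_stack([energy, peak, valley, pcs]))
    return np.concatenate(feats, axis=1)


def unit_quality(spike_times_ms, cluster_features, other_features,
                 refractory_ms: float = 1.5) -> QualityReport:
    """Combine the two acceptance criteria into one report."""
    iso, capped = isolation_distance(cluster_features, other_features)
    return QualityReport(
        refractory_violation_fraction(spike_times_ms, refractory_ms),
        iso, n_spikes=len(np.asarray(spike_times_ms)), isolation_capped=capped)
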