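"""Detection and classification of stimulus-evoked responses.

A unit has an evoked response when its trial-mean SDF (sigma = 4 ms)
exceeds baseline mean + 2 baseline SDs for a contiguous run longer than
15 ms whose start falls within 0-100 ms after stimulus onset (first
peak) or after stimulus offset (second peak; offset = onset + 100 ms for
the 100-ms cues).  Latency is the first suprathreshold sample of the
qualifying run; duration is the time spent above threshold.

Mean evoked rates use modality-specific windows after stimulus onset:
0-40 ms for auditory responses and 50-100 ms for visual responses.

A unit is visual (auditory) when the criterion holds on visual-only
(auditory-only) trials, and multisensory when it holds on audiovisual
trials alone or when both unisensory responses are present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import EpochDefinition, epoch_rate

EVOKED_WINDOWS_MS = {"auditory": (0.0, 40.0), "visual": (50.0, 100.0)}


@dataclass
class EvokedResponse:
    present: bool
    latency_ms: float | None = None       # from the respective anchor (onset/offset)
    duration_ms: float | None = None
    peak_window: str | None = None        # "onset" or "offset"
    threshold_sp_s: float | None = None
    degenerate_baseline: bool = False


def _runs(mask: np.ndarray):
    """(start, length) of each maximal True run."""
    if not mask.any():
        return []
    d = np.diff(np.concatenate([[0], mask.astype(int), [0]]))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends - starts))


def detect_evoked(mean_sdf: np.ndarray, times_ms: np.ndarray,
                  baseline_mean: float, baseline_sd: float,
                  n_sd: float = 2.0, min_duration_ms: float = 15.0,
                  stim_duration_ms: float = 100.0,
                  sd_floor_sp_s: float = 1.0) -> EvokedResponse:
    """Threshold-crossing evoked-response detection on a trial-mean SDF.

    `times_ms` is relative to stimulus onset and must cover [-100, 200).
    The threshold is ``baseline_mean + n_sd * baseline_sd``; when the
    baseline SD is zero (silent baseline) the detection falls back to
    ``baseline_mean + n_sd * sd_floor_sp_s`` and flags the result.
    """
    mean_sdf = np.asarray(mean_sdf, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    step = times_ms[1] - times_ms[0]
    degenerate = baseline_sd == 0.0
    sd = sd_floor_sp_s if degenerate else baseline_sd
    threshold = baseline_mean + n_sd * sd

    above = mean_sdf > threshold
    best = None
    for anchor_name, anchor in (("onset", 0.0), ("offset", stim_duration_ms)):
        for start, length in _runs(above):
            t0, t1 = times_ms[start], times_ms[start] + length * step
            # the run must start inside the search window, or already be
            # suprathreshold when the window opens (latency 0)
            if not (anchor <= t0 < anchor + 100.0) and not (t0 < anchor < t1):
                continue
            eff_start = max(t0, anchor)
            if t1 - eff_start <= min_duration_ms:
                continue
            if best is None:
                best = EvokedResponse(
                    True, latency_ms=float(eff_start - anchor),
                    duration_ms=float(t1 - eff_start), peak_window=anchor_name,
                    threshold_sp_s=float(threshold),
                    degenerate_baseline=degenerate)
        if best is not None:
            break
    if best is None:
        return EvokedResponse(False, threshold_sp_s=float(threshold),
                              degenerate_baseline=degenerate)
    return best


def evoked_rate(spike_times_ms, trials, response_type: str) -> np.ndarray:
    """Per-trial mean rate in the modality-specific evoked window.

    ``response_type`` is ``"auditory"`` ([0, 40) ms after onset) or
    ``"visual"`` ([50, 100) ms after onset).
    """
    if response_type not in EVOKED_WINDOWS_MS:
        raise ValueError(
            f"response_type must be one of {sorted(EVOKED_WINDOWS_MS)}")
    window = EVOKED_WINDOWS_MS[response_type]
    epoch = EpochDefinition(response_type, "cue_on_ms", window)
    return epoch_rate(spike_times_ms, trials, epoch)


def classify_modality(response_v: EvokedResponse, response_a: EvokedResponse,
                      response_av: EvokedResponse | None = None) -> str:
    """Label a unit visual / auditory / multisensory / none.

    Multisensory when both unisensory responses are present, or when only
    the audiovisual-condition data meet the evoked criterion (a response
    that emerges under combined stimulation; a cell with one unisensory
    response will normally also respond under AV, which does not by
    itself make it multisensory).
    """
    v, a = response_v.present, response_a.present
    av = response_av.present if response_av is not None else False
    if v and a:
        return "multisensory"
    if v:
        return "visual"
    if a:
        return "auditory"
    if av:
        return "multisensory"
    return "none"
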