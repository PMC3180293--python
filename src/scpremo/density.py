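"""Event-aligned spike density functions, epoch rates and trial filtering.

The spike density function (SDF) is the Gaussian-kernel-smoothed firing
rate (sigma = 15 ms for movement-epoch analyses, 4 ms for sensory
analyses) evaluated on a uniform 1-ms grid.  The discretised kernel is
truncated at +/-4 sigma and renormalised to exact unit mass, so the SDF
of a spike train integrates to the spike count (in s^-1 units) to within
floating-point error for spikes away from the window edges.

Epoch rates are count-based (exact): spikes in a half-open window divided
by the window length.  The three canonical epochs are the 100 ms before
cue onset (baseline), the 100 ms after cue onset (evoked) and the 100 ms
before nose withdrawal (premovement).

``filter_trials`` centralises the trial-exclusion rules every downstream
statistic consumes, in particular the exclusion of trials with reaction
time below 150 ms from neural analyses (so that sensory-evoked activity
does not contaminate the premovement epoch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NEURAL_MIN_RT_MS = 150.0


@dataclass(frozen=True)
class AlignmentSpec:
    align_event: str = "withdrawal"        # "cue_on" or "withdrawal"
    window_ms: tuple[float, float] = (-400.0, 200.0)
    kernel_sigma_ms: float = 15.0
    grid_step_ms: float = 1.0

    def __post_init__(self):
        if self.align_event not in ("cue_on", "withdrawal"):
            raise ValueError("align_event must be 'cue_on' or 'withdrawal'")
        if not self.window_ms[0] < self.window_ms[1]:
            raise ValueError("window must satisfy pre < post")
        if self.kernel_sigma_ms <= 0 or self.grid_step_ms <= 0:
            raise ValueError("sigma and grid step must be positive")

    @property
    def anchor_column(self) -> str:
        return {"cue_on": "cue_on_ms", "withdrawal": "withdrawal_ms"}[self.align_event]


@dataclass(frozen=True)
class EpochDefinition:
    name: str
    anchor: str                     # trial-table column holding the event time
    interval_ms: tuple[float, float]


BASELINE_EPOCH = EpochDefinition("baseline", "cue_on_ms", (-100.0, 0.0))
EVOKED_EPOCH = EpochDefinition("evoked", "cue_on_ms", (0.0, 100.0))
PREMOVEMENT_EPOCH = EpochDefinition("premovement", "withdrawal_ms", (-100.0, 0.0))


@dataclass
class SDFMatrix:
    """Per-trial event-aligned SDFs on a shared time grid (sp/s)."""

    unit_id: str
    trial_ids: np.ndarray
    times_ms: np.ndarray            # grid, relative to the anchor event
    rates: np.ndarray               # (n_trials, n_times)

    def mean(self) -> np.ndarray:
        return self.rates.mean(axis=0)

    def subset(self, mask) -> "SDFMatrix":
        mask = np.asarray(mask)
        return SDFMatrix(self.unit_id, self.trial_ids[mask],
                         self.times_ms, self.rates[mask])


def filter_trials(trials: pd.DataFrame, purpose: str = "neural",
                  exclude_corrections: bool = True,
                  min_rt_ms: float = NEURAL_MIN_RT_MS) -> pd.DataFrame:
    """Select the trial subset appropriate for a given analysis.

    purpose:
      * ``"neural"`` — correct, non-catch, RT >= `min_rt_ms` (default
        150 ms), correction-procedure repeats excluded by default;
      * ``"behavior"`` — correct, non-catch;
      * ``"error_analysis"`` — false-hit errors only (a nose poke into the
        wrong hole); callers must check that at least 4 such trials exist.
    """
    non_catch = trials["modality"] != "catch"
    if purpose == "neural":
        keep = (trials["correct"] & non_catch
                & (trials["rt_ms"] >= min_rt_ms))
        if exclude_corrections:
            keep &= ~trials["is_correction_trial"]
    elif purpose == "behavior":
        keep = trials["correct"] & non_catch
    elif purpose == "error_analysis":
        keep = (~trials["correct"] & non_catch
                & trials["choice_side"].isin(["left", "right"]))
    else:
        raise ValueError(f"unknown purpose {purpose!r}")
    return trials[keep]


def _discrete_kernel(sigma_ms: float, step_ms: float) -> np.ndarray:
    radius = int(np.ceil(4.0 * sigma_ms / step_ms))
    x = np.arange(-radius, radius + 1) * step_ms
    k = np.exp(-0.5 * (x / sigma_ms) ** 2)
    return k / k.sum()           # exact unit mass despite truncation


def compute_sdf(spike_times_ms: np.ndarray, trials: pd.DataFrame,
                spec: AlignmentSpec = AlignmentSpec(),
                unit_id: str = "") -> SDFMatrix:
    """Per-trial SDF matrix aligned to the spec's anchor event.

    Spikes in the window expanded by +/-4 sigma are binned on the grid and
    convolved with the unit-mass Gaussian kernel; rates are in sp/s.
    """
    spike_times_ms = np.asarray(spike_times_ms, dtype=float)
    pre, post = spec.window_ms
    step = spec.grid_step_ms
    grid = pre + step * np.arange(int(round((post - pre) / step)))
    kernel = _discrete_kernel(spec.kernel_sigma_ms, step)
    radius = (kernel.size - 1) // 2

    anchors = trials[spec.anchor_column].to_numpy(float)
    edges = np.concatenate([grid - step / 2, [grid[-1] + step / 2]])
    pad_edges = np.concatenate(
        [edges[0] - step * np.arange(radius, 0, -1), edges,
         edges[-1] + step * np.arange(1, radius + 1)])

    rates = np.empty((len(anchors), grid.size))
    for i, a in enumerate(anchors):
        rel = spike_times_ms[np.searchsorted(spike_times_ms, a + pad_edges[0]):
                             np.searchsorted(spike_times_ms, a + pad_edges[-1])] - a
        counts, _ = np.histogram(rel, bins=pad_edges)
        smoothed = np.convolve(counts, kernel, mode="same")[radius:radius + grid.size]
        rates[i] = smoothed * (1000.0 / step)
    return SDFMatrix(unit_id, trials["trial_id"].to_numpy(), grid, rates)


def epoch_rate(spike_times_ms: np.ndarray, trials: pd.DataFrame,
               epoch: EpochDefinition) -> np.ndarray:
    """Per-trial firing rate (sp/s): count in the half-open epoch / length."""
    spike_times_ms = np.asarray(spike_times_ms, dtype=float)
    a, b = epoch.interval_ms
    anchors = trials[epoch.anchor].to_numpy(float)
    lo = np.searchsorted(spike_times_ms, anchors + a, side="left")
    hi = np.searchsorted(spike_times_ms, anchors + b, side="left")
    return (hi - lo) * (1000.0 / (b - a))


def median_split_sdf(sdf: SDFMatrix, rt_ms: np.ndarray):
    """Mean SDFs of the faster and slower halves split at the median RT.

    Trials with RT exactly at the median join the fast half.
    Returns ``(fast_mean, slow_mean)`` on the SDF's grid.
    """
    rt_ms = np.asarray(rt_ms, dtype=float)
    if len(rt_ms) != sdf.rates.shape[0]:
        raise ValueError("rt_ms length must match the SDF trial count")
    if len(rt_ms) < 2:
        raise ValueError("median split requires at least 2 trials")
    fast = rt_ms <= np.median(rt_ms)
    if fast.all():               # all RTs identical: even split by order
        fast = np.arange(len(rt_ms)) < (len(rt_ms) + 1) // 2
    return sdf.rates[fast].mean(axis=0), sdf.rates[~fast].mean(axis=0)
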