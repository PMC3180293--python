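"""Synthetic session generator with known ground truth.

Emulates the statistical structure of a two-alternative audiovisual
discrimination session: randomized 400-800 ms foreperiods, 100-ms
left/right visual (V), auditory (A) or audiovisual (AV) cues with equal
probability, 16.7% catch trials requiring a 1000-ms hold, per-modality
reaction-time (RT) distributions with audiovisual facilitation, error
trials followed by correction-procedure repeats, and populations of
neurons whose premovement firing is coupled to RT with configurable sign
and strength, with sensory-evoked components and multisensory
enhancement/depression factors.

Reaction times are drawn from a shifted log-normal (shift 100 ms)
moment-matched to the configured per-modality mean and SD — right-skewed
and strictly positive, the typical shape of rodent RT distributions.

All times are milliseconds (64-bit floats) on a single session clock;
every window convention is half-open ``[start, end)``.  One master seed
drives the session; per-unit streams are spawned deterministically from
it, so fixed-seed output is bit-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

MODALITIES = ("V", "A", "AV")

#: trial-table column order used by every writer/reader in the package
TRIAL_COLUMNS = [
    "trial_id", "session_id", "stimulus_side", "modality",
    "poke_in_ms", "cue_on_ms", "withdrawal_ms", "choice_side",
    "correct", "rt_ms", "movement_time_ms", "is_correction_trial",
    "injection_condition",
]


@dataclass
class TaskConfig:
    """Parameters of one simulated behavioral session.

    Defaults reproduce the task statistics the analysis assumes: equal
    V/A/AV probability, 16.7% catch trials, foreperiod uniform on
    [400, 800) ms, 100-ms cues, a 2.1-s response window, and mean RTs of
    386.3 / 394.9 / 322.4 ms for V / A / AV.
    """

    n_trials: int = 200
    foreperiod_range_ms: tuple[float, float] = (400.0, 800.0)
    cue_duration_ms: float = 100.0
    catch_fraction: float = 0.167
    catch_hold_ms: float = 1000.0
    response_window_ms: float = 2100.0
    rt_mean_ms: dict = field(
        default_factory=lambda: {"V": 386.3, "A": 394.9, "AV": 322.4})
    rt_sd_ms: dict = field(
        default_factory=lambda: {"V": 98.7, "A": 101.6, "AV": 86.5})
    rt_shift_ms: float = 100.0
    error_rate: float = 0.19
    movement_time_mean_ms: float = 300.0
    movement_time_sd_ms: float = 80.0
    intertrial_interval_ms: float = 2000.0
    session_id: str = "sim"
    injection_condition: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.catch_fraction <= 1.0):
            raise ValueError("catch_fraction must lie in [0, 1]")
        lo, hi = self.foreperiod_range_ms
        if not lo < hi:
            raise ValueError("foreperiod range must satisfy low < high")
        if set(self.rt_mean_ms) != set(MODALITIES) or set(self.rt_sd_ms) != set(MODALITIES):
            raise ValueError(f"RT parameters must cover exactly {MODALITIES}")
        for name in ("cue_duration_ms", "catch_hold_ms", "response_window_ms",
                     "movement_time_mean_ms", "intertrial_interval_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        vals = list(self.rt_mean_ms.values()) + list(self.rt_sd_ms.values())
        if not np.all(np.isfinite(vals)):
            raise ValueError("RT parameters must be finite")
        if any(m <= self.rt_shift_ms for m in self.rt_mean_ms.values()):
            raise ValueError("rt_mean_ms must exceed rt_shift_ms")
        if not (0.0 <= self.error_rate <= 1.0):
            raise ValueError("error_rate must lie in [0, 1]")


@dataclass
class NeuronParams:
    """Generative parameters of one synthetic unit.

    The premovement component is a linear ramp ending at nose withdrawal
    whose per-trial amplitude is

        direction_gain(side) * (premove_amp + rt_coupling_beta * (rt - median RT))
        * (av_modulation_factor  if the trial is audiovisual)

    so the sign of ``premove_amp`` sets activation vs suppression, the
    sign of ``rt_coupling_beta`` sets the direction of the RT-rate
    correlation, and ``av_modulation_factor`` > 1 (< 1) produces
    multisensory enhancement (depression) of premovement activity
    independently of the evoked components.
    """

    unit_id: str = "u0"
    baseline_rate_sp_s: float = 10.0
    premove_amp_sp_s: float = 0.0
    premove_onset_ms: float = -200.0       # relative to withdrawal, < 0
    rt_coupling_beta: float = 0.0          # sp/s per ms of RT deviation
    direction_gain_contra: float = 1.0
    direction_gain_ipsi: float = 1.0
    sensory_amp_V_sp_s: float = 0.0
    sensory_amp_A_sp_s: float = 0.0
    sensory_latency_V_ms: float = 70.0
    sensory_latency_A_ms: float = 20.0
    sensory_width_ms: float = 10.0
    av_sensory_factor: float = 1.0         # scales both evoked bumps under AV
    av_modulation_factor: float = 1.0      # scales premovement amplitude under AV
    generated_type_label: str = "none"     # one of {"1","2","3","4","none"}

    def __post_init__(self) -> None:
        if self.baseline_rate_sp_s < 0:
            raise ValueError("baseline_rate_sp_s must be >= 0")
        if self.direction_gain_contra < 0 or self.direction_gain_ipsi < 0:
            raise ValueError("direction gains must be >= 0")
        if self.premove_onset_ms >= 0:
            raise ValueError("premove_onset_ms must be negative")


@dataclass
class UnitSpikeData:
    """Spike timestamps of one unit on the session clock (ms, sorted)."""

    unit_id: str
    spike_times_ms: np.ndarray
    ground_truth_params: NeuronParams | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times_ms, dtype=float)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("spike times must be strictly sorted and non-negative")
        self.spike_times_ms = t


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def generate_behavior(config: TaskConfig) -> pd.DataFrame:
    """Generate one session's trial table.

    Catch trials are drawn per-trial with probability ``catch_fraction``;
    non-catch trials get an equiprobable modality and side, an RT from the
    modality's shifted log-normal, and (with probability ``error_rate``) a
    choice on the wrong side.  A trial following an error repeats the
    previous stimulus and is flagged ``is_correction_trial`` (the
    correction procedure).  Trials are laid out sequentially on one
    session clock.
    """
    n = int(config.n_trials)
    cols = TRIAL_COLUMNS
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            cols, [int, str, str, str, float, float, float, str, bool,
                   float, float, bool, str])})

    rng = np.random.default_rng(config.seed)
    is_catch = rng.random(n) < config.catch_fraction
    modality = np.where(is_catch, "catch",
                        rng.choice(MODALITIES, size=n))
    side = np.where(is_catch, "none", rng.choice(["left", "right"], size=n))
    lo, hi = config.foreperiod_range_ms
    foreperiod = rng.uniform(lo, hi, size=n)

    err = (rng.random(n) < config.error_rate) & ~is_catch

    # correction procedure: repeat the stimulus of an error trial
    # (before RTs are drawn, so RTs follow the repeated trial's modality)
    is_corr = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(err[:-1]):
        if not is_catch[i + 1]:
            modality[i + 1] = modality[i]
            side[i + 1] = side[i]
            is_corr[i + 1] = True

    rt = np.full(n, np.nan)
    for m in MODALITIES:
        sel = modality == m
        mu, sig = _lognormal_params(config.rt_mean_ms[m] - config.rt_shift_ms,
                                    config.rt_sd_ms[m])
        rt[sel] = config.rt_shift_ms + rng.lognormal(mu, sig, size=int(sel.sum()))
    rt = np.minimum(rt, config.response_window_ms)

    choice = np.where(is_catch, "none", side)
    flip = {"left": "right", "right": "left"}
    for i in np.flatnonzero(err):
        choice[i] = flip[side[i]]
    correct = ~err

    mu_mt, sig_mt = _lognormal_params(
        config.movement_time_mean_ms - 50.0, config.movement_time_sd_ms)
    movement_time = 50.0 + rng.lognormal(mu_mt, sig_mt, size=n)
    movement_time[is_catch] = np.nan

    hold = np.where(is_catch, foreperiod + config.catch_hold_ms, foreperiod + rt)
    trial_span = hold + np.where(is_catch, 0.0, movement_time) \
        + config.intertrial_interval_ms
    poke_in = np.concatenate([[0.0], np.cumsum(trial_span)[:-1]]) + 500.0
    cue_on = np.where(is_catch, np.nan, poke_in + foreperiod)
    withdrawal = poke_in + hold
    rt[is_catch] = np.nan

    return pd.DataFrame({
        "trial_id": np.arange(n),
        "session_id": config.session_id,
        "stimulus_side": side,
        "modality": modality,
        "poke_in_ms": poke_in,
        "cue_on_ms": cue_on,
        "withdrawal_ms": withdrawal,
        "choice_side": choice,
        "correct": correct,
        "rt_ms": rt,
        "movement_time_ms": movement_time,
        "is_correction_trial": is_corr,
        "injection_condition": config.injection_condition,
    })[cols]


def contraversive_side(hemisphere: str) -> str:
    """Movement side that is contraversive to the recorded hemisphere."""
    if hemisphere not in ("left", "right"):
        raise ValueError("hemisphere must be 'left' or 'right'")
    return "right" if hemisphere == "left" else "left"


def _gauss(t, center, width):
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def premovement_amplitude(trial, params: NeuronParams, median_rt_ms: float,
                          hemisphere: str = "left") -> float:
    """Effective premovement ramp amplitude (sp/s) for one trial."""
    contra = contraversive_side(hemisphere)
    gain = (params.direction_gain_contra if trial["choice_side"] == contra
            else params.direction_gain_ipsi)
    amp = params.premove_amp_sp_s + params.rt_coupling_beta * (
        trial["rt_ms"] - median_rt_ms)
    if trial["modality"] == "AV":
        amp = amp * params.av_modulation_factor
    return gain * amp


def trial_rate_function(trial, params: NeuronParams, median_rt_ms: float,
                        hemisphere: str = "left"):
    """Instantaneous firing rate (sp/s) of one unit on one trial.

    Returns a vectorized callable ``rate(t_ms)`` on the session clock:
    baseline, plus Gaussian sensory bumps after cue onset (per-modality
    amplitude; under AV both bumps are present, each scaled by
    ``av_sensory_factor``), plus a linear premovement ramp rising from
    ``premove_onset_ms`` to the effective amplitude at withdrawal and
    decaying back to zero over 100 ms after withdrawal.  Clamped at zero.
    """
    is_catch = trial["modality"] == "catch"
    amp_eff = 0.0 if is_catch else premovement_amplitude(
        trial, params, median_rt_ms, hemisphere)
    wd = trial["withdrawal_ms"]
    cue = trial["cue_on_ms"]
    onset = wd + params.premove_onset_ms
    ramp_len = -params.premove_onset_ms

    amps = {"V": 0.0, "A": 0.0}
    if not is_catch:
        av = trial["modality"] == "AV"
        if trial["modality"] == "V" or av:
            amps["V"] = params.sensory_amp_V_sp_s * (
                params.av_sensory_factor if av else 1.0)
        if trial["modality"] == "A" or av:
            amps["A"] = params.sensory_amp_A_sp_s * (
                params.av_sensory_factor if av else 1.0)

    def rate(t):
        t = np.asarray(t, dtype=float)
        r = np.full(t.shape, params.baseline_rate_sp_s)
        if amps["V"]:
            r = r + amps["V"] * _gauss(t, cue + params.sensory_latency_V_ms,
                                       params.sensory_width_ms)
        if amps["A"]:
            r = r + amps["A"] * _gauss(t, cue + params.sensory_latency_A_ms,
                                       params.sensory_width_ms)
        if amp_eff != 0.0 and not is_catch:
            rising = (t >= onset) & (t < wd)
            r[rising] += amp_eff * (t[rising] - onset) / ramp_len
            falling = (t >= wd) & (t < wd + 100.0)
            r[falling] += amp_eff * (1.0 - (t[falling] - wd) / 100.0)
        return np.maximum(r, 0.0)

    rate.max_bound = (params.baseline_rate_sp_s
                      + max(amps["V"], 0.0) + max(amps["A"], 0.0)
                      + max(amp_eff, 0.0))
    return rate


def generate_spike_trains(trials: pd.DataFrame,
                          population: list[NeuronParams],
                          seed: int = 0,
                          hemisphere: str = "left",
                          trial_pad_ms: tuple[float, float] = (300.0, 400.0),
                          ) -> list[UnitSpikeData]:
    """Sample spike trains by thinning each unit's trial rate function.

    Spikes are generated per trial over ``[poke_in - pad_pre,
    withdrawal + pad_post)`` (baseline rate holds outside the modelled
    transients) and concatenated on the session clock.  Per-unit random
    streams are spawned from the master seed, so output is reproducible
    and independent of population order changes downstream of spawning.
    """
    med_rt = float(np.nanmedian(trials["rt_ms"])) if len(trials) else 0.0
    streams = np.random.SeedSequence(seed).spawn(len(population))
    out = []
    pad_pre, pad_post = trial_pad_ms
    trial_records = trials.to_dict("records")
    for params, ss in zip(population, streams):
        rng = np.random.default_rng(ss)
        times = []
        for trial in trial_records:
            t0 = trial["poke_in_ms"] - pad_pre
            t1 = trial["withdrawal_ms"] + pad_post
            rate = trial_rate_function(trial, params, med_rt, hemisphere)
            rmax = rate.max_bound
            if rmax <= 0:
                continue
            n_cand = rng.poisson(rmax * (t1 - t0) / 1000.0)
            cand = np.sort(rng.uniform(t0, t1, size=n_cand))
            keep = rng.random(n_cand) * rmax < rate(cand)
            times.append(cand[keep])
        st = np.concatenate(times) if times else np.empty(0)
        st = np.unique(st)  # strict ordering (ties have probability 0)
        out.append(UnitSpikeData(params.unit_id, st, params))
    return out


def default_template(amp_uv: float = 100.0, n_samples: int = 32,
                     trough_sample: int = 10) -> np.ndarray:
    """Biphasic extracellular spike template (trough at `trough_sample`)."""
    i = np.arange(n_samples)
    w = (-np.exp(-0.5 * ((i - trough_sample) / 1.6) ** 2)
         + 0.35 * np.exp(-0.5 * ((i - trough_sample - 6) / 3.2) ** 2))
    return amp_uv * w / np.abs(w).max()


def synthesize_wideband(units: list[UnitSpikeData],
                        template: np.ndarray | None = None,
                        noise_sd_uv: float = 10.0,
                        fs_hz: float = 25000.0,
                        n_channels: int = 4,
                        channel_scales: np.ndarray | None = None,
                        duration_ms: float | None = None,
                        seed: int = 0):
    """Render spike trains into a noisy tetrode-like voltage trace.

    Returns ``(trace, true_indices)`` where ``trace`` is an
    ``(n_channels, n_samples)`` float array in µV (Gaussian noise plus the
    template added at every ground-truth spike time, per-channel scaled)
    and ``true_indices`` is the sorted array of ground-truth trough sample
    indices.  Identical-time spikes simply sum.
    """
    if template is None:
        template = default_template()
    template = np.asarray(template, dtype=float)
    if channel_scales is None:
        channel_scales = np.linspace(1.0, 0.4, n_channels)
    all_times = (np.concatenate([u.spike_times_ms for u in units])
                 if units else np.empty(0))
    if duration_ms is None:
        duration_ms = (all_times.max() + 50.0) if all_times.size else 1000.0
    n_samples = int(round(duration_ms * fs_hz / 1000.0))
    rng = np.random.default_rng(seed)
    trace = rng.normal(0.0, noise_sd_uv, size=(n_channels, n_samples))

    trough = int(np.argmin(template))
    starts = np.round(all_times * fs_hz / 1000.0).astype(int) - trough
    true_idx = []
    for s in starts:
        e = s + template.size
        if s < 0 or e > n_samples:
            continue
        for c in range(n_channels):
            trace[c, s:e] += channel_scales[c] * template
        true_idx.append(s + trough)
    return trace, np.array(sorted(true_idx), dtype=int)


_TYPE_SIGNS = {"1": (+1, +1), "2": (+1, -1), "3": (-1, +1), "4": (-1, -1)}


def make_population(n_per_type: int = 10,
                    baseline_rate_sp_s: float = 10.0,
                    premove_amp_sp_s: float = 8.0,
                    rt_coupling_beta: float = 0.06,
                    av_modulation_factor: float = 1.0,
                    **overrides) -> list[NeuronParams]:
    """Build a balanced population of type-1..4 units.

    The four types occupy the quadrants of (sign of premovement activity,
    sign of RT-rate correlation): the amplitude sign is ``premove_amp``'s
    and the correlation sign is ``rt_coupling_beta``'s.  The default
    |beta| of 0.06 sp/s per ms produces |r| near 0.3 at 200 trials with
    an 8 sp/s ramp on a 10 sp/s baseline.
    """
    pop = []
    for label, (s_amp, s_beta) in _TYPE_SIGNS.items():
        for k in range(n_per_type):
            pop.append(NeuronParams(
                unit_id=f"type{label}_{k}",
                baseline_rate_sp_s=baseline_rate_sp_s,
                premove_amp_sp_s=s_amp * premove_amp_sp_s,
                rt_coupling_beta=s_beta * rt_coupling_beta,
                av_modulation_factor=av_modulation_factor,
                generated_type_label=label,
                **overrides))
    return pop


def simulate_session(config: TaskConfig, population: list[NeuronParams],
                     hemisphere: str = "left"):
    """Generate behavior and matching spike trains for one session."""
    trials = generate_behavior(config)
    units = generate_spike_trains(trials, population,
                                  seed=config.seed + 1, hemisphere=hemisphere)
    return trials, units


# ---------------------------------------------------------------------------
# plain-text serialization

def write_trial_table(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, sep="\t", index=False)


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table {path} missing columns: {sorted(missing)}")
    return df[TRIAL_COLUMNS]


def write_spikes(units: list[UnitSpikeData], path) -> None:
    with open(path, "w") as fh:
        fh.write("unit_id\ttime_ms\n")
        for u in units:
            for t in u.spike_times_ms:
                fh.write(f"{u.unit_id}\t{float(t)!r}\n")


def read_spikes(path) -> list[UnitSpikeData]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [UnitSpikeData(uid, np.sort(g["time_ms"].to_numpy(float)))
            for uid, g in df.groupby("unit_id", sort=True)]


def write_wideband(trace: np.ndarray, path_stem, fs_hz: float = 25000.0,
                   uv_per_bit: float = 0.1) -> None:
    """Raw little-endian int16 binary plus a JSON sidecar."""
    stem = Path(path_stem)
    data = np.round(trace / uv_per_bit).astype("<i2")
    data.T.tofile(stem.with_suffix(".dat"))  # sample-major interleave
    sidecar = {"fs_hz": fs_hz, "n_channels": int(trace.shape[0]),
               "uv_per_bit": uv_per_bit, "dtype": "<i2",
               "order": "sample_major"}
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_wideband(path_stem) -> tuple[np.ndarray, dict]:
    stem = Path(path_stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    raw = np.fromfile(stem.with_suffix(".dat"), dtype=meta["dtype"])
    trace = raw.reshape(-1, meta["n_channels"]).T * meta["uv_per_bit"]
    return trace, meta


def write_ground_truth(population: list[NeuronParams], path) -> None:
    Path(path).write_text(json.dumps([asdict(p) for p in population], indent=1))


def read_ground_truth(path) -> list[NeuronParams]:
    return [NeuronParams(**d) for d in json.loads(Path(path).read_text())]
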