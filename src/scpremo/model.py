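"""Session-level model objects tying the analysis stages together.

``SessionModel`` wraps one session's trial table and unit spike trains;
``fit()`` runs the full per-unit analysis — premovement and direction
ROC indices with permutation significance, trial-by-trial RT-rate
correlations, the four-type classification, multisensory modulation
indices and sensory-response classification — and returns a
``SessionResults`` object holding the per-unit/per-direction profile
table, the population summaries and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .density import (
    AlignmentSpec, BASELINE_EPOCH, PREMOVEMENT_EPOCH,
    compute_sdf, epoch_rate, filter_trials,
)
from .neurontype import classify_neuron, msi, population_summary, rt_rate_correlation
from .roc import (
    center_of_mass, correct_vs_error_preference, index_timecourse,
    permutation_test,
)
from .sensory import classify_modality, detect_evoked, evoked_rate
from .simulate import MODALITIES, UnitSpikeData, contraversive_side


@dataclass
class AnalysisConfig:
    """All analysis-stage parameters, defaulting to the standard values."""

    hemisphere: str = "left"
    min_rt_ms: float = 150.0
    exclude_corrections: bool = True
    n_perm: int = 500
    alpha: float = 0.05
    type_threshold: float = 0.1
    kernel_sigma_ms: float = 15.0
    sensory_sigma_ms: float = 4.0
    min_error_trials: int = 4
    sensory_analysis: bool = True
    error_analysis: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SessionResults:
    """Fitted per-unit profiles and population summaries for one session."""

    profiles: pd.DataFrame
    unit_info: pd.DataFrame
    config: AnalysisConfig
    n_trials_total: int
    n_trials_neural: int
    population: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = []
        w = 62
        lines.append("=" * w)
        lines.append("Superior colliculus premovement analysis".center(w))
        lines.append("=" * w)
        lines.append(f"Units analysed:            {self.unit_info.shape[0]}")
        lines.append(f"Trials (total / neural):   "
                     f"{self.n_trials_total} / {self.n_trials_neural}")
        lines.append(f"Permutations per test:     {self.config.n_perm}")
        lines.append("-" * w)
        sig = self.profiles[self.profiles["premovement_p"] < self.config.alpha]
        lines.append("Significant premovement activity "
                     f"(p<{self.config.alpha:g}): "
                     f"{sig['unit_id'].nunique()}/{self.unit_info.shape[0]} units")
        if "type_fractions" in self.population:
            lines.append("")
            lines.append("Type fractions by movement direction:")
            tf = self.population["type_fractions"]
            lines.append(tf.to_string(float_format=lambda x: f"{x:.3f}"))
        if "correlation_vs_zero" in self.population:
            lines.append("")
            lines.append("RT-rate correlation vs 0 (one-sample t):")
            lines.append(self.population["correlation_vs_zero"].to_string(
                float_format=lambda x: f"{x:.4f}"))
        lines.append("=" * w)
        return "\n".join(lines)


class SessionModel:
    """Analysis model for one recorded (or simulated) session.

    Parameters
    ----------
    trials : trial table (one row per trial, standard columns)
    units : list of UnitSpikeData
    config : AnalysisConfig
    """

    def __init__(self, trials: pd.DataFrame, units: list[UnitSpikeData],
                 config: AnalysisConfig | None = None):
        self.trials = trials.reset_index(drop=True)
        self.units = units
        self.config = config or AnalysisConfig()
        self.neural_trials = filter_trials(
            self.trials, "neural",
            exclude_corrections=self.config.exclude_corrections,
            min_rt_ms=self.config.min_rt_ms)

    @classmethod
    def from_files(cls, trial_path, spike_path,
                   config: AnalysisConfig | None = None) -> "SessionModel":
        from .simulate import read_spikes, read_trial_table
        return cls(read_trial_table(trial_path), read_spikes(spike_path), config)

    # -- per-unit pieces ---------------------------------------------------

    def _direction_mask(self, trials: pd.DataFrame) -> np.ndarray:
        contra = contraversive_side(self.config.hemisphere)
        return (trials["choice_side"] == contra).to_numpy()

    def _sensory_profile(self, unit: UnitSpikeData, rng) -> dict:
        cfg = self.config
        spec = AlignmentSpec("cue_on", (-100.0, 200.0), cfg.sensory_sigma_ms)
        responses = {}
        for m in MODALITIES:
            sub = self.neural_trials[self.neural_trials["modality"] == m]
            if len(sub) == 0:
                responses[m] = None
                continue
            sdf = compute_sdf(unit.spike_times_ms, sub, spec, unit.unit_id)
            mean_sdf = sdf.mean()
            base = mean_sdf[sdf.times_ms < 0.0]
            responses[m] = detect_evoked(mean_sdf, sdf.times_ms,
                                         float(base.mean()), float(base.std()))
        if any(r is None for r in responses.values()):
            return {"modality_class": "none", "sensory_msi": np.nan}
        label = classify_modality(responses["V"], responses["A"], responses["AV"])
        sensory_msi = np.nan
        if label != "none":
            window = {"visual": "visual", "auditory": "auditory"}.get(label)
            rates = {}
            for m in MODALITIES:
                sub = self.neural_trials[self.neural_trials["modality"] == m]
                if window is None:   # multisensory: full 100-ms evoked epoch
                    aud = evoked_rate(unit.spike_times_ms, sub, "auditory")
                    vis = evoked_rate(unit.spike_times_ms, sub, "visual")
                    rates[m] = float(np.mean(0.4 * aud + 0.5 * vis) / 0.9)
                else:
                    rates[m] = float(
                        evoked_rate(unit.spike_times_ms, sub, window).mean())
            sensory_msi = msi(rates["AV"], rates["V"], rates["A"],
                              epoch="sensory").msi
        return {"modality_class": label, "sensory_msi": sensory_msi,
                "evoked": responses}

    def fit(self) -> SessionResults:
        cfg = self.config
        neural = self.neural_trials
        contra_mask = self._direction_mask(neural)
        rt = neural["rt_ms"].to_numpy(float)
        modality = neural["modality"].to_numpy()
        streams = np.random.SeedSequence(cfg.seed).spawn(len(self.units))

        rows, unit_rows = [], []
        for unit, ss in zip(self.units, streams):
            rng = np.random.default_rng(ss)
            base = epoch_rate(unit.spike_times_ms, neural, BASELINE_EPOCH)
            pre = epoch_rate(unit.spike_times_ms, neural, PREMOVEMENT_EPOCH)

            info = {"unit_id": unit.unit_id,
                    "n_spikes": unit.spike_times_ms.size,
                    "modality_class": "none", "sensory_msi": np.nan}
            if cfg.sensory_analysis:
                sens = self._sensory_profile(unit, rng)
                info["modality_class"] = sens["modality_class"]
                info["sensory_msi"] = sens["sensory_msi"]

            if contra_mask.any() and (~contra_mask).any():
                dp = permutation_test(pre[contra_mask], pre[~contra_mask],
                                      n_perm=cfg.n_perm, seed=rng)
                info["direction_index"] = dp.index
                info["direction_p"] = dp.p_value
            else:
                info["direction_index"] = np.nan
                info["direction_p"] = np.nan

            if cfg.error_analysis:
                ce = correct_vs_error_preference(
                    unit.spike_times_ms, self.trials,
                    hemisphere=cfg.hemisphere, n_perm=cfg.n_perm,
                    seed=cfg.seed, min_error_trials=cfg.min_error_trials)
                info["error_sufficient"] = ce.sufficient
                info["error_index"] = ce.error.index if ce.sufficient else np.nan
                info["correct_index"] = (ce.correct.index if ce.sufficient
                                         else np.nan)
            unit_rows.append(info)

            for direction, mask in (("contra", contra_mask),
                                    ("ipsi", ~contra_mask)):
                if mask.sum() < 3:
                    continue
                pm = permutation_test(pre[mask], base[mask],
                                      n_perm=cfg.n_perm, seed=rng)
                corr = rt_rate_correlation(pre[mask], rt[mask])
                label = classify_neuron(pm.index, pm.p_value, corr.r,
                                        threshold=cfg.type_threshold,
                                        alpha=cfg.alpha)
                mod_rates = {m: float(pre[mask & (modality == m)].mean())
                             if (mask & (modality == m)).any() else np.nan
                             for m in MODALITIES}
                if np.all(np.isfinite(list(mod_rates.values()))):
                    m_res = msi(mod_rates["AV"], mod_rates["V"], mod_rates["A"])
                    msi_val = m_res.msi
                else:
                    msi_val = np.nan
                rows.append({
                    "unit_id": unit.unit_id, "direction": direction,
                    "n_trials": int(mask.sum()),
                    "premovement_index": pm.index, "premovement_p": pm.p_value,
                    "r": corr.r, "r_p": corr.p_value,
                    "type": label.label, "representative": label.representative,
                    "msi": msi_val,
                    "av_rate": mod_rates["AV"], "v_rate": mod_rates["V"],
                    "a_rate": mod_rates["A"],
                    "modality_class": info["modality_class"],
                    "sensory_msi": info["sensory_msi"],
                    "generated_type": (unit.ground_truth_params.generated_type_label
                                       if unit.ground_truth_params else None),
                })

        profiles = pd.DataFrame(rows)
        unit_info = pd.DataFrame(unit_rows)
        results = SessionResults(
            profiles=profiles, unit_info=unit_info, config=cfg,
            n_trials_total=len(self.trials), n_trials_neural=len(neural))
        if len(profiles):
            results.population = population_summary(profiles)
        return results

    # -- time courses ------------------------------------------------------

    def direction_timecourse(self, unit: UnitSpikeData,
                             window_ms: tuple[float, float] = (-400.0, 200.0),
                             width_ms: float = 100.0, step_ms: float = 20.0):
        """Sliding-window direction preference aligned to withdrawal.

        Returns the ``RocTimeCourse`` plus its center of mass of
        significant positive preference (or None).
        """
        cfg = self.config
        spec = AlignmentSpec("withdrawal", window_ms, cfg.kernel_sigma_ms)
        neural = self.neural_trials
        mask = self._direction_mask(neural)
        sdf = compute_sdf(unit.spike_times_ms, neural, spec, unit.unit_id)
        tc = index_timecourse(sdf.subset(mask), sdf.subset(~mask),
                              width_ms=width_ms, step_ms=step_ms,
                              n_perm=cfg.n_perm, seed=cfg.seed)
        return tc, center_of_mass(tc)
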