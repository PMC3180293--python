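"""End-to-end pipeline: configuration, staged execution, manifest, report.

A run is one output directory holding every stage's outputs as plain
delimited text / JSON, a snapshot of the configuration and a manifest
with checksums, so a rerun with the same configuration and seed
reproduces all numeric outputs bit-identically.  Existing run
directories are never overwritten.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import rt_anova, session_summary
from .model import AnalysisConfig, SessionModel
from .simulate import (
    TaskConfig, make_population, read_spikes, read_trial_table,
    simulate_session, write_ground_truth, write_spikes, write_trial_table,
)

_SIM_EXTRA_KEYS = {
    "n_per_type", "baseline_rate_sp_s", "premove_amp_sp_s",
    "rt_coupling_beta", "av_modulation_factor",
}
_TOP_KEYS = {"seed", "simulate", "analysis", "inputs"}


def _dataclass_fields(cls) -> set[str]:
    return {f.name for f in dataclasses.fields(cls)}


def validate_config(config: dict) -> dict:
    """Reject unknown keys, naming each offender."""
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    sim = config.get("simulate") or {}
    bad = set(sim) - _dataclass_fields(TaskConfig) - _SIM_EXTRA_KEYS
    if bad:
        raise ValueError(f"unknown simulate key(s): {sorted(bad)}")
    ana = config.get("analysis") or {}
    bad = set(ana) - _dataclass_fields(AnalysisConfig)
    if bad:
        raise ValueError(f"unknown analysis key(s): {sorted(bad)}")
    inputs = config.get("inputs") or {}
    bad = set(inputs) - {"trials", "spikes"}
    if bad:
        raise ValueError(f"unknown inputs key(s): {sorted(bad)}")
    return config


def load_config(path) -> dict:
    config = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(config, dict):
        raise ValueError(f"configuration in {path} must be a mapping")
    return validate_config(config)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> Path:
    """Execute the configured stages into a fresh run directory.

    Stages: simulate (or ingest the configured input files) -> trial
    filtering / per-unit analysis (``SessionModel.fit``) -> behavioral
    summary -> report + manifest.  Returns the run directory path.
    """
    config = validate_config(dict(config))
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        raise FileExistsError(f"run directory {out} already exists; refusing "
                              "to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config["seed"] = int(seed)
    master_seed = int(config.get("seed", 0))

    sim_cfg = dict(config.get("simulate") or {})
    inputs = config.get("inputs") or {}
    if inputs:
        trials = read_trial_table(inputs["trials"])
        units = read_spikes(inputs["spikes"])
    else:
        extra = {k: sim_cfg.pop(k) for k in list(sim_cfg)
                 if k in _SIM_EXTRA_KEYS}
        task = TaskConfig(seed=master_seed, **sim_cfg)
        population = make_population(
            n_per_type=int(extra.get("n_per_type", 2)),
            baseline_rate_sp_s=float(extra.get("baseline_rate_sp_s", 10.0)),
            premove_amp_sp_s=float(extra.get("premove_amp_sp_s", 8.0)),
            rt_coupling_beta=float(extra.get("rt_coupling_beta", 0.06)),
            av_modulation_factor=float(extra.get("av_modulation_factor", 1.0)))
        trials, units = simulate_session(task, population)
        write_ground_truth(population, out / "ground_truth.json")
    write_trial_table(trials, out / "trials.tsv")
    write_spikes(units, out / "spikes.tsv")

    ana_cfg = AnalysisConfig(seed=master_seed, **(config.get("analysis") or {}))
    model = SessionModel(trials, units, ana_cfg)
    results = model.fit()
    results.profiles.to_csv(out / "profiles.tsv", sep="\t", index=False)
    results.unit_info.to_csv(out / "unit_info.tsv", sep="\t", index=False)

    behav = session_summary(trials)
    behav.to_csv(out / "behavior_summary.tsv", sep="\t", index=False)

    (out / "report.txt").write_text(results.summary() + "\n")
    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))

    stage_log = {
        "n_trials_total": int(len(trials)),
        "n_trials_neural": int(results.n_trials_neural),
        "n_units": int(len(units)),
        "n_units_significant_premovement": int(
            results.profiles.loc[results.profiles["premovement_p"]
                                 < ana_cfg.alpha, "unit_id"].nunique())
        if len(results.profiles) else 0,
    }
    manifest = {
        "scpremo_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__, "pandas": pd.__version__,
        "seed": master_seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config, sort_keys=True).encode()).hexdigest(),
        "stages": stage_log,
        "files": {p.name: _sha256(p) for p in sorted(out.iterdir())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def report(run_dir) -> str:
    """Human-readable summary of a completed run directory."""
    run = Path(run_dir)
    required = ["manifest.json", "profiles.tsv", "behavior_summary.tsv",
                "report.txt"]
    missing = [f for f in required if not (run / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"incomplete run {run}: missing {missing}")
    parts = [(run / "report.txt").read_text()]
    behav = pd.read_csv(run / "behavior_summary.tsv", sep="\t")
    parts.append("Behavior (per session x modality):")
    parts.append(behav.to_string(index=False,
                                 float_format=lambda x: f"{x:.1f}"))
    by_sess = behav.pivot_table(index="session_id", columns="modality",
                                values="mean_rt_ms").reset_index().melt(
        id_vars="session_id", value_name="mean_rt_ms")
    if by_sess["session_id"].nunique() >= 2:
        res = rt_anova(by_sess)
        parts.append(f"RT ANOVA (RM): F={res['F']:.2f}, p={res['p']:.4g}")
    return "\n\n".join(parts)
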