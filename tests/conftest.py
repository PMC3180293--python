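import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import scpremo as sp

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_session():
    """200-trial session with one unit per type (shared across tests)."""
    cfg = sp.TaskConfig(n_trials=200, seed=11)
    pop = sp.make_population(n_per_type=1)
    trials, units = sp.simulate_session(cfg, pop)
    return cfg, trials, units


@pytest.fixture(scope="session")
def behavior_trials():
    return sp.generate_behavior(sp.TaskConfig(n_trials=6000, seed=42))


def make_trials(rts_ms, anchor0_ms=10_000.0, spacing_ms=5_000.0,
                modality="V", side="right"):
    """Minimal hand-built trial table with given reaction times."""
    n = len(rts_ms)
    cue = anchor0_ms + spacing_ms * np.arange(n)
    rts = np.asarray(rts_ms, dtype=float)
    return pd.DataFrame({
        "trial_id": np.arange(n), "session_id": "t",
        "stimulus_side": side, "modality": modality,
        "poke_in_ms": cue - 500.0, "cue_on_ms": cue,
        "withdrawal_ms": cue + rts, "choice_side": side,
        "correct": True, "rt_ms": rts, "movement_time_ms": 300.0,
        "is_correction_trial": False, "injection_condition": "none",
    })
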