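"""RT-rate correlation, the four-type classification and the MSI.

Units with significant premovement activity (permutation p < 0.05 for
the premovement-vs-baseline ROC index) fall into one of four types per
movement direction, by the quadrant of (sign of premovement activity
index, sign of the trial-by-trial Pearson correlation between
premovement firing rate and reaction time):

    type 1: index > 0, r > 0   activation that brakes reactions
    type 2: index > 0, r < 0   activation that accelerates reactions
    type 3: index < 0, r > 0   suppression that brakes reactions
    type 4: index < 0, r < 0   suppression that accelerates reactions

"Representative" units additionally satisfy |index| > 0.1 and |r| > 0.1,
removing units near the category boundaries.

The multisensory modulation index (MSI) contrasts the mean premovement
rate under the audiovisual condition (AV) with the average of the
unisensory means (UNIave = (V + A)/2):

    MSI = (AV - UNIave) / (AV + UNIave)

bounded in [-1, 1]; positive values indicate multisensory enhancement,
negative values depression.  This normalised-contrast form matches the
observed index scale (about +/-0.2) and is scale-invariant in the rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REPRESENTATIVE_THRESHOLD = 0.1


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n_trials: int
    defined: bool = True


@dataclass
class TypeLabel:
    label: str                    # "1".."4" or "unclassified"
    representative: bool


@dataclass
class MsiResult:
    msi: float
    av_rate: float
    v_rate: float
    a_rate: float
    epoch: str = "premovement"
    degenerate: bool = False


def rt_rate_correlation(rates_sp_s, rt_ms) -> CorrelationResult:
    """Pearson correlation between premovement rates and reaction times.

    Inputs must come from neural-filtered trials of one movement
    direction.  Zero variance in either variable yields an undefined
    result (``defined=False``), excluded from population statistics.
    """
    rates = np.asarray(rates_sp_s, dtype=float)
    rt = np.asarray(rt_ms, dtype=float)
    if rates.size != rt.size or rates.size < 3:
        raise ValueError("need matched samples with n >= 3")
    if np.std(rates) == 0.0 or np.std(rt) == 0.0:
        return CorrelationResult(np.nan, np.nan, rates.size, defined=False)
    r, p = stats.pearsonr(rates, rt)
    return CorrelationResult(float(r), float(p), rates.size)


def classify_neuron(premovement_index: float, premovement_p: float,
                    r: float, threshold: float = REPRESENTATIVE_THRESHOLD,
                    alpha: float = 0.05) -> TypeLabel:
    """Assign the four-type label for one movement direction.

    Units without significant premovement activity (permutation p >=
    `alpha` against the prestimulus baseline), with an undefined
    correlation, or lying exactly on a category boundary are
    unclassified.
    """
    if (premovement_p >= alpha or not np.isfinite(r)
            or premovement_index == 0.0 or r == 0.0):
        return TypeLabel("unclassified", False)
    label = {(True, True): "1", (True, False): "2",
             (False, True): "3", (False, False): "4"}[
        (premovement_index > 0, r > 0)]
    representative = abs(premovement_index) > threshold and abs(r) > threshold
    return TypeLabel(label, representative)


def msi(av_rate: float, v_rate: float, a_rate: float,
        epoch: str = "premovement") -> MsiResult:
    """Multisensory modulation index ``(AV - UNIave)/(AV + UNIave)``."""
    if min(av_rate, v_rate, a_rate) < 0:
        raise ValueError("firing rates must be non-negative")
    uni = (v_rate + a_rate) / 2.0
    if av_rate + uni == 0.0:
        return MsiResult(0.0, av_rate, v_rate, a_rate, epoch, degenerate=True)
    return MsiResult((av_rate - uni) / (av_rate + uni),
                     av_rate, v_rate, a_rate, epoch)


def _one_sample_t(values: np.ndarray):
    values = values[np.isfinite(values)]
    if values.size < 2 or np.std(values, ddof=1) == 0.0:
        return {"n": int(values.size), "mean": float(values.mean()) if values.size else np.nan,
                "sd": np.nan, "t": np.nan, "p": np.nan, "tested": False}
    t, p = stats.ttest_1samp(values, 0.0)
    return {"n": int(values.size), "mean": float(values.mean()),
            "sd": float(values.std(ddof=1)), "t": float(t), "p": float(p),
            "tested": True}


def population_summary(profiles: pd.DataFrame) -> dict:
    """Population tables over per-unit, per-direction profiles.

    Expects one row per unit x movement direction with columns
    ``unit_id, direction, type, representative, r, msi`` and optionally
    ``sensory_msi``.  Returns type-fraction tables, one-sample t-tests of
    the correlation coefficients against zero per direction, mean MSI per
    type x direction with t-tests, and (when sensory MSIs are present)
    the correlation between sensory and premovement MSIs.
    """
    if len(profiles) == 0:
        raise ValueError("population_summary needs at least one profile row")
    out: dict = {}

    frac = {}
    for direction, g in profiles.groupby("direction"):
        counts = g["type"].value_counts()
        frac[direction] = {t: counts.get(t, 0) / len(g)
                           for t in ["1", "2", "3", "4", "unclassified"]}
    out["type_fractions"] = pd.DataFrame(frac)

    out["correlation_vs_zero"] = pd.DataFrame({
        d: _one_sample_t(g["r"].to_numpy(float))
        for d, g in profiles.groupby("direction")})

    rows = {}
    for (d, t), g in profiles.groupby(["direction", "type"]):
        rows[(d, t)] = _one_sample_t(g["msi"].to_numpy(float))
    out["msi_by_type"] = pd.DataFrame(rows)

    if "sensory_msi" in profiles.columns:
        sub = profiles.dropna(subset=["sensory_msi", "msi"])
        if len(sub) >= 3:
            r, p = stats.pearsonr(sub["sensory_msi"], sub["msi"])
            out["sensory_vs_premovement_msi"] = {
                "r": float(r), "p": float(p), "n": int(len(sub))}
    return out
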