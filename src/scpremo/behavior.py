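"""Behavioral statistics: RT comparisons and inactivation-session tests.

Reaction times across the three stimulus modalities are compared with a
one-way repeated-measures ANOVA on per-session modality means (sessions
as subjects) followed by Tukey's HSD for pairwise post hoc comparisons.

Muscimol-injection sessions are compared to control with within-animal
paired t-tests per modality, Bonferroni-corrected over the comparison
family (by default the 3 modalities x 2 injection sides).  The per-animal
multisensory-facilitation test asks whether audiovisual RTs are shorter
than those of the faster unisensory modality (one-sided two-sample
t-test).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .density import filter_trials
from .simulate import MODALITIES


def session_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-session x modality RT mean/SD/n plus the session success rate."""
    rows = []
    for (sess, inj), g in trials.groupby(["session_id", "injection_condition"]):
        non_catch = g[g["modality"] != "catch"]
        success = float(non_catch["correct"].mean()) if len(non_catch) else np.nan
        ok = filter_trials(g, "behavior")
        for m in MODALITIES:
            rt = ok.loc[ok["modality"] == m, "rt_ms"]
            rows.append({"session_id": sess, "injection_condition": inj,
                         "modality": m, "mean_rt_ms": float(rt.mean()),
                         "sd_rt_ms": float(rt.std(ddof=1)),
                         "n": int(len(rt)), "success_rate": success})
    return pd.DataFrame(rows)


def rt_anova(session_means: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Repeated-measures one-way ANOVA on per-session modality mean RTs.

    `session_means` needs columns ``session_id, modality, mean_rt_ms``
    with every modality present in every session (sessions are the
    repeated-measures subjects).  Returns the F test plus a Tukey HSD
    post hoc table over modalities.
    """
    counts = session_means.groupby("session_id")["modality"].nunique()
    bad = counts[counts != len(MODALITIES)]
    if len(bad):
        raise ValueError(
            f"sessions missing modality cells: {sorted(bad.index)}")
    if counts.size < 2:
        raise ValueError("repeated-measures ANOVA needs >= 2 sessions")

    by_mod = session_means.groupby("modality")["mean_rt_ms"].mean()
    if np.allclose(by_mod, by_mod.iloc[0]) and np.ptp(
            session_means["mean_rt_ms"].to_numpy()) == 0.0:
        f, p = 0.0, 1.0       # no variance anywhere: no effect by definition
    else:
        res = AnovaRM(session_means, depvar="mean_rt_ms", subject="session_id",
                      within=["modality"]).fit()
        f = float(res.anova_table.loc["modality", "F Value"])
        p = float(res.anova_table.loc["modality", "Pr > F"])

    tk = pairwise_tukeyhsd(session_means["mean_rt_ms"],
                           session_means["modality"], alpha=alpha)
    tukey = pd.DataFrame(tk.summary().data[1:],
                         columns=tk.summary().data[0])
    return {"F": f, "p": p, "df": (len(MODALITIES) - 1,
                                   (counts.size - 1) * (len(MODALITIES) - 1)),
            "tukey": tukey}


def tukey_declares(tukey: pd.DataFrame, faster: str, slower: str) -> bool:
    """True when the Tukey table rejects with `faster` having the lower mean."""
    for _, row in tukey.iterrows():
        pair = {row["group1"], row["group2"]}
        if pair == {faster, slower} and row["reject"]:
            diff = float(row["meandiff"])
            return diff > 0 if row["group1"] == faster else diff < 0
    return False


def injection_comparison(animal_means: pd.DataFrame,
                         bonferroni_m: int | None = None) -> pd.DataFrame:
    """Paired t-tests of each injection condition against control.

    `animal_means` needs columns ``animal_id, condition, modality,
    mean_rt_ms`` where condition is ``control`` or an injection label
    (e.g. ``muscimol_ipsi`` / ``muscimol_contra``); pairing is
    within-animal.  The Bonferroni factor defaults to (number of
    injection conditions) x (number of modalities).
    """
    conditions = [c for c in animal_means["condition"].unique() if c != "control"]
    if not conditions:
        raise ValueError("no injection conditions besides control")
    modalities = sorted(animal_means["modality"].unique())
    m = bonferroni_m if bonferroni_m is not None else len(conditions) * len(modalities)

    pivot = animal_means.pivot_table(index=["animal_id", "modality"],
                                     columns="condition", values="mean_rt_ms")
    rows = []
    for cond in conditions:
        for mod in modalities:
            sub = pivot.xs(mod, level="modality")[["control", cond]].dropna()
            if len(sub) < 2:
                raise ValueError(
                    f"paired comparison {cond}/{mod} needs >= 2 animals")
            diff = sub[cond] - sub["control"]
            if np.allclose(diff, 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(sub[cond], sub["control"])
            rows.append({"condition": cond, "modality": mod,
                         "n_animals": int(len(sub)),
                         "mean_effect_ms": float(diff.mean()),
                         "t": float(t), "p_raw": float(p),
                         "p_bonferroni": float(min(1.0, p * m))})
    return pd.DataFrame(rows)


def facilitation_test_per_animal(rts_by_modality: dict[str, np.ndarray],
                                 alpha: float = 0.05) -> dict:
    """One-sided test of audiovisual facilitation for a single animal.

    AV-trial RTs are compared against the faster (smaller-mean)
    unisensory modality's RTs with a two-sample t-test, one-sided for
    AV < unisensory.  Degenerate (zero-variance) inputs are flagged and
    not tested.
    """
    missing = {"V", "A", "AV"} - set(rts_by_modality)
    if missing:
        raise ValueError(f"missing modalities: {sorted(missing)}")
    rts = {m: np.asarray(v, dtype=float) for m, v in rts_by_modality.items()}
    if any(v.size < 2 for v in rts.values()):
        raise ValueError("each modality needs >= 2 trials")
    faster = "V" if rts["V"].mean() <= rts["A"].mean() else "A"
    av, uni = rts["AV"], rts[faster]
    if np.std(av, ddof=1) == 0.0 and np.std(uni, ddof=1) == 0.0:
        return {"significant": False, "t": np.nan, "p": np.nan,
                "faster_unisensory": faster, "degenerate": True}
    t, p = stats.ttest_ind(av, uni, alternative="less")
    return {"significant": bool(p < alpha), "t": float(t), "p": float(p),
            "faster_unisensory": faster, "degenerate": False}
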