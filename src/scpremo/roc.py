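"""Scaled ROC discrimination indices with permutation significance.

The ROC area between two firing-rate distributions is the probability
that an ideal observer correctly classifies which condition a rate was
recorded under; it equals the Mann-Whitney U statistic divided by
``n_a * n_b`` with ties counted one half.  The scaled index is
``2 * area - 1`` in [-1, 1]: 0 means no difference, and the sign says
which condition the unit fires more under (positive = condition A).

Significance comes from a label-shuffling permutation test (500
repetitions by default, two-sided on |index|, add-one corrected so the
smallest attainable p is 1/(n_perm + 1)).  Permutations operate on the
pooled ranks, which are invariant under label exchange, so each null
index costs only a rank subset sum.

The two summary indices of the pipeline are

* direction preference index — condition A = contraversive movement
  trials, B = ipsiversive ones, premovement-epoch rates;
* premovement activity index — condition A = premovement-epoch rates,
  B = prestimulus-baseline rates of the same trials.

and the time-resolved variant slides a 100-ms window in 20-ms steps over
per-trial SDF means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .density import PREMOVEMENT_EPOCH, epoch_rate, filter_trials
from .simulate import contraversive_side


@dataclass
class RocResult:
    index: float
    p_value: float
    n_a: int
    n_b: int
    seed: int | None = None

    @property
    def area(self) -> float:
        return (self.index + 1.0) / 2.0


@dataclass
class RocTimeCourse:
    window_centers_ms: np.ndarray
    index: np.ndarray
    p_value: np.ndarray
    window_width_ms: float = 100.0
    step_ms: float = 20.0
    alpha: float = 0.05

    @property
    def significant(self) -> np.ndarray:
        return self.p_value < self.alpha


def _check_samples(values_a, values_b):
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ROC analysis requires both samples to be nonempty")
    return a, b


def roc_area(values_a, values_b) -> float:
    """P(a > b) + 0.5 P(a = b) over all cross pairs (rank-based)."""
    a, b = _check_samples(values_a, values_b)
    ranks = rankdata(np.concatenate([a, b]))
    u = ranks[:a.size].sum() - a.size * (a.size + 1) / 2.0
    return u / (a.size * b.size)


def roc_index(values_a, values_b) -> float:
    """Scaled ROC area, ``2*area - 1`` in [-1, 1]."""
    return 2.0 * roc_area(values_a, values_b) - 1.0


def _perm_indices(rng, n_perm: int, n: int, n_a: int) -> np.ndarray:
    # random label shuffles preserving group sizes: first n_a columns of
    # row-wise random orderings
    return np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_a]


def permutation_test(values_a, values_b, n_perm: int = 500,
                     seed: int | np.random.Generator = 0) -> RocResult:
    """Two-sided permutation test of the scaled ROC index.

    Group labels are shuffled ``n_perm`` times preserving group sizes;
    ``p = (1 + #{|index_perm| >= |index_obs|}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a, b = _check_samples(values_a, values_b)
    n_a, n = a.size, a.size + b.size
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ranks = rankdata(np.concatenate([a, b]))
    scale = 2.0 / (n_a * b.size)
    offset = n_a * (n_a + 1) / 2.0
    obs = scale * (ranks[:n_a].sum() - offset) - 1.0
    null = scale * (ranks[_perm_indices(rng, n_perm, n, n_a)].sum(axis=1)
                    - offset) - 1.0
    exceed = np.count_nonzero(np.abs(null) >= np.abs(obs) - 1e-12)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return RocResult(index=float(obs), p_value=float(p), n_a=n_a, n_b=b.size,
                     seed=None if isinstance(seed, np.random.Generator) else seed)


def index_timecourse(sdf_a, sdf_b, width_ms: float = 100.0,
                     step_ms: float = 20.0, n_perm: int = 500,
                     seed: int = 0) -> RocTimeCourse:
    """Sliding-window scaled ROC index between two SDF trial sets.

    Both SDF matrices must share the time grid.  Each window's statistic
    is the per-trial mean SDF inside the (half-open) window; only windows
    fully contained in the grid are evaluated, with centers at
    ``grid_start + width/2 + k*step``.
    """
    if not np.array_equal(sdf_a.times_ms, sdf_b.times_ms):
        raise ValueError("SDF matrices must share one time grid")
    t = sdf_a.times_ms
    gstep = t[1] - t[0]
    w = int(round(width_ms / gstep))
    s = int(round(step_ms / gstep))
    if w > t.size:
        raise ValueError("time grid is shorter than one window")
    starts = np.arange(0, t.size - w + 1, s)
    centers = t[starts] + width_ms / 2.0

    # per-trial window means via cumulative sums
    def win_means(rates):
        c = np.concatenate([np.zeros((rates.shape[0], 1)),
                            np.cumsum(rates, axis=1)], axis=1)
        return (c[:, starts + w] - c[:, starts]) / w

    ma, mb = win_means(sdf_a.rates), win_means(sdf_b.rates)
    rng = np.random.default_rng(seed)
    idx = np.empty(starts.size)
    pval = np.empty(starts.size)
    for j in range(starts.size):
        r = permutation_test(ma[:, j], mb[:, j], n_perm=n_perm, seed=rng)
        idx[j], pval[j] = r.index, r.p_value
    return RocTimeCourse(centers, idx, pval, width_ms, step_ms)


def center_of_mass(tc: RocTimeCourse) -> float | None:
    """Index-weighted mean time of significant positive windows.

    Returns ``None`` when no window has a significant positive index.
    """
    sel = tc.significant & (tc.index > 0)
    if not sel.any():
        return None
    return float(np.sum(tc.window_centers_ms[sel] * tc.index[sel])
                 / np.sum(tc.index[sel]))


@dataclass
class CorrectErrorPreference:
    sufficient: bool
    n_error_trials: int
    correct: RocResult | None = None
    error: RocResult | None = None


MIN_ERROR_TRIALS = 4


def correct_vs_error_preference(spike_times_ms, trials,
                                hemisphere: str = "left",
                                n_perm: int = 500, seed: int = 0,
                                min_error_trials: int = MIN_ERROR_TRIALS,
                                ) -> CorrectErrorPreference:
    """Premovement direction preference on correct vs false-hit-error trials.

    Both indices group trials by movement (choice) direction, so a
    movement-coding unit yields same-sign preferences on the two sets.
    Requires at least `min_error_trials` false-hit errors.
    """
    contra = contraversive_side(hemisphere)
    err = filter_trials(trials, "error_analysis")
    n_err = len(err)
    if n_err < min_error_trials:
        return CorrectErrorPreference(False, n_err)
    cor = filter_trials(trials, "neural")

    res = []
    for sub, sd in ((cor, seed), (err, seed + 1)):
        rates = epoch_rate(spike_times_ms, sub, PREMOVEMENT_EPOCH)
        is_contra = (sub["choice_side"] == contra).to_numpy()
        if is_contra.all() or not is_contra.any():
            return CorrectErrorPreference(False, n_err)
        res.append(permutation_test(rates[is_contra], rates[~is_contra],
                                    n_perm=n_perm, seed=sd))
    return CorrectErrorPreference(True, n_err, correct=res[0], error=res[1])
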