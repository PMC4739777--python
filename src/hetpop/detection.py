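"""Hit/miss and reaction-time statistics.

Effect sizes (pooled-SD Cohen's d per contrast, averaged over the test
contrasts 0.5-32%), ROC separability (rank-statistic AUC), per-session
metric-vs-reaction-time regressions with group-level tests, 10-90% rise
times, the leave-one-out pre-stimulus predictability statistic delta,
inter-trial activation-pattern consistency with a within-orientation
shuffle, orientation-averaged noise correlations, Clopper-Pearson
binomial intervals, and Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .preprocess import TrialResponseMatrix, TuningAssignment
from .session import TEST_CONTRASTS


# ---------------------------------------------------------------------------
# Effect size and ROC
# ---------------------------------------------------------------------------

def cohens_d(group_a, group_b) -> float:
    """(mean_a - mean_b) / pooled SD."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    pooled_var = (((a.size - 1) * a.var(ddof=1)
                   + (b.size - 1) * b.var(ddof=1))
                  / (a.size + b.size - 2))
    if pooled_var == 0:
        raise ValueError("pooled SD is zero")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def effect_size_by_contrast(metric_values: np.ndarray,
                            contrasts: np.ndarray,
                            outcomes: np.ndarray,
                            test_contrasts=TEST_CONTRASTS) -> dict:
    """Hit-vs-miss Cohen's d per test contrast plus their mean."""
    per_contrast = {}
    for c in test_contrasts:
        hits = metric_values[(contrasts == c) & (outcomes == "hit")]
        misses = metric_values[(contrasts == c) & (outcomes == "miss")]
        if hits.size >= 2 and misses.size >= 2:
            per_contrast[c] = cohens_d(hits, misses)
        else:
            per_contrast[c] = np.nan
    vals = [v for v in per_contrast.values() if np.isfinite(v)]
    return {"per_contrast": per_contrast,
            "mean": float(np.mean(vals)) if vals else np.nan}


def roc_auc(hit_values, miss_values) -> float:
    """Area under the ROC curve via the rank statistic.

    Equals the probability that a random hit value exceeds a random
    miss value, ties counted half (Mann-Whitney U / (n_h * n_m)).
    """
    h = np.asarray(hit_values, float)
    m = np.asarray(miss_values, float)
    if h.size == 0 or m.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([h, m])
    ranks = sps.rankdata(combined)
    u = ranks[:h.size].sum() - h.size * (h.size + 1) / 2.0
    return float(u / (h.size * m.size))


def auc_by_contrast(metric_values, contrasts, outcomes,
                    test_contrasts=TEST_CONTRASTS) -> dict:
    per_contrast = {}
    for c in test_contrasts:
        hits = metric_values[(contrasts == c) & (outcomes == "hit")]
        misses = metric_values[(contrasts == c) & (outcomes == "miss")]
        # a stratum needs >= 2 trials per group to say anything about
        # separability (same guard as the effect-size average)
        per_contrast[c] = (roc_auc(hits, misses)
                           if hits.size >= 2 and misses.size >= 2
                           else np.nan)
    vals = [v for v in per_contrast.values() if np.isfinite(v)]
    return {"per_contrast": per_contrast,
            "mean": float(np.mean(vals)) if vals else np.nan}


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def regress_metric_on_rt(metric_values, reaction_times) -> RegressionResult:
    """OLS of a per-trial metric on hit reaction times (one session)."""
    m = np.asarray(metric_values, float)
    rt = np.asarray(reaction_times, float)
    ok = np.isfinite(m) & np.isfinite(rt)
    m, rt = m[ok], rt[ok]
    if m.size < 3:
        raise ValueError("need >= 3 trials with reaction times")
    if np.ptp(rt) == 0:
        raise ValueError("degenerate reaction-time variance")
    fit = sps.linregress(rt, m)
    return RegressionResult(slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue ** 2),
                            p_value=float(fit.pvalue),
                            n=int(m.size))


def group_slope_test(slopes: Sequence[float], n_comparisons: int = 1,
                     ) -> dict:
    """One-sample t-test of per-session slopes vs 0, Holm-adjusted."""
    slopes = np.asarray(slopes, float)
    t, p = sps.ttest_1samp(slopes, 0.0)
    p_adj = min(1.0, p * n_comparisons)  # Bonferroni-Holm, single rank
    return {"mean_slope": float(slopes.mean()), "t": float(t),
            "p": float(p), "p_holm": float(p_adj)}


# ---------------------------------------------------------------------------
# Rise time
# ---------------------------------------------------------------------------

def rise_time_10_90(times: np.ndarray, trace: np.ndarray,
                    baseline_window=(-3.0, 0.0)) -> float:
    """10-90% rise time of a trial-averaged metric trace.

    Baseline is the mean over the pre-stimulus window; the 10% and 90%
    levels of the baseline-to-maximum excursion are located by linear
    interpolation at their first crossings after onset.  Returns NaN
    (undefined) when the maximum does not exceed baseline.
    """
    times = np.asarray(times, float)
    trace = np.asarray(trace, float)
    base_mask = (times >= baseline_window[0]) & (times < baseline_window[1])
    if not base_mask.any():
        raise ValueError("trace does not cover the baseline window")
    baseline = trace[base_mask].mean()
    stim = times >= 0
    if not stim.any():
        raise ValueError("trace does not cover the stimulus period")
    peak = trace[stim].max()
    if peak <= baseline:
        return np.nan
    lo = baseline + 0.1 * (peak - baseline)
    hi = baseline + 0.9 * (peak - baseline)

    def first_crossing(level):
        t_s = times[stim]
        y = trace[stim]
        above = y >= level
        if above[0]:
            return t_s[0]
        idx = np.nonzero(above)[0]
        if idx.size == 0:
            return np.nan
        j = idx[0]
        # linear interpolation between j-1 and j
        t0, t1 = t_s[j - 1], t_s[j]
        y0, y1 = y[j - 1], y[j]
        return t0 + (level - y0) / (y1 - y0) * (t1 - t0)

    t10 = first_crossing(lo)
    t90 = first_crossing(hi)
    return float(t90 - t10)


# ---------------------------------------------------------------------------
# Pre-stimulus predictability (delta)
# ---------------------------------------------------------------------------

@dataclass
class PredictabilityResult:
    deltas: np.ndarray
    mean: float
    pair: tuple


def prestim_predictability_delta(points_r1, points_r2) -> PredictabilityResult:
    """Leave-one-out separability of two response-type point groups.

    For each point i of group r1,
    ``delta = 2 * (d(i, mu_r2) / (d(i, mu_r2) + d(i, mu_r1_without_i)) - 0.5)``
    so +1 means i sits on its own group's leave-one-out mean, -1 on the
    other group's mean, and random placement averages 0.
    """
    a = np.atleast_2d(np.asarray(points_r1, float))
    b = np.atleast_2d(np.asarray(points_r2, float))
    if a.shape[0] == 1 and a.size > 1 and np.ndim(points_r1) == 1:
        a = a.T
    if b.shape[0] == 1 and b.size > 1 and np.ndim(points_r2) == 1:
        b = b.T
    if a.shape[0] < 2:
        raise ValueError("need >= 2 points in the reference group")
    mu_other = b.mean(axis=0)
    deltas = np.empty(a.shape[0])
    for i in range(a.shape[0]):
        own = np.delete(a, i, axis=0).mean(axis=0)
        d_other = np.linalg.norm(a[i] - mu_other)
        d_own = np.linalg.norm(a[i] - own)
        total = d_other + d_own
        deltas[i] = 0.0 if total == 0 else 2.0 * (d_other / total - 0.5)
    return PredictabilityResult(deltas=deltas, mean=float(deltas.mean()),
                                pair=("r1", "r2"))


# ---------------------------------------------------------------------------
# Pattern consistency
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyResult:
    real: dict          # (population, response_type) -> mean pair correlation
    shuffled: dict
    omitted: list = field(default_factory=list)


def _mean_pair_correlation(vectors: np.ndarray) -> float:
    """Mean Pearson correlation over unique pairs of columns."""
    T = vectors.shape[1]
    if T < 2:
        return np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        cm = np.corrcoef(vectors.T)
    iu = np.triu_indices(T, k=1)
    return float(np.nanmean(cm[iu]))


def pattern_consistency(responses: TrialResponseMatrix,
                        tuning: TuningAssignment,
                        labels: np.ndarray,
                        shuffle_iterations: int = 100,
                        rng=None,
                        test_contrasts=TEST_CONTRASTS,
                        shuffle_scope: str = "orientation",
                        ) -> ConsistencyResult:
    """Inter-trial correlation of response vectors by response type.

    For each orientation (test contrasts pooled) and each response type
    in ``labels`` (e.g. miss/slow/fast), the mean pairwise Pearson
    correlation between same-type trial response vectors is computed
    separately for the preferred population (neurons tuned to that
    orientation) and the nonpreferred population, then averaged over
    orientations.  The shuffle null permutes each neuron's responses
    across trials (response types mixed), preserving the orientation
    signal but destroying trial identity.

    ``shuffle_scope`` controls the permutation stratum: "orientation"
    mixes all test-contrast trials of an orientation, whereas
    "orientation_contrast" permutes within each (orientation, contrast)
    cell, additionally preserving each neuron's contrast-response
    profile.  The latter makes the real-vs-shuffled excess insensitive
    to response types having different contrast compositions (hits skew
    toward high contrast), which otherwise inflates same-type pair
    correlations for reasons unrelated to trial-specific coupling.
    """
    if shuffle_scope not in ("orientation", "orientation_contrast"):
        raise ValueError(f"unknown shuffle_scope {shuffle_scope!r}")
    rng = np.random.default_rng(rng)
    R = responses.values
    oris = responses.orientations()
    cons = responses.contrasts()
    labels = np.asarray(labels, dtype=object)
    types = [t for t in ("miss", "slow", "fast")
             if t in labels] or list(pd_unique(labels))
    in_test = np.isin(cons, test_contrasts)

    real: dict = {}
    shuffled: dict = {}
    omitted = []
    consistent = tuning.consistent
    for pop_name in ("preferred", "nonpreferred"):
        for rtype in types:
            per_ori_real, per_ori_sh = [], []
            for o in np.unique(oris[in_test]):
                if pop_name == "preferred":
                    neurons = consistent & (tuning.preferred_orientation == o)
                else:
                    neurons = consistent & (tuning.preferred_orientation != o)
                cols_all = in_test & (oris == o)
                cols = cols_all & (labels == rtype)
                if neurons.sum() < 2 or cols.sum() < 2:
                    omitted.append((pop_name, rtype, o))
                    continue
                vecs = R[np.ix_(neurons, np.nonzero(cols)[0])]
                per_ori_real.append(_mean_pair_correlation(vecs))

                # shuffle trial identities per neuron within the scope
                pool_idx = np.nonzero(cols_all)[0]
                sel = np.isin(pool_idx, np.nonzero(cols)[0])
                sub = R[np.ix_(neurons, pool_idx)]
                if shuffle_scope == "orientation":
                    groups = [np.arange(pool_idx.size)]
                else:
                    pool_cons = cons[pool_idx]
                    groups = [np.nonzero(pool_cons == c)[0]
                              for c in np.unique(pool_cons)]
                sh_vals = np.empty(shuffle_iterations)
                n_sub = sub.shape[0]
                for it in range(shuffle_iterations):
                    perm = np.tile(np.arange(pool_idx.size), (n_sub, 1))
                    for g in groups:
                        order = np.argsort(rng.random((n_sub, g.size)),
                                           axis=1)
                        perm[:, g] = g[order]
                    shuf = np.take_along_axis(sub, perm, axis=1)
                    sh_vals[it] = _mean_pair_correlation(shuf[:, sel])
                per_ori_sh.append(float(np.nanmean(sh_vals)))
            real[(pop_name, rtype)] = (float(np.nanmean(per_ori_real))
                                       if per_ori_real else np.nan)
            shuffled[(pop_name, rtype)] = (float(np.nanmean(per_ori_sh))
                                           if per_ori_sh else np.nan)
    return ConsistencyResult(real=real, shuffled=shuffled, omitted=omitted)


def pd_unique(values):
    seen = []
    for v in values:
        if v not in seen:
            seen.append(v)
    return seen


# ---------------------------------------------------------------------------
# Noise correlations
# ---------------------------------------------------------------------------

@dataclass
class NoiseCorrelationMatrix:
    values: np.ndarray        # [n x n], mean over orientations, NaN diagonal
    orientations_used: list
    flagged: list = field(default_factory=list)

    def mean_offdiag(self) -> float:
        iu = np.triu_indices(self.values.shape[0], k=1)
        return float(np.nanmean(self.values[iu]))


def noise_correlations(responses: TrialResponseMatrix,
                       subset_mask: Optional[np.ndarray] = None,
                       min_repetitions: int = 3,
                       test_contrasts=TEST_CONTRASTS) -> NoiseCorrelationMatrix:
    """Pairwise trial-by-trial correlations averaged over orientations.

    Per orientation, each neuron's responses over repetitions (test-
    contrast trials, optionally restricted to a subset such as the
    fastest or slowest half) form a vector; the per-pair Pearson
    correlation of those vectors is averaged over the 4 orientations.
    Orientations with too few repetitions, and pairs with zero-variance
    vectors, are excluded from the average.
    """
    R = responses.values
    oris = responses.orientations()
    cons = responses.contrasts()
    keep = np.isin(cons, test_contrasts)
    if subset_mask is not None:
        keep = keep & np.asarray(subset_mask, bool)
    n = R.shape[0]
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n))
    used, flagged = [], []
    for o in np.unique(oris):
        cols = keep & (oris == o)
        if cols.sum() < min_repetitions:
            flagged.append((o, "too few repetitions"))
            continue
        sub = R[:, cols]
        sd = sub.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cm = np.corrcoef(sub)
        valid = (sd > 0)[:, None] & (sd > 0)[None, :]
        acc[valid] += cm[valid]
        cnt[valid] += 1
        used.append(o)
        if not valid.all():
            flagged.append((o, "zero-variance neurons excluded"))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = acc / cnt
    np.fill_diagonal(mean, np.nan)
    return NoiseCorrelationMatrix(values=mean, orientations_used=used,
                                  flagged=flagged)


# ---------------------------------------------------------------------------
# Behavioral statistics
# ---------------------------------------------------------------------------

def clopper_pearson_ci(successes: int, trials: int,
                       level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes outside [0, trials]")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(
        sps.beta.ppf(alpha / 2.0, successes, trials - successes + 1))
    upper = 1.0 if successes == trials else float(
        sps.beta.ppf(1.0 - alpha / 2.0, successes + 1, trials - successes))
    return lower, upper


def significant_detection(probe0: tuple[int, int],
                          probe100: tuple[int, int],
                          level: float = 0.95) -> bool:
    """Non-overlap of the 0%- and 100%-probe response-rate intervals."""
    lo0, hi0 = clopper_pearson_ci(*probe0, level)
    lo100, hi100 = clopper_pearson_ci(*probe100, level)
    return hi0 < lo100 or hi100 < lo0


def fdr_correct(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def split_fast_slow(responses: TrialResponseMatrix) -> np.ndarray:
    """Label each trial miss / slow / fast (or "" for probes and FAs).

    Hits are median-split on reaction time *per contrast*; with an odd
    count the median trial goes to slow.  A contrast with a single hit
    labels it slow.
    """
    outs = responses.outcomes()
    cons = responses.contrasts()
    rts = responses.reaction_times()
    labels = np.array([""] * len(outs), dtype=object)
    labels[outs == "miss"] = "miss"
    for c in np.unique(cons[outs == "hit"]):
        idx = np.nonzero((outs == "hit") & (cons == c))[0]
        order = idx[np.argsort(rts[idx], kind="stable")]
        n_fast = len(order) // 2
        labels[order[:n_fast]] = "fast"
        labels[order[n_fast:]] = "slow"
    return labels
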