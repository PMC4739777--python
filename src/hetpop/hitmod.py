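"""Hit-modulation index and its neuron/trial decomposition.

For each hit trial t and neuron i, the hit-modulation index is the
neuron's response z-scored against the *miss* trials of the same
stimulus (identical orientation and contrast):

    psi_{i,t} = (R_{i,t} - mu_{m,c,theta}) / sigma_{m,c,theta}

The resulting matrix is approximated by neuron identity (row means),
trial fluctuations (column means), or both (sum of the two marginal
matrices), and each approximation's explained variance uses an
*uncentered* total sum of squares (SS_tot = sum of squared psi values).
Significance comes from shuffle nulls that permute neuron identities
within trials, trial identities within neurons, or both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .preprocess import TrialResponseMatrix
from .session import TEST_CONTRASTS


@dataclass
class HitModulationMatrix:
    values: np.ndarray                 # [n_neurons x n_hit_trials]
    orientations: np.ndarray           # per column
    contrasts: np.ndarray              # per column
    dropped_strata: list = field(default_factory=list)


def hit_modulation_matrix(responses: TrialResponseMatrix,
                          contrasts=TEST_CONTRASTS) -> HitModulationMatrix:
    """psi per neuron per hit trial vs same-(orientation, contrast) misses.

    Strata with fewer than 2 miss trials (or zero miss SD) cannot
    provide a reference distribution; their hit columns are dropped and
    reported.
    """
    R = responses.values
    oris = responses.orientations()
    cons = responses.contrasts()
    outs = responses.outcomes()

    cols, col_ori, col_con, dropped = [], [], [], []
    for c in contrasts:
        for o in np.unique(oris):
            stratum = (cons == c) & (oris == o)
            hits = stratum & (outs == "hit")
            misses = stratum & (outs == "miss")
            if not hits.any():
                continue
            if misses.sum() < 2:
                dropped.append((o, c, "fewer than 2 miss trials"))
                continue
            mu = R[:, misses].mean(axis=1)
            sigma = R[:, misses].std(axis=1, ddof=1)
            if np.any(sigma == 0):
                dropped.append((o, c, "zero miss SD"))
                continue
            psi = (R[:, hits] - mu[:, None]) / sigma[:, None]
            cols.append(psi)
            col_ori.extend([o] * int(hits.sum()))
            col_con.extend([c] * int(hits.sum()))

    values = np.concatenate(cols, axis=1) if cols else np.empty(
        (R.shape[0], 0))
    return HitModulationMatrix(
        values=values,
        orientations=np.array(col_ori),
        contrasts=np.array(col_con),
        dropped_strata=dropped,
    )


def _r_squared(psi: np.ndarray, approx: np.ndarray) -> float:
    ss_tot = float((psi ** 2).sum())
    if ss_tot == 0:
        raise ValueError("SS_tot is zero")
    ss_res = float(((psi - approx) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def _approximation(psi: np.ndarray, mode: str,
                   grand_mean_corrected: bool = False) -> np.ndarray:
    by_neuron = np.broadcast_to(psi.mean(axis=1, keepdims=True), psi.shape)
    by_trial = np.broadcast_to(psi.mean(axis=0, keepdims=True), psi.shape)
    if mode == "neuron":
        return by_neuron
    if mode == "trial":
        return by_trial
    if mode == "both":
        both = by_neuron + by_trial
        if grand_mean_corrected:
            both = both - psi.mean()
        return both
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class DecompositionResult:
    r_squared: dict
    shuffle_mean: dict
    shuffle_sd: dict
    significant: dict
    frac_modulated_neurons: float
    frac_modulated_shuffle_mean: float
    frac_modulated_shuffle_sd: float
    frac_modulated_significant: bool


def decompose(psi: HitModulationMatrix, iterations: int = 1000,
              alpha: float = 0.05, rng=None,
              grand_mean_corrected: bool = False) -> DecompositionResult:
    """Explained variance of psi by neuron identity, trial fluctuations,
    or both, each against its shuffle null.

    A mode is significant when its real R^2 is at least 2 shuffle SDs
    above the shuffle mean.  The fraction of significantly hit-modulated
    neurons (two-sided one-sample t-test of each neuron's psi row vs 0)
    is judged against the same 2-SD criterion under the "both" shuffle.
    """
    rng = np.random.default_rng(rng)
    P = psi.values
    if P.size == 0:
        raise ValueError("empty hit-modulation matrix")
    n, T = P.shape
    modes = ("neuron", "trial", "both")

    real = {m: _r_squared(P, _approximation(P, m, grand_mean_corrected))
            for m in modes}

    def shuffled(mode):
        Q = P
        if mode in ("neuron", "both"):
            idx = np.argsort(rng.random((n, T)), axis=0)
            Q = Q[idx, np.arange(T)[None, :]]
        if mode in ("trial", "both"):
            idx = np.argsort(rng.random((n, T)), axis=1)
            Q = Q[np.arange(n)[:, None], idx]
        return Q

    sh_mean, sh_sd, signif = {}, {}, {}
    frac_sh = np.empty(iterations)
    frac_real = _fraction_modulated(P, alpha)
    sh_vals = {m: np.empty(iterations) for m in modes}
    for it in range(iterations):
        for m in modes:
            Q = shuffled(m)
            sh_vals[m][it] = _r_squared(
                Q, _approximation(Q, m, grand_mean_corrected))
            if m == "both":
                frac_sh[it] = _fraction_modulated(Q, alpha)
    for m in modes:
        sh_mean[m] = float(sh_vals[m].mean())
        sh_sd[m] = float(sh_vals[m].std())
        signif[m] = real[m] >= sh_mean[m] + 2.0 * sh_sd[m]

    return DecompositionResult(
        r_squared=real,
        shuffle_mean=sh_mean,
        shuffle_sd=sh_sd,
        significant=signif,
        frac_modulated_neurons=frac_real,
        frac_modulated_shuffle_mean=float(frac_sh.mean()),
        frac_modulated_shuffle_sd=float(frac_sh.std()),
        frac_modulated_significant=bool(
            frac_real >= frac_sh.mean() + 2.0 * frac_sh.std()),
    )


def _fraction_modulated(P: np.ndarray, alpha: float) -> float:
    _, p = sps.ttest_1samp(P, 0.0, axis=1)
    return float(np.mean(p < alpha))
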