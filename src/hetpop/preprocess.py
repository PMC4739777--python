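"""Fluorescence to per-trial response matrices.

Steps, in pipeline order: sliding dF/F0 baseline (mean of the lowest
50% of a 30 s window centred on each frame), optional neuropil
subtraction (F_corr = F_soma - r * F_neuropil with r the per-neuron
soma/neuropil correlation), soma/neuropil discriminability QC, trial
response extraction with fast-lick exclusion and miss-duration
matching, per-neuron z-scoring, and preferred-orientation assignment
with a block-consistency filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .session import (
    AnalysisConfig,
    ORIENTATIONS,
    SessionData,
    TrialRecord,
)

STIMULUS_MAX_S = 3.0


# ---------------------------------------------------------------------------
# dF/F0
# ---------------------------------------------------------------------------

def compute_dff(fluorescence: np.ndarray, frame_rate: float,
                baseline_window_s: float = 30.0,
                stride: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-percentile dF/F0.

    For each frame i, the baseline F0_i is the mean of the lowest 50% of
    values in a ``baseline_window_s`` window centred on i (truncated at
    the recording edges); dF/F_i = (F_i - F0_i) / F0_i.

    ``stride`` > 1 evaluates F0 on every ``stride``-th frame and
    linearly interpolates between them; the baseline varies on the
    window's 30 s timescale, so a sub-second stride changes the result
    negligibly while cutting cost by ``1/stride``.

    Returns ``(dff, degenerate)`` where ``degenerate`` flags neurons
    whose baseline is not strictly positive somewhere (their dF/F is
    NaN at those frames).
    """
    f = np.atleast_2d(np.asarray(fluorescence, float))
    n, n_frames = f.shape
    window = int(round(baseline_window_s * frame_rate))
    window = max(3, min(window, n_frames))
    if stride < 1:
        raise ValueError("stride must be >= 1")
    half = window // 2

    centers = np.arange(0, n_frames, stride)
    if centers[-1] != n_frames - 1:
        centers = np.append(centers, n_frames - 1)

    f0 = np.empty((n, centers.size))
    # interior frames share a full-width window: vectorized partition
    interior = (centers >= half) & (centers + (window - half) <= n_frames)
    k = max(1, window // 2)  # lowest 50%
    for i in range(n):
        row = f[i]
        if interior.any():
            sw = sliding_window_view(row, window)
            starts = centers[interior] - half
            chunk = 2048
            vals = np.empty(starts.size)
            for s in range(0, starts.size, chunk):
                blk = sw[starts[s:s + chunk]]
                vals[s:s + chunk] = np.mean(
                    np.partition(blk, k - 1, axis=1)[:, :k], axis=1)
            f0[i, interior] = vals
        for j in np.nonzero(~interior)[0]:
            c = centers[j]
            lo = max(0, c - half)
            hi = min(n_frames, c + (window - half))
            seg = np.sort(row[lo:hi])
            kk = max(1, (hi - lo) // 2)
            f0[i, j] = seg[:kk].mean()

    if centers.size < n_frames:
        frames = np.arange(n_frames)
        f0_full = np.empty_like(f)
        for i in range(n):
            f0_full[i] = np.interp(frames, centers, f0[i])
    else:
        f0_full = f0

    degenerate = (f0_full <= 0).any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (f - f0_full) / f0_full
    dff[f0_full <= 0] = np.nan
    return dff, degenerate


def neuropil_correct(soma: np.ndarray, neuropil: np.ndarray,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the correlated neuropil component per neuron.

    ``F_corr = F_soma - r * F_neuropil`` with r the Pearson correlation
    over frames between each neuron's somatic and surrounding neuropil
    fluorescence.  Zero-variance neuropil gives r = 0 (no correction).
    """
    soma = np.atleast_2d(np.asarray(soma, float))
    neuropil = np.atleast_2d(np.asarray(neuropil, float))
    if soma.shape != neuropil.shape:
        raise ValueError(f"shape mismatch: soma {soma.shape} vs "
                         f"neuropil {neuropil.shape}")
    s = soma - soma.mean(axis=1, keepdims=True)
    p = neuropil - neuropil.mean(axis=1, keepdims=True)
    s_sd = s.std(axis=1)
    p_sd = p.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (s * p).mean(axis=1) / (s_sd * p_sd)
    r[(p_sd == 0) | (s_sd == 0)] = 0.0
    corrected = soma - r[:, None] * neuropil
    return corrected, r


@dataclass
class QCReport:
    """Soma/neuropil discriminability per neuron."""

    discriminability: np.ndarray      # [n x frames], D_r in [0, 1]
    max_subthreshold_s: np.ndarray    # per neuron, seconds
    flagged: np.ndarray               # per neuron, epoch > 1.0 s
    neuropil_r: Optional[np.ndarray] = None


def discriminability_qc(soma: np.ndarray, neuropil: np.ndarray,
                        frame_rate: float,
                        threshold: float = 0.5,
                        max_epoch_s: float = 1.0) -> QCReport:
    """Per-frame D_r = F_soma / (F_soma + F_neuropil) with epoch flags.

    A neuron is flagged when D_r stays at or below 0.5 (soma no brighter
    than neuropil) for a contiguous epoch longer than 1.0 s.
    """
    soma = np.atleast_2d(np.asarray(soma, float))
    neuropil = np.atleast_2d(np.asarray(neuropil, float))
    if soma.shape != neuropil.shape:
        raise ValueError("soma/neuropil shape mismatch")
    with np.errstate(divide="ignore", invalid="ignore"):
        d_r = soma / (soma + neuropil)
    below = d_r <= threshold
    n, n_frames = below.shape
    max_epochs = np.zeros(n)
    for i in range(n):
        run = best = 0
        for b in below[i]:
            run = run + 1 if b else 0
            best = max(best, run)
        max_epochs[i] = best / frame_rate
    return QCReport(
        discriminability=d_r,
        max_subthreshold_s=max_epochs,
        flagged=max_epochs > max_epoch_s,
    )


# ---------------------------------------------------------------------------
# Trial responses
# ---------------------------------------------------------------------------

@dataclass
class TrialResponseMatrix:
    """Mean dF/F0 per neuron over each trial's analysis interval."""

    values: np.ndarray                 # [n_neurons x n_trials]
    trial_refs: list[TrialRecord]
    neuron_ids: np.ndarray
    excluded: list[TrialRecord] = field(default_factory=list)

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    def column_attr(self, fn) -> np.ndarray:
        return np.array([fn(tr) for tr in self.trial_refs])

    def orientations(self) -> np.ndarray:
        return self.column_attr(lambda tr: tr.condition.orientation)

    def contrasts(self) -> np.ndarray:
        return self.column_attr(lambda tr: tr.condition.contrast)

    def outcomes(self) -> np.ndarray:
        return self.column_attr(lambda tr: tr.outcome)

    def reaction_times(self) -> np.ndarray:
        return self.column_attr(
            lambda tr: np.nan if tr.reaction_time is None
            else tr.reaction_time)

    def subset(self, mask) -> "TrialResponseMatrix":
        mask = np.asarray(mask)
        idx = np.nonzero(mask)[0] if mask.dtype == bool else mask
        return TrialResponseMatrix(
            values=self.values[:, idx],
            trial_refs=[self.trial_refs[i] for i in idx],
            neuron_ids=self.neuron_ids,
            excluded=self.excluded,
        )


def extract_trial_responses(session: SessionData, dff: np.ndarray,
                            config: Optional[AnalysisConfig] = None,
                            ) -> TrialResponseMatrix:
    """Mean dF/F over each trial's analysis window.

    Response trials faster than the 150 ms exclusion threshold are
    discarded (reason ``fast_lick``) because such licks cannot be
    stimulus-driven.  To equalise acquisition duration between hits and
    misses, each miss trial's window is truncated to a duration drawn
    (seeded) from the hit reaction-time distribution of the same
    contrast; contrasts with no hits fall back to the pooled hit RT
    distribution.
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(config.rng_seed)
    fs = session.frame_rate

    hit_rts: dict[float, list[float]] = {}
    for tr in session.trials:
        if tr.outcome == "hit" and tr.reaction_time is not None \
                and tr.reaction_time >= config.rt_exclusion_s:
            hit_rts.setdefault(tr.condition.contrast, []).append(
                tr.reaction_time)
    pooled_rts = [rt for rts in hit_rts.values() for rt in rts]

    kept, excluded, columns = [], [], []
    for tr in session.trials:
        if tr.is_response and tr.reaction_time is not None \
                and tr.reaction_time < config.rt_exclusion_s:
            tr.excluded = True
            tr.exclusion_reason = "fast_lick"
            excluded.append(tr)
            continue
        if tr.outcome == "miss":
            pool = hit_rts.get(tr.condition.contrast) or pooled_rts
            if pool:
                dur = float(rng.choice(pool))
            else:
                dur = STIMULUS_MAX_S
            end = tr.onset_frame + max(1, int(round(dur * fs)))
            tr.analysis_offset_frame = min(end, tr.offset_frame)
        else:
            tr.analysis_offset_frame = tr.offset_frame
        resp = np.nanmean(dff[:, tr.onset_frame:tr.analysis_offset_frame],
                          axis=1)
        kept.append(tr)
        columns.append(resp)

    values = np.column_stack(columns) if columns else np.empty(
        (dff.shape[0], 0))
    return TrialResponseMatrix(
        values=values,
        trial_refs=kept,
        neuron_ids=np.arange(dff.shape[0]),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# z-scoring
# ---------------------------------------------------------------------------

@dataclass
class ZScoreMatrix:
    """Trial responses in per-neuron SD units (sample SD, ddof=1)."""

    values: np.ndarray                 # [n_neurons x n_trials]
    scope: str
    mu: np.ndarray
    sigma: np.ndarray
    trial_refs: list[TrialRecord]
    neuron_ids: np.ndarray
    dropped_neurons: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int))

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]


def zscore_responses(responses: TrialResponseMatrix,
                     scope: str = "global") -> ZScoreMatrix:
    """z = (R - mu_i) / sigma_i per neuron, globally or per contrast.

    Global scope normalizes each neuron over all trial types (so
    high-contrast preferred stimuli get large z); per-contrast scope
    normalizes within each contrast stratum.  Zero-variance neurons are
    dropped.
    """
    R = responses.values
    if scope == "global":
        mu = R.mean(axis=1)
        sigma = R.std(axis=1, ddof=1)
    elif scope == "per_contrast":
        contrasts = responses.contrasts()
        mu = np.empty_like(R)
        sigma = np.empty_like(R)
        for c in np.unique(contrasts):
            cols = contrasts == c
            if cols.sum() < 2:
                raise ValueError(
                    f"contrast {c}: need >= 2 trials to z-score")
            mu[:, cols] = R[:, cols].mean(axis=1, keepdims=True)
            sigma[:, cols] = R[:, cols].std(axis=1, ddof=1, keepdims=True)
    else:
        raise ValueError(f"unknown scope {scope!r}")

    sig_per_neuron = sigma if sigma.ndim == 1 else sigma.min(axis=1)
    keep = sig_per_neuron > 0
    dropped = np.nonzero(~keep)[0]
    if sigma.ndim == 1:
        z = (R[keep] - mu[keep, None]) / sigma[keep, None]
    else:
        z = (R[keep] - mu[keep]) / sigma[keep]
    return ZScoreMatrix(
        values=z,
        scope=scope,
        mu=mu[keep] if mu.ndim == 1 else mu[keep],
        sigma=sigma[keep] if sigma.ndim == 1 else sigma[keep],
        trial_refs=responses.trial_refs,
        neuron_ids=responses.neuron_ids[keep],
        dropped_neurons=responses.neuron_ids[dropped],
    )


# ---------------------------------------------------------------------------
# Preferred orientation
# ---------------------------------------------------------------------------

@dataclass
class TuningAssignment:
    preferred_orientation: np.ndarray   # degrees, per neuron
    per_block: pd.DataFrame             # neuron x block preferences
    consistent: np.ndarray              # bool per neuron
    ties: list = field(default_factory=list)


def _argmax_orientation(means: np.ndarray) -> tuple[float, bool]:
    """Index of the best orientation; ties break toward the lowest angle."""
    best = np.nanmax(means)
    winners = np.nonzero(means == best)[0]
    return ORIENTATIONS[winners[0]], len(winners) > 1


def assign_preferred_orientation(responses: TrialResponseMatrix,
                                 ) -> TuningAssignment:
    """Preferred orientation = argmax of mean response over 4 orientations.

    All non-probe contrasts are pooled.  Per-block preferences are also
    computed; a neuron is *consistent* when the fraction of blocks whose
    preference differs from its modal preference does not exceed 1/3.
    """
    R = responses.values
    oris = responses.orientations()
    contrasts = responses.contrasts()
    blocks = responses.column_attr(lambda tr: tr.block_index)
    informative = contrasts > 0
    n = R.shape[0]

    def ori_means(mask):
        out = np.full((n, len(ORIENTATIONS)), np.nan)
        for j, o in enumerate(ORIENTATIONS):
            cols = mask & (oris == o)
            if cols.any():
                out[:, j] = R[:, cols].mean(axis=1)
        return out

    overall = ori_means(informative)
    preferred = np.empty(n)
    ties = []
    for i in range(n):
        preferred[i], tied = _argmax_orientation(overall[i])
        if tied:
            ties.append(i)

    block_ids = sorted(set(blocks))
    per_block = np.full((n, len(block_ids)), np.nan)
    for bj, b in enumerate(block_ids):
        bm = ori_means(informative & (blocks == b))
        for i in range(n):
            if not np.all(np.isnan(bm[i])):
                per_block[i, bj], _ = _argmax_orientation(bm[i])

    consistent = np.empty(n, dtype=bool)
    for i in range(n):
        prefs = per_block[i][~np.isnan(per_block[i])]
        if prefs.size == 0:
            consistent[i] = False
            continue
        vals, counts = np.unique(prefs, return_counts=True)
        modal = vals[np.argmax(counts)]
        disagree = np.mean(prefs != modal)
        consistent[i] = disagree <= (1.0 / 3.0)

    return TuningAssignment(
        preferred_orientation=preferred,
        per_block=pd.DataFrame(per_block,
                               columns=[f"block_{b}" for b in block_ids]),
        consistent=consistent,
        ties=ties,
    )
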