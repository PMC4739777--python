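"""Per-trial population statistics.

The central quantity is *population heterogeneity* h_t: for one trial,
z-score every neuron's response over all trials, form the matrix of
absolute pairwise z differences H_t = |z_t - z_t^T|, and average its
n(n-1)/2 unique entries.  High h_t means the neurons were activated
dissimilarly on that trial.

Comparators: a multidimensional variant (Euclidean distance from the
population vector to the all-equal diagonal of neural space), the
instantaneous Pearson-like correlation (per-trial mean and SD of
pairwise products of z-scores; unbounded, but its mean over trials
recovers the ordinary Pearson matrix), across-neuron variance and
sparseness (kurtosis), and Gaussian-windowed sliding correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import kurtosis as _kurtosis

from .preprocess import TrialResponseMatrix, ZScoreMatrix


@dataclass
class MetricSeries:
    """One scalar per trial (or per frame in time-resolved mode)."""

    metric_name: str
    values: np.ndarray
    units: str = ""

    def __len__(self):
        return len(self.values)


def _as_matrix(z) -> np.ndarray:
    if isinstance(z, (ZScoreMatrix, TrialResponseMatrix)):
        return z.values
    return np.atleast_2d(np.asarray(z, float))


def heterogeneity_matrix(z_t: np.ndarray) -> np.ndarray:
    """H_t = |z_t - z_t^T| for one trial's population vector."""
    z_t = np.asarray(z_t, float)
    return np.abs(z_t[:, None] - z_t[None, :])


def heterogeneity(z) -> MetricSeries:
    """Mean absolute pairwise z difference per trial (h_t)."""
    Z = _as_matrix(z)
    n = Z.shape[0]
    if n < 2:
        raise ValueError("heterogeneity needs >= 2 neurons")
    diff = np.abs(Z[:, None, :] - Z[None, :, :])
    iu = np.triu_indices(n, k=1)
    vals = diff[iu].mean(axis=0)
    return MetricSeries("heterogeneity", vals, units="SD")


def multidim_heterogeneity(r) -> MetricSeries:
    """Euclidean distance from each trial's point to the main diagonal.

    The projection of a population vector r onto the all-equal diagonal
    is mean(r) * 1, so the distance is sqrt(sum_i (r_i - mean(r))^2).
    """
    R = _as_matrix(r)
    if R.shape[0] < 2:
        raise ValueError("needs >= 2 neurons")
    dev = R - R.mean(axis=0, keepdims=True)
    vals = np.sqrt((dev ** 2).sum(axis=0))
    return MetricSeries("multidim_heterogeneity", vals,
                        units="point-space distance")


def pearson_like(z) -> tuple[MetricSeries, MetricSeries]:
    """Instantaneous Pearson-like correlation: per-trial pair statistics.

    Per trial, the pairwise products z_x,t * z_y,t over unique pairs
    give a distribution whose mean is the per-trial correlation proxy
    and whose SD (population SD over pairs) is its spread.  Both use
    closed-form pair sums, so no pair matrix is materialized.
    """
    Z = _as_matrix(z)
    n = Z.shape[0]
    if n < 2:
        raise ValueError("needs >= 2 neurons")
    npairs = n * (n - 1) / 2.0
    s1 = Z.sum(axis=0)
    s2 = (Z ** 2).sum(axis=0)
    pair_sum = (s1 ** 2 - s2) / 2.0
    mean = pair_sum / npairs
    # sum over pairs of (z_i z_j)^2 = ((sum z^2)^2 - sum z^4) / 2
    pair_sq = (s2 ** 2 - (Z ** 4).sum(axis=0)) / 2.0
    var = np.maximum(pair_sq / npairs - mean ** 2, 0.0)
    return (MetricSeries("pearson_like_mean", mean),
            MetricSeries("pearson_like_spread", np.sqrt(var)))


def variance_metric(z) -> MetricSeries:
    """Across-neuron sample variance per trial."""
    Z = _as_matrix(z)
    return MetricSeries("variance", Z.var(axis=0, ddof=1))


def sparseness_kurtosis(z) -> MetricSeries:
    """Across-neuron kurtosis per trial (raw fourth standardized moment;
    a Gaussian profile gives 3).  Needs >= 4 neurons; zero-variance
    trials are NaN."""
    Z = _as_matrix(z)
    if Z.shape[0] < 4:
        raise ValueError("kurtosis needs >= 4 neurons")
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = _kurtosis(Z, axis=0, fisher=False, bias=True)
    vals = np.where(Z.std(axis=0) == 0, np.nan, vals)
    return MetricSeries("sparseness_kurtosis", vals)


@dataclass
class SlidingWindowConfig:
    """Gaussian sliding-window correlation scale.

    The kernel is a Gaussian whose full width at half maximum equals
    ``time_scale`` (default 1.0 s, about the median reaction time).
    """

    time_scale: float = 1.0
    kernel: str = "gaussian_fwhm"

    def sigma_frames(self, frame_rate: float) -> float:
        fwhm = self.time_scale * frame_rate
        return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def sliding_window_correlation(dff: np.ndarray, frame_rate: float,
                               intervals,
                               cfg: Optional[SlidingWindowConfig] = None,
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Windowed pairwise correlations per trial.

    For each trial interval ``[onset, offset)``, a Gaussian-weighted
    Pearson correlation is computed per neuron pair at each in-trial
    frame and averaged over frames; returned are the per-trial mean and
    SD over unique pairs, plus a flag for intervals shorter than the
    window (computed with the truncated window).
    """
    cfg = cfg or SlidingWindowConfig()
    dff = np.atleast_2d(np.asarray(dff, float))
    n = dff.shape[0]
    sigma = cfg.sigma_frames(frame_rate)
    iu = np.triu_indices(n, k=1)
    means, spreads, flags = [], [], []
    for onset, offset in intervals:
        seg = dff[:, onset:offset]
        m = seg.shape[1]
        flags.append(m < cfg.time_scale * frame_rate)
        sm = gaussian_filter1d(seg, sigma, axis=1, mode="nearest")
        sm2 = gaussian_filter1d(seg ** 2, sigma, axis=1, mode="nearest")
        var = np.maximum(sm2 - sm ** 2, 0.0)
        prod = seg[:, None, :] * seg[None, :, :]
        smp = gaussian_filter1d(prod, sigma, axis=2, mode="nearest")
        cov = smp - sm[:, None, :] * sm[None, :, :]
        denom = np.sqrt(var[:, None, :] * var[None, :, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = cov / denom
        pair_corr = np.nanmean(corr[iu[0], iu[1], :], axis=1)
        means.append(np.nanmean(pair_corr))
        spreads.append(np.nanstd(pair_corr))
    return np.array(means), np.array(spreads), np.array(flags)


def metric_timecourse(dff: np.ndarray, frame_rate: float, trials,
                      z: ZScoreMatrix, metric: str = "heterogeneity",
                      prestim_window_s: float = 3.0):
    """Frame-resolved metric around each trial.

    Per-frame z-scores reuse the *trial-level* mu_i, sigma_i so the
    frame- and trial-resolved metrics share a scale.  Each segment runs
    from ``-prestim_window_s`` before onset to the trial's analysis
    offset; segments with insufficient pre-stimulus frames are
    truncated and flagged.

    Returns a list of ``(times, values, flagged)`` per trial, with
    times in seconds relative to stimulus onset.
    """
    if metric not in ("mean_dff", "heterogeneity"):
        raise ValueError(f"unknown timecourse metric {metric!r}")
    dff = np.atleast_2d(np.asarray(dff, float))
    keep = np.asarray(z.neuron_ids)
    sub = dff[keep]
    mu = z.mu if z.mu.ndim == 1 else z.mu[:, 0]
    sigma = z.sigma if z.sigma.ndim == 1 else z.sigma[:, 0]
    pre = int(round(prestim_window_s * frame_rate))
    out = []
    for tr in trials:
        end = tr.analysis_offset_frame or tr.offset_frame
        start = tr.onset_frame - pre
        flagged = start < 0
        start = max(0, start)
        seg = sub[:, start:end]
        zf = (seg - mu[:, None]) / sigma[:, None]
        if metric == "mean_dff":
            vals = seg.mean(axis=0)
        else:
            vals = heterogeneity(zf).values
        times = (np.arange(start, end) - tr.onset_frame) / frame_rate
        out.append((times, vals, flagged))
    return out


def prestim_metric(dff: np.ndarray, frame_rate: float, trials,
                   z: ZScoreMatrix, metric: str = "heterogeneity",
                   prestim_window_s: float = 3.0) -> MetricSeries:
    """Mean of the frame-resolved metric over each trial's pre-stimulus
    window (the 3 s preceding onset by default)."""
    courses = metric_timecourse(dff, frame_rate, trials, z, metric,
                                prestim_window_s)
    vals = []
    for times, values, _ in courses:
        mask = times < 0
        vals.append(values[mask].mean() if mask.any() else np.nan)
    return MetricSeries(f"prestim_{metric}", np.array(vals))
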