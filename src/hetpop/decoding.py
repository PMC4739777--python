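"""Gaussian naive-Bayes decoders.

All decoders share one likelihood machinery: per neuron and class, a
Gaussian is fit to the training trials' mean dF/F (SDs floored at
1e-6), and a test trial's class log-likelihood is the sum of per-neuron
log densities.  Read-out is the maximum-likelihood class (uniform
priors); all computation stays in log space.  Cross-validation is
leave-one-out wherever the decoded trials contributed to the model.

Decoders: stimulus presence (0% vs 100% models read out on the trial's
preferred population), 4-class orientation per contrast, 21-class
stimulus type (4 orientations x 5 contrasts + probe), and the angular
single-trial predictive decoder of the subsequent response type from a
pre-stimulus scalar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as sps

from .preprocess import TrialResponseMatrix, TuningAssignment
from .session import ORIENTATIONS

SIGMA_FLOOR = 1e-6


def _log_gauss(x, mu, sigma):
    sigma = np.maximum(sigma, SIGMA_FLOOR)
    return -0.5 * np.log(2.0 * np.pi) - np.log(sigma) \
        - 0.5 * ((x - mu) / sigma) ** 2


@dataclass
class DecodingResult:
    decoded: np.ndarray          # decoded class per trial (object array)
    log_posteriors: np.ndarray   # [n_trials x n_classes], normalized logs
    classes: list
    correct: Optional[np.ndarray] = None
    accuracy: Optional[float] = None
    strata: dict = field(default_factory=dict)


def _normalize_log(logp: np.ndarray) -> np.ndarray:
    m = logp.max(axis=1, keepdims=True)
    w = np.exp(logp - m)
    return logp - (m + np.log(w.sum(axis=1, keepdims=True)))


# ---------------------------------------------------------------------------
# Stimulus presence
# ---------------------------------------------------------------------------

def decode_stimulus_presence(responses: TrialResponseMatrix,
                             tuning: TuningAssignment) -> DecodingResult:
    """Binary present/absent decoding against 0% and 100% models.

    For each trial, only neurons whose preferred orientation matches
    the trial's (nominal) orientation contribute.  The "absent" model
    is fit on 0%-contrast probes, the "present" model on 100%-contrast
    trials of the matching orientation.  Test contrasts (0.5-32%) never
    enter the models, so they are automatically cross-validated;
    0%/100% trials themselves are decoded leave-one-out.  Ties break
    toward "absent".
    """
    R = responses.values
    oris = responses.orientations()
    cons = responses.contrasts()
    n_trials = R.shape[1]
    probe_cols = np.nonzero(cons == 0.0)[0]
    full_cols = {o: np.nonzero((cons == 100.0) & (oris == o))[0]
                 for o in ORIENTATIONS}

    decoded = np.array([None] * n_trials, dtype=object)
    logpost = np.full((n_trials, 2), np.nan)
    skipped = []
    for t in range(n_trials):
        o = oris[t]
        neurons = tuning.consistent & (tuning.preferred_orientation == o)
        if not neurons.any():
            skipped.append(t)
            continue
        absent_cols = probe_cols[probe_cols != t]
        present_cols = full_cols[o][full_cols[o] != t]
        if absent_cols.size < 2 or present_cols.size < 2:
            skipped.append(t)
            continue
        x = R[neurons, t]
        ll = np.empty(2)
        for k, cols in enumerate((absent_cols, present_cols)):
            mu = R[np.ix_(neurons, cols)].mean(axis=1)
            sd = R[np.ix_(neurons, cols)].std(axis=1, ddof=1)
            ll[k] = _log_gauss(x, mu, sd).sum()
        decoded[t] = "present" if ll[1] > ll[0] else "absent"
        logpost[t] = _normalize_log(ll[None, :])[0]

    result = DecodingResult(decoded=decoded, log_posteriors=logpost,
                            classes=["absent", "present"])
    result.strata["skipped_trials"] = skipped
    return result


def presence_rate_by_contrast(result: DecodingResult,
                              responses: TrialResponseMatrix,
                              outcome_filter=None) -> dict:
    """Fraction of trials decoded "present" per contrast."""
    cons = responses.contrasts()
    outs = responses.outcomes()
    rates = {}
    for c in np.unique(cons):
        mask = cons == c
        if outcome_filter is not None:
            mask &= np.isin(outs, outcome_filter)
        dec = [d for d in result.decoded[mask] if d is not None]
        rates[float(c)] = (np.mean([d == "present" for d in dec])
                           if dec else np.nan)
    return rates


def presence_behavior_similarity(decoder_rates, behavior_rates,
                                 iterations: int = 1000,
                                 rng=None) -> dict:
    """Pearson similarity of decoder and behavioral curves over contrasts,
    with a contrast-label-shuffle null (mean over iterations)."""
    rng = np.random.default_rng(rng)
    d = np.asarray(decoder_rates, float)
    b = np.asarray(behavior_rates, float)
    if d.size < 3:
        raise ValueError("need >= 3 contrast levels")
    if d.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a performance curve")
    real = float(np.corrcoef(d, b)[0, 1])
    sh = np.empty(iterations)
    for it in range(iterations):
        sh[it] = np.corrcoef(rng.permutation(d), rng.permutation(b))[0, 1]
    return {"similarity": real, "shuffled_similarity": float(sh.mean())}


def chi_square_correspondence(decoded_present: np.ndarray,
                              is_hit: np.ndarray) -> dict:
    """Pearson chi-square (no continuity correction) of the pooled 2x2
    decoder-output x behavioral-outcome table."""
    dec = np.asarray(decoded_present, bool)
    hit = np.asarray(is_hit, bool)
    table = np.array([
        [np.sum(dec & hit), np.sum(dec & ~hit)],
        [np.sum(~dec & hit), np.sum(~dec & ~hit)],
    ], float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square table has an empty margin")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return {"chi2": float(chi2), "p": float(p), "table": table}


# ---------------------------------------------------------------------------
# Generic leave-one-out Gaussian naive Bayes
# ---------------------------------------------------------------------------

def loo_gaussian_nb(X: np.ndarray, labels: np.ndarray,
                    min_per_class: int = 2) -> DecodingResult:
    """Leave-one-out Gaussian naive Bayes on features x trials.

    ``X`` is [n_features x n_trials].  For each trial, class Gaussians
    are refit without it; classes with fewer than ``min_per_class``
    remaining trials raise.  Ties break toward the first class in
    sorted order (deterministic).
    """
    X = np.atleast_2d(np.asarray(X, float))
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    n_trials = X.shape[1]
    counts = {c: int(np.sum(labels == c)) for c in classes}
    for c, cnt in counts.items():
        if cnt - 1 < min_per_class:
            raise ValueError(
                f"class {c!r}: only {cnt} trials, need > {min_per_class}")

    logpost = np.empty((n_trials, len(classes)))
    decoded = np.empty(n_trials, dtype=object)
    for t in range(n_trials):
        ll = np.empty(len(classes))
        for k, c in enumerate(classes):
            cols = np.nonzero(labels == c)[0]
            cols = cols[cols != t]
            mu = X[:, cols].mean(axis=1)
            sd = X[:, cols].std(axis=1, ddof=1)
            ll[k] = _log_gauss(X[:, t], mu, sd).sum()
        decoded[t] = classes[int(np.argmax(ll))]
        logpost[t] = _normalize_log(ll[None, :])[0]
    correct = decoded == labels
    return DecodingResult(decoded=decoded, log_posteriors=logpost,
                          classes=classes, correct=correct,
                          accuracy=float(correct.mean()),
                          strata={"true_labels": labels.copy()})


# ---------------------------------------------------------------------------
# Orientation and stimulus-type decoding
# ---------------------------------------------------------------------------

def decode_orientation(responses: TrialResponseMatrix,
                       contrast: float) -> DecodingResult:
    """4-class leave-one-out orientation decoding at one contrast."""
    cons = responses.contrasts()
    mask = cons == contrast
    sub = responses.subset(mask)
    labels = sub.orientations()
    if len(set(labels.tolist())) < 2:
        raise ValueError("need >= 2 orientation classes")
    return loo_gaussian_nb(sub.values, labels)


def orientation_accuracy_by_contrast(responses: TrialResponseMatrix,
                                     contrasts=None) -> dict:
    out = {}
    cons = responses.contrasts()
    for c in (contrasts if contrasts is not None else np.unique(cons)):
        try:
            out[float(c)] = decode_orientation(responses, c).accuracy
        except ValueError:
            out[float(c)] = np.nan
    return out


def decoding_vs_metric_split(correct: np.ndarray,
                             metric_values: np.ndarray,
                             contrasts: np.ndarray) -> dict:
    """Accuracy increase for high- vs low-metric trial halves.

    Per contrast, trials are median-split on the metric; the difference
    in mean decoding accuracy, averaged over contrasts, is expressed as
    a percentage increase of high over low.  A zero low-half accuracy
    makes the percentage undefined (flagged, NaN).
    """
    correct = np.asarray(correct, float)
    metric_values = np.asarray(metric_values, float)
    contrasts = np.asarray(contrasts)
    highs, lows = [], []
    for c in np.unique(contrasts):
        idx = np.nonzero(contrasts == c)[0]
        if idx.size < 4:
            continue
        order = idx[np.argsort(metric_values[idx], kind="stable")]
        n_low = idx.size // 2
        lows.append(correct[order[:n_low]].mean())
        highs.append(correct[order[n_low:]].mean())
    if not highs:
        raise ValueError("no contrast with >= 4 trials")
    high, low = float(np.mean(highs)), float(np.mean(lows))
    pct = np.nan if low == 0 else 100.0 * (high - low) / low
    return {"high_accuracy": high, "low_accuracy": low,
            "pct_increase": pct, "undefined": low == 0}


def decode_stimulus_type(responses: TrialResponseMatrix) -> DecodingResult:
    """21-class stimulus-type decoding (4 orientations x 5 contrasts
    plus one pooled probe class), leave-one-out; under-sampled classes
    are dropped with the class set renormalized."""
    oris = responses.orientations()
    cons = responses.contrasts()
    labels = np.array([
        "probe" if c == 0.0 else f"{o:g}deg_{c:g}pct"
        for o, c in zip(oris, cons)], dtype=object)
    keep = np.ones(len(labels), bool)
    dropped = []
    for c in sorted(set(labels.tolist())):
        if np.sum(labels == c) < 3:
            keep &= labels != c
            dropped.append(c)
    sub = responses.subset(keep)
    result = loo_gaussian_nb(sub.values, labels[keep], min_per_class=2)
    result.strata["dropped_classes"] = dropped
    result.strata["kept_mask"] = keep
    return result


def stimulus_type_accuracy_by_outcome(result: DecodingResult,
                                      outcomes: np.ndarray) -> dict:
    """Per-class accuracy averaged within hits and misses separately,
    then over classes."""
    outcomes = np.asarray(outcomes)
    out = {}
    for outcome in ("hit", "miss"):
        accs = []
        for c in result.classes:
            mask = (outcomes == outcome) & (labels_true(result) == c)
            if mask.any():
                accs.append(result.correct[mask].mean())
        out[outcome] = float(np.mean(accs)) if accs else np.nan
    return out


def labels_true(result: DecodingResult) -> np.ndarray:
    """True labels reconstructed from decoded/correct bookkeeping."""
    if "true_labels" in result.strata:
        return result.strata["true_labels"]
    raise KeyError("true labels not recorded on this result")


# ---------------------------------------------------------------------------
# Single-trial predictive decoding of response type
# ---------------------------------------------------------------------------

RESPONSE_ANGLES = {"miss": 0.0, "slow": 2.0 * np.pi / 3.0,
                   "fast": 4.0 * np.pi / 3.0}


@dataclass
class PredictiveDecodingResult:
    mean_likelihoods: dict       # true type -> 3-vector over classes
    resultants: dict             # true type -> (angle, magnitude)
    indices: dict                # true type -> normalized accuracy index
    mean_index: float
    classes: list


def angular_index(mean_likelihoods: np.ndarray, classes: list,
                  true_class: str) -> tuple[float, float, float]:
    """Resultant vector of class likelihoods placed 2pi/3 apart.

    Returns (angle, magnitude, index) with index = cos(angle difference
    to the true class) * magnitude; chance (uniform likelihoods) gives
    magnitude 0, hence index 0.
    """
    angles = np.array([RESPONSE_ANGLES[c] for c in classes])
    vec = (mean_likelihoods[:, None]
           * np.column_stack([np.cos(angles), np.sin(angles)])).sum(axis=0)
    mag = float(np.linalg.norm(vec))
    if mag == 0:
        return 0.0, 0.0, 0.0
    ang = float(np.arctan2(vec[1], vec[0]))
    idx = float(np.cos(ang - RESPONSE_ANGLES[true_class]) * mag)
    return ang, mag, idx


def predictive_decode_response_type(prestim_values: np.ndarray,
                                    labels: np.ndarray,
                                    ) -> PredictiveDecodingResult:
    """Angular predictive decoding of miss/slow/fast from a pre-stimulus
    scalar (heterogeneity or mean dF/F).

    A leave-one-out 1-D Gaussian naive Bayes yields per-trial relative
    likelihoods over the three response types; these are averaged per
    true type and summarized as a resultant vector on the unit circle
    (classes at 0, 2pi/3, 4pi/3) whose alignment-weighted magnitude is
    the normalized decoding accuracy index in [-1, +1], chance 0.
    """
    x = np.asarray(prestim_values, float)[None, :]
    labels = np.asarray(labels, dtype=object)
    result = loo_gaussian_nb(x, labels)
    classes = result.classes
    rel = np.exp(result.log_posteriors)

    mean_likelihoods, resultants, indices = {}, {}, {}
    for c in classes:
        mask = labels == c
        ml = rel[mask].mean(axis=0)
        ang, mag, idx = angular_index(ml, classes, c)
        mean_likelihoods[c] = ml
        resultants[c] = (ang, mag)
        indices[c] = idx
    return PredictiveDecodingResult(
        mean_likelihoods=mean_likelihoods,
        resultants=resultants,
        indices=indices,
        mean_index=float(np.mean(list(indices.values()))),
        classes=classes,
    )
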