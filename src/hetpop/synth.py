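"""Synthetic go/no-go imaging sessions with known ground truth.

The generator emulates the structure the analyses assume: randomized
48-trial blocks (8 drifting-grating directions x 6 contrasts, so 0%
probes are 1 in 6 trials), stimulus up to 3 s terminated by the
response, 10-12 s inter-trial intervals, orientation-tuned neurons with
Naka-Rushton contrast responses sampled at 25.4 Hz, and a contrast-
dependent psychometric function with contrast- and arousal-dependent
reaction times.

Detection-related structure is injected so the pipeline has something
to recover:

* hit trials carry a *larger multiplicative per-neuron gain spread*
  than miss trials (heterogeneity up, population mean ~constant because
  gains are mean-one lognormals);
* hit trials carry a small additive population boost and a fixed
  activation-pattern vector (inter-trial pattern consistency);
* a per-trial AR(1) arousal latent shortens reaction times, widens the
  stimulus gain spread, and raises pre-stimulus baseline dispersion
  (pre-stimulus heterogeneity predicts fast responses).

A spike-rate-like drive is convolved with a single-exponential calcium
kernel and corrupted with noise and shared neuropil contamination to
give the fluorescence matrices.  Everything is deterministic given the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import lfilter

from .session import (
    CONTRAST_LEVELS,
    DIRECTIONS,
    ORIENTATIONS,
    SessionData,
    StimulusCondition,
    TrialRecord,
)

STIMULUS_MAX_S = 3.0


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic task and population.

    Sizes, timing, and the contrast set follow the task design; effect
    parameters are the generator's own minimal phenomenology (see
    docs/methods.md for units and rationale).
    """

    n_neurons: int = 80
    n_blocks: int = 8
    frame_rate: float = 25.4
    iti_range_s: tuple = (10.0, 12.0)

    # tuning / contrast response
    tuning_concentration: float = 1.5
    contrast_semisaturation: float = 10.0   # Naka-Rushton c50, % contrast
    contrast_exponent: float = 2.0
    response_amplitude: float = 0.5         # median peak drive, dF/F units
    baseline_rate: float = 0.10             # spontaneous drive, dF/F units

    # behavior: (lapse, false-alarm rate, contrast at 50% detection, slope)
    psychometric_params: tuple = (0.10, 0.15, 4.0, 1.2)
    # (base RT s, contrast speedup s, arousal speedup s, jitter scale s)
    rt_params: tuple = (1.8, 0.9, 0.4, 0.20)

    # detection-related population effects
    hit_gain_spread: float = 0.55           # SD of log-gain on hit trials
    miss_gain_spread: float = 0.15          # SD of log-gain on miss trials
    hit_mean_boost: float = 0.003           # additive population dF/F on hits
    hit_pattern_strength: float = 0.4       # amplitude of fixed hit pattern
    arousal_autocorr: float = 0.6           # AR(1) coefficient of the latent
    arousal_gain_coupling: float = 0.08     # log-gain SD per arousal unit
    prestim_dispersion_base: float = 0.30   # baseline log-dispersion
    prestim_dispersion_arousal: float = 0.6
    prestim_dispersion_epoch_s: float = 5.0  # pre-onset span carrying the state

    # measurement
    calcium_tau: float = 1.0                # indicator decay, s
    noise_sd: float = 0.04                  # additive noise, dF/F units
    neuropil_contamination: tuple = (0.1, 0.6)
    seed: int = 0

    def __post_init__(self):
        lapse, fa, c50, slope = self.psychometric_params
        if not (0.0 <= lapse <= 1.0 and 0.0 <= fa <= 1.0):
            raise ValueError("lapse and false-alarm rates must lie in [0, 1]")
        if c50 <= 0 or slope <= 0:
            raise ValueError("psychometric threshold and slope must be > 0")
        for name in ("hit_gain_spread", "miss_gain_spread", "hit_mean_boost",
                     "hit_pattern_strength", "noise_sd",
                     "prestim_dispersion_base", "prestim_dispersion_arousal",
                     "arousal_gain_coupling"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.neuropil_contamination
        if not (0.1 <= lo <= hi <= 0.6):
            raise ValueError("neuropil contamination must lie within [0.1, 0.6]")
        if self.n_neurons < 2 or self.n_blocks < 1:
            raise ValueError("need >= 2 neurons and >= 1 block")
        if not 0.0 <= self.arousal_autocorr < 1.0:
            raise ValueError("arousal_autocorr must lie in [0, 1)")


def null_config(**overrides) -> GeneratorConfig:
    """A configuration with every detection-related effect switched off.

    Hit and miss trials are statistically identical and the arousal
    latent is decoupled from the neural data, so every hit/miss and
    pre-stimulus detector in the pipeline should sit at chance.
    """
    base = dict(
        hit_gain_spread=0.15,
        miss_gain_spread=0.15,
        hit_mean_boost=0.0,
        hit_pattern_strength=0.0,
        arousal_gain_coupling=0.0,
        prestim_dispersion_arousal=0.0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@dataclass
class GroundTruth:
    """Latent parameters of a generated session, for recovery tests."""

    preferred_orientation: np.ndarray     # degrees, per neuron
    hit_pattern_vector: np.ndarray        # unit norm, per neuron
    arousal_trace: np.ndarray             # per trial
    true_hit_flags: np.ndarray            # bool, per trial
    gain_spread: np.ndarray               # per-trial log-gain SD
    gain_vectors: np.ndarray              # [n_neurons x n_trials]


def psychometric_shape(contrast, params) -> np.ndarray:
    """Detection probability shape F(c) in [0, 1]; F(0) = 0, F(c50) = 0.5."""
    _, _, c50, slope = params
    c = np.asarray(contrast, float)
    out = np.zeros_like(c)
    pos = c > 0
    out[pos] = 1.0 / (1.0 + (c50 / c[pos]) ** slope)
    return out


def response_probability(contrast, params) -> np.ndarray:
    lapse, fa, _, _ = params
    return fa + (1.0 - fa - lapse) * psychometric_shape(contrast, params)


def simulate_behavior(conditions: Sequence[StimulusCondition],
                      config: GeneratorConfig,
                      arousal: np.ndarray,
                      rng: np.random.Generator):
    """Draw (outcome, reaction_time) per trial from the behavioral model.

    Responses follow the psychometric function; reaction times are
    ``base - contrast effect - arousal effect + positive jitter``,
    truncated to (0, 3.0] s.
    """
    base, c_speed, a_speed, jitter = config.rt_params
    out = []
    for cond, a in zip(conditions, arousal):
        p = float(response_probability(cond.contrast, config.psychometric_params))
        responded = rng.random() < p
        if responded:
            shape = float(psychometric_shape(cond.contrast,
                                             config.psychometric_params))
            rt = base - c_speed * shape - a_speed * a
            rt = rt + rng.exponential(jitter)
            rt = float(np.clip(rt, 0.08, STIMULUS_MAX_S))
            outcome = "false_alarm" if cond.is_probe else "hit"
            out.append((outcome, rt))
        else:
            outcome = "correct_rejection" if cond.is_probe else "miss"
            out.append((outcome, None))
    return out


def _block_conditions(rng: np.random.Generator) -> list[StimulusCondition]:
    conds = [StimulusCondition(direction=d, contrast=c)
             for d in DIRECTIONS for c in CONTRAST_LEVELS]
    order = rng.permutation(len(conds))
    return [conds[i] for i in order]


def _tuning_curve(pref_ori_deg, ori_deg, kappa) -> np.ndarray:
    """von-Mises-like orientation tuning, peak 1 at the preferred axis."""
    delta = np.deg2rad(ori_deg - pref_ori_deg)
    return np.exp(kappa * (np.cos(2.0 * delta) - 1.0))


def _naka_rushton(contrast, c50, q) -> np.ndarray:
    c = np.asarray(contrast, float)
    return c ** q / (c ** q + c50 ** q)


def generate_session(config: Optional[GeneratorConfig] = None,
                     ) -> tuple[SessionData, GroundTruth]:
    """Generate one synthetic session plus its ground truth."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    fs = config.frame_rate
    n = config.n_neurons

    # --- population ------------------------------------------------------
    pref_ori = rng.choice(ORIENTATIONS, size=n)
    amp = config.response_amplitude * rng.lognormal(0.0, 0.3, size=n)
    # zero-mean unit-norm pattern: consistent across hit trials without
    # shifting the population mean (orthogonal to the main diagonal)
    pattern = rng.normal(size=n)
    pattern -= pattern.mean()
    pattern /= np.linalg.norm(pattern)

    # --- trials ----------------------------------------------------------
    conditions: list[StimulusCondition] = []
    block_of: list[int] = []
    for b in range(config.n_blocks):
        block = _block_conditions(rng)
        conditions.extend(block)
        block_of.extend([b] * len(block))
    n_trials = len(conditions)

    # AR(1) arousal latent, stationary unit variance
    rho = config.arousal_autocorr
    innov = rng.normal(size=n_trials) * np.sqrt(1.0 - rho ** 2)
    arousal = np.empty(n_trials)
    prev = rng.normal()
    for t in range(n_trials):
        prev = rho * prev + innov[t]
        arousal[t] = prev

    behavior = simulate_behavior(conditions, config, arousal, rng)

    # --- timeline --------------------------------------------------------
    lo, hi = config.iti_range_s
    itis = rng.uniform(lo, hi, size=n_trials)
    onset_frames = np.empty(n_trials, dtype=int)
    offset_frames = np.empty(n_trials, dtype=int)
    cursor = itis[0]
    for t, (outcome, rt) in enumerate(behavior):
        onset_frames[t] = int(round(cursor * fs))
        dur = rt if rt is not None else STIMULUS_MAX_S
        offset_frames[t] = onset_frames[t] + max(1, int(round(dur * fs)))
        cursor += STIMULUS_MAX_S
        if t + 1 < n_trials:
            cursor += itis[t + 1]
    n_frames = int(round((cursor + 2.0) * fs))

    # --- neural drive ----------------------------------------------------
    is_hit = np.array([b[0] == "hit" for b in behavior])
    spread = np.where(is_hit, config.hit_gain_spread, config.miss_gain_spread)
    spread = np.clip(spread + config.arousal_gain_coupling * arousal,
                     0.02, None)
    xi = rng.normal(size=(n, n_trials))
    gains = np.exp(spread[None, :] * xi - 0.5 * spread[None, :] ** 2)

    drive = np.full((n, n_frames), config.baseline_rate)
    prestim_frames = int(round(config.prestim_dispersion_epoch_s * fs))
    for t, cond in enumerate(conditions):
        on, off = onset_frames[t], offset_frames[t]
        if not cond.is_probe:
            tun = _tuning_curve(pref_ori, cond.orientation,
                                config.tuning_concentration)
            resp = amp * tun * _naka_rushton(cond.contrast,
                                             config.contrast_semisaturation,
                                             config.contrast_exponent)
            resp = resp * gains[:, t]
            if is_hit[t]:
                resp = resp + config.hit_mean_boost
                resp = resp + config.hit_pattern_strength * pattern
            # the hit pattern may suppress a neuron below baseline; the
            # total drive (not the stimulus component) is clipped at 0
            # below, so the pattern keeps its zero population mean
            drive[:, on:off] += resp[:, None]
        # arousal-dependent pre-stimulus baseline dispersion
        s_pre = max(0.01, config.prestim_dispersion_base
                    + config.prestim_dispersion_arousal * arousal[t])
        factor = np.exp(s_pre * rng.normal(size=n) - 0.5 * s_pre ** 2)
        pre0 = max(0, on - prestim_frames)
        drive[:, pre0:on] *= factor[:, None]

    np.clip(drive, 0.0, None, out=drive)

    # calcium kernel: normalized single-exponential smoother
    alpha = np.exp(-1.0 / (fs * config.calcium_tau))
    dff_signal = lfilter([1.0 - alpha], [1.0, -alpha], drive, axis=1)

    # --- fluorescence ----------------------------------------------------
    f0 = rng.normal(100.0, 10.0, size=n).clip(60.0, None)
    # shared neuropil background: slow common fluctuation + faint stimulus echo
    slow = lfilter([1.0 - 0.99], [1.0, -0.99], rng.normal(size=n_frames))
    npil_dff = 0.15 * slow / max(slow.std(), 1e-12) \
        + 0.10 * dff_signal.mean(axis=0)
    contam = rng.uniform(*config.neuropil_contamination, size=n)
    f0_np = rng.normal(90.0, 8.0, size=n).clip(50.0, None)
    neuropil = f0_np[:, None] * (
        1.0 + npil_dff[None, :]
        + 0.3 * config.noise_sd * rng.normal(size=(n, n_frames)))
    soma = f0[:, None] * (
        1.0 + dff_signal + contam[:, None] * npil_dff[None, :]
        + config.noise_sd * rng.normal(size=(n, n_frames)))

    trials = []
    for t, cond in enumerate(conditions):
        outcome, rt = behavior[t]
        trials.append(TrialRecord(
            trial_index=t,
            condition=cond,
            onset_frame=int(onset_frames[t]),
            offset_frame=int(offset_frames[t]),
            outcome=outcome,
            reaction_time=rt,
            block_index=block_of[t],
        ))

    session = SessionData(frame_rate=fs, soma_fluorescence=soma,
                          trials=trials, neuropil_fluorescence=neuropil)
    truth = GroundTruth(
        preferred_orientation=pref_ori,
        hit_pattern_vector=pattern,
        arousal_trace=arousal,
        true_hit_flags=is_hit,
        gain_spread=spread,
        gain_vectors=gains,
    )
    return session, truth
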