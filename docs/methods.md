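# Methods

This note documents the models and procedures the package implements,
the parameters that matter, the design decisions taken where the design
was genuinely open, and what the synthetic-data tests do and do not
establish about real recordings.

## Task and data model

A session is a fluorescence matrix (neurons x frames, optional matched
neuropil matrix), a frame rate (default 25.4 Hz), and a trial table.
Trials follow a go/no-go contrast-detection design: 8 drifting-grating
directions x 6 contrasts (0, 0.5, 2, 8, 32, 100%), each block of 48
trials presenting every condition once in random order; stimuli last up
to 3 s and end at the lick for response trials; inter-trial intervals
are 10-12 s.  0%-contrast probes yield false-alarm / correct-rejection
outcomes; all other contrasts yield hit / miss.  Frame indexing is
0-based with half-open intervals [onset, offset); the analysis window
of a trial never extends past the stimulus offset, keeping
reward/lick-contaminated frames out of every response estimate.
Directions fold onto 4 orientations (mod 180), because the neurons are
modeled (and, in this preparation, largely behave) as orientation-
rather than direction-tuned.

## Preprocessing

* **dF/F0.** Per frame, the baseline F0 is the mean of the lowest 50%
  of fluorescence values in a 30 s window centred on the frame,
  truncated (not reflected) at the recording edges; dF/F = (F-F0)/F0.
  The exact per-frame computation is O(F x W); because F0 varies on the
  30 s window scale, the implementation can evaluate it on every k-th
  frame and interpolate linearly (`stride` parameter).  The drivers use
  stride 8 (0.31 s), which differs from the exact baseline by <1% of a
  typical transient; correctness tests run stride 1 against a
  brute-force sort-and-average oracle.
* **Neuropil.** F_corr = F_soma - r * F_neuropil with r the per-neuron
  Pearson correlation between soma and neuropil traces (r = 0 for
  degenerate neuropil).  QC computes the per-frame discriminability
  D_r = F_soma/(F_soma+F_neuropil) and flags neurons whose D_r stays
  at or below 0.5 for more than 1.0 s contiguously.
* **Trial extraction.** Response trials faster than 150 ms are excluded
  (`fast_lick`): such licks cannot be stimulus-driven.  Because hits
  terminate the stimulus at the reaction time while misses last the
  full 3 s, miss analysis windows are truncated to a duration drawn
  (seeded, reproducible) from the same-contrast hit reaction-time
  distribution, equalizing acquisition time between outcome groups;
  contrasts with no hits fall back to the pooled hit distribution.
* **z-scoring.** z = (R - mu_i)/sigma_i per neuron with sample SD
  (ddof = 1; the choice is scale-consistent for all downstream
  metrics).  Scope is configurable: global (over all trial types; the
  default) or per contrast.
* **Tuning.** Preferred orientation is the argmax over the 4
  orientations of the mean response, pooling all non-probe contrasts
  (pooling high contrasts only gives the same answer in the generator
  and is not separately implemented); ties break toward the lowest
  angle, deterministically.  A neuron is "consistent" when at most 1/3
  of repetition blocks prefer an orientation different from its modal
  block preference; the comparison is to the modal preference.

## Population metrics

Heterogeneity h_t is the mean of the n(n-1)/2 unique entries of
H_t = |z_t - z_t^T|.  It is invariant to adding a constant to all
z-scores of a trial and scales linearly under positive scaling.  The
multidimensional variant is the Euclidean distance from the population
vector to its projection on the all-equal diagonal,
sqrt(sum_i (r_i - mean(r))^2).  The instantaneous Pearson-like
correlation of a trial is the mean over unique pairs of z_x,t * z_y,t
(mean over trials of the pair series recovers the ordinary Pearson
matrix when population-SD z-scores are used); its spread is the
population SD over pairs.  Ř is not bounded to [-1, 1].  Sparseness is
reported as the raw fourth standardized moment (Gaussian -> 3).
Sliding-window correlations use a Gaussian kernel whose FWHM equals
the 1.0 s time scale — a reproducible stand-in for a wavelet-windowed
correlation at the same scale; it matches on the constructed test
cases (identical, anti-correlated, independent traces).  Frame-resolved
metrics reuse the *trial-level* mu_i, sigma_i so frame and trial
series share one scale; pre-stimulus values average the 3 s before
onset.

## Hit modulation

Psi_{i,t} = (R_{i,t} - mu_{m,c,theta}) / sigma_{m,c,theta} uses all
miss trials of the same orientation and contrast (all blocks pooled);
strata with fewer than 2 misses or zero miss SD are dropped and
reported.  R^2 of the neuron-mean, trial-mean, and summed ("both")
approximations uses uncentered SS_tot; the "both" approximation is the
literal sum of the two marginal matrices (a grand-mean-corrected
variant is available behind a flag).  Significance: real R^2 at least
2 SD above the mean of 1000 shuffles that permute neuron identities
within trials, trial identities within neurons, or both.  Per-neuron
hit modulation is a two-sided one-sample t-test of the neuron's Psi
row against 0 at alpha = 0.05.

**Known property.**  Because every hit trial of a stratum is
standardized by the *same estimated* miss mean and SD, all entries of
a row share that estimation error (variance ~ 1/n_miss per stratum).
This is genuine neuron-identity structure that the neuron-identity
shuffle destroys, so the neuron-mode significance test over-flags on
sessions whose strata have few misses even when hits and misses are
statistically identical — the excess is scale-free and does not vanish
with larger matrices (the shuffle SD shrinks faster than the bias).
The decomposition is correctly calibrated on exchangeable inputs
(i.i.d. matrices; tested).  Neuron-mode significance on real sessions
should therefore be read against this caveat.

## Detection statistics

Cohen's d uses the pooled SD; hit/miss effect sizes and ROC AUCs are
computed per test contrast (0.5-32%) and averaged, requiring at least
2 trials per group per stratum.  AUC is the rank statistic
(Mann-Whitney U scaled), ties counted half.  Metric-vs-reaction-time
regressions are ordinary least squares per session; group-level
inference is a one-sample t-test of per-session slopes with
Bonferroni-Holm correction.  Rise times locate the 10% and 90% levels
of the baseline-to-maximum excursion by linear interpolation at the
first crossings after onset (baseline = mean over the 3 s pre-stimulus
window; a flat trace is undefined).  Hits are median-split into fast
and slow per contrast, the median trial going to slow.

The predictability statistic for a point i of response group r1
against group r2 is delta = 2*(d(i, mu_r2)/(d(i, mu_r2)+d(i, mu_r1
without i)) - 0.5): +1 when the point sits on its own leave-one-out
group mean, -1 on the other group's mean, 0 in expectation under
random placement (a small negative leave-one-out bias of order 1/n
exists at tiny group sizes; it is within the Monte-Carlo tolerance at
n = 8).  Group-level delta uses one point per session (the session's
mean pre-stimulus metric per response type), matching the
across-animal construction; per-trial deltas are additionally
available but are sensitive to the skew of trial-level distributions
and are not the primary statistic.

Pattern consistency is the mean Pearson correlation between
same-orientation, same-response-type trial response vectors (test
contrasts pooled), computed separately for the preferred and
nonpreferred populations and averaged over orientations, against a
100-iteration shuffle that permutes each neuron's responses across
trials.  Two shuffle scopes exist: within orientation (the default,
mixing contrasts and response types) and within orientation x contrast.
Because hits concentrate at high contrasts, the contrast-pooled
correlations of hit pairs exceed those of miss pairs for composition
reasons alone; the orientation x contrast scope preserves each
neuron's contrast profile in the null and therefore isolates
trial-specific across-neuron coupling.  The cohort-level calibration
and recovery suites use that scope.

Noise correlations are per-pair Pearson correlations of repetition
vectors per orientation (test contrasts), averaged over the 4
orientations; orientations with fewer than 3 repetitions in the
requested subset, and zero-variance pairs, are excluded and flagged.
Behavioral detection is "significant" when the Clopper-Pearson 95%
intervals of the 0%- and 100%-contrast response rates do not overlap.
Multiple comparisons use Benjamini-Hochberg FDR unless a procedure
states Holm.

## Decoders

All decoders are Gaussian naive Bayes evaluated in log space with a
1e-6 SD floor and uniform priors; read-out is the maximum-likelihood
class; cross-validation is leave-one-out wherever the decoded trial
contributed to the model.  Presence decoding fits the "absent" model
on 0% probes (pooled over nominal orientations) and the "present"
model on 100% trials of the trial's orientation, summing log densities
over the preferred population; test contrasts are automatically
cross-validated, and ties break toward "absent" (conservative).
Orientation decoding is 4-class per contrast over all neurons;
stimulus-type decoding has 21 classes (4 orientations x 5 contrasts
plus one pooled probe class), dropping under-sampled classes.  The
single-trial predictive decoder fits a 1-D model on a pre-stimulus
scalar, averages the per-trial relative likelihoods per true response
type, places the types at 0, 2pi/3, 4pi/3 on the unit circle, and
reports cos(resultant angle - true angle) x resultant magnitude — an
index in [-1, 1] with chance 0.

Leave-one-out decoders are *anti-biased* at small class sizes (the
held-out trial's exclusion pushes its own class model away from it),
so shuffled-label accuracies fall slightly below nominal chance when
classes have only a handful of trials; with the full 8-block design
(~16 repetitions per orientation x contrast) the shuffled accuracies
sit at chance, which is how the chance-level checks are run.

## Geometry

Mirroring r' = 2 mu_r - r reflects a population point through its
projection on the diagonal, preserving the mean and the distance to
the diagonal exactly; it is an involution.  The asymmetry index
mirrors each point one at a time and averages the change in mean
pairwise distance.  (For an exactly mirror-symmetric cloud this index
is not zero but -2 mean(||deviation||)/n_pairs, because the mirrored
point lands on its existing partner; the tests assert the closed
form.)  Heterogeneity removal divides a point by its deviation norm
and restores the original mean, leaving every trial at distance
exactly 1.0 from the diagonal; mean removal subtracts the per-trial
mean; composing both places trials on the unit sphere of the zero-mean
subspace, and the two transforms commute.  Post-removal hit/miss
decoding uses the leave-one-out diagonal-Gaussian decoder (consistent
with the package's other decoders; the removal analysis does not
depend on the classifier family) and reports balanced accuracy.

## Synthetic generator

The generator's purpose is to produce sessions with the statistical
structure the analyses assume, with every effect switchable off
(`null_config`).  Components and defaults:

* **Task**: 8 blocks x 48 conditions, 25.4 Hz, 3 s stimuli, ITI
  U(10, 12) s.
* **Behavior**: response probability fa + (1-fa-lapse)/(1+(c50/c)^s)
  with lapse 0.10, false-alarm rate 0.15, c50 = 4% contrast, slope
  1.2 — a mid-training psychometric curve with usable numbers of both
  hits and misses at every test contrast.  Reaction time = 1.8 s
  - 0.9 s x psychometric shape - 0.4 s x arousal + Exp(0.2 s) jitter,
  clipped to (0, 3] s: faster at high contrast and in high-arousal
  states.
* **Neurons**: preferred orientations uniform over the 4 axes;
  von-Mises-like tuning exp(kappa(cos 2Δ - 1)), kappa = 1.5;
  Naka-Rushton contrast response c^2/(c^2 + 10^2); lognormal response
  amplitudes (median 0.5 dF/F); baseline drive 0.1 dF/F.
* **Detection-related effects** (the structure the pipeline recovers):
  per-neuron multiplicative gains exp(s xi - s^2/2) with log-SD
  s = 0.55 on hits vs 0.15 on misses — mean-one, so heterogeneity
  rises on hits while the population mean barely moves; a small
  additive hit boost (0.003 dF/F); a fixed zero-mean unit-norm hit
  pattern (amplitude 0.4) added to every hit trial's drive, giving
  inter-trial pattern consistency without shifting the population
  mean (the amplitude is set so the pattern's correlation signal
  survives the hit gain noise); an AR(1) arousal latent (rho = 0.6)
  that both shortens reaction times and scales pre-stimulus baseline
  dispersion (log-SD 0.3 + 0.6 x arousal over the 5 s before onset),
  implementing state-dependent pre-stimulus heterogeneity that
  predicts fast responses.
* **Measurement**: drive convolved with a normalized single-exponential
  calcium kernel (tau = 1 s, no saturation — the simplest form that
  preserves trial-mean ordering); soma fluorescence F0(1 + dff +
  contamination x neuropil + noise) with per-neuron contamination
  U(0.1, 0.6) of a shared slow neuropil background; additive noise SD
  0.04 dF/F.

Effect magnitudes were fixed at design time so that the documented
recovery properties hold robustly across seeds, mirroring the
qualitative pattern the package is built to detect (heterogeneity
separating hits from misses roughly twice as well as the mean);
the generator is a phenomenological model, not a fit to data.

**What the generator does not emulate**: spiking dynamics and
indicator nonlinearity/saturation, locomotion and eye-movement
artifacts, slow drift and z-motion, realistic pairwise noise-
correlation structure (correlations arise only through shared
neuropil background and arousal), learning or satiety trends within a
session, and lick-related motor signals.  Passing the recovery suite
therefore shows that the *pipeline* detects the intended effects when
present and stays at chance when absent — not that real cortical data
contain those effects.

## Problem sizes and reproducibility

Every stochastic stage derives its generator from one seed, and
sessions are bit-reproducible given their config.  The test suites run
at desk scale: oracle checks at up to 50 neurons / 200 trials;
calibration on 20 single sessions (40 neurons, 2 blocks) under the
null configuration; recovery on 20 cohorts of 8 sessions (60 neurons,
3 blocks each — within-study-range trial counts per condition at a
reduced neuron count).  The acceptance script uses one full-design
session (80 neurons, 8 blocks) for the metric-equivalence anchor and
twenty 30-neuron full-design sessions for the shuffled-label chance
anchors.  Group-level statements in the drivers use 8-session cohorts,
one summary point per session.
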