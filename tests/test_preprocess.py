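import numpy as np
import pytest

from hetpop import AnalysisConfig, SessionData, StimulusCondition, TrialRecord
from hetpop.preprocess import (
    TrialResponseMatrix,
    assign_preferred_orientation,
    compute_dff,
    discriminability_qc,
    extract_trial_responses,
    neuropil_correct,
    zscore_responses,
)


def brute_force_dff(f, frame_rate, window_s):
    """O(F*W) per-frame sort-and-average baseline oracle."""
    f = np.asarray(f, float)
    n_frames = f.size
    window = max(3, min(int(round(window_s * frame_rate)), n_frames))
    half = window // 2
    out = np.empty(n_frames)
    for i in range(n_frames):
        lo = max(0, i - half)
        hi = min(n_frames, i + (window - half))
        seg = np.sort(f[lo:hi])
        k = max(1, (hi - lo) // 2)
        f0 = seg[:k].mean()
        out[i] = (f[i] - f0) / f0
    return out


class TestComputeDff:
    def test_constant_trace_is_zero(self):
        dff, bad = compute_dff(np.full((1, 200), 100.0), 25.4, 2.0)
        np.testing.assert_allclose(dff, 0.0, atol=1e-12)
        assert not bad.any()

    def test_single_spike_frame(self):
        """One frame at 150 over a flat 100 baseline gives dF/F ~ 0.5
        (the lowest 50% of the full-trace window stays at 100)."""
        f = np.full(100, 100.0)
        f[50] = 150.0
        dff, _ = compute_dff(f[None, :], 1.0, 200.0)
        assert dff[0, 50] == pytest.approx(0.5, abs=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        f = rng.normal(100.0, 5.0, 500).clip(50, None)
        dff, _ = compute_dff(f[None, :], 25.4, 3.0)
        np.testing.assert_allclose(dff[0], brute_force_dff(f, 25.4, 3.0),
                                   rtol=1e-10, atol=1e-12)

    def test_stride_interpolation_is_close_to_exact(self, rng):
        f = 100.0 + np.cumsum(rng.normal(0, 0.2, 2000))
        f = f.clip(50, None)
        exact, _ = compute_dff(f[None, :], 25.4, 10.0, stride=1)
        fast, _ = compute_dff(f[None, :], 25.4, 10.0, stride=8)
        assert np.max(np.abs(exact - fast)) < 5e-3

    def test_degenerate_baseline_flagged(self):
        f = np.full((1, 100), -5.0)
        dff, bad = compute_dff(f, 25.4, 1.0)
        assert bad[0]
        assert np.isnan(dff[0]).all()


class TestNeuropilCorrect:
    def test_identical_gives_r1_and_zero(self, rng):
        soma = rng.normal(100, 5, (3, 200))
        corrected, r = neuropil_correct(soma, soma)
        np.testing.assert_allclose(r, 1.0)
        np.testing.assert_allclose(corrected, 0.0, atol=1e-9)

    def test_independent_neuropil_leaves_soma(self, rng):
        soma = rng.normal(100, 5, (2, 5000))
        npil = rng.normal(90, 5, (2, 5000))
        corrected, r = neuropil_correct(soma, npil)
        assert np.all(np.abs(r) < 0.1)
        assert np.max(np.abs(corrected - soma)) < 0.1 * 90 + 1

    def test_zero_variance_neuropil(self, rng):
        soma = rng.normal(100, 5, (1, 100))
        corrected, r = neuropil_correct(soma, np.full((1, 100), 42.0))
        assert r[0] == 0.0
        np.testing.assert_array_equal(corrected, soma)

    def test_generator_contamination_in_plausible_range(self, small_session):
        session, _ = small_session
        _, r = neuropil_correct(session.soma_fluorescence,
                                session.neuropil_fluorescence)
        assert 0.02 < np.median(r) < 0.8


class TestDiscriminabilityQC:
    def test_equal_luminance_flags_whole_recording(self):
        f = np.full((1, 254), 80.0)
        rep = discriminability_qc(f, f, 25.4)
        np.testing.assert_allclose(rep.discriminability, 0.5)
        assert rep.max_subthreshold_s[0] == pytest.approx(10.0)
        assert rep.flagged[0]

    def test_bright_soma_passes(self):
        soma = np.full((1, 100), 90.0)
        rep = discriminability_qc(soma, soma / 3.0, 25.4)
        np.testing.assert_allclose(rep.discriminability, 0.75)
        assert not rep.flagged[0]

    def test_epoch_threshold_is_one_second(self):
        fs = 10.0
        soma = np.full((1, 100), 90.0)
        npil = np.full((1, 100), 30.0)
        npil[0, 10:25] = 200.0   # 1.5 s below threshold
        rep = discriminability_qc(soma, npil, fs)
        assert rep.max_subthreshold_s[0] == pytest.approx(1.5)
        assert rep.flagged[0]
        npil[0, 10:25] = 30.0
        npil[0, 40:48] = 200.0   # 0.8 s
        rep = discriminability_qc(soma, npil, fs)
        assert not rep.flagged[0]


def _session_for_extraction(rts, fs=10.0, n_frames=600):
    """Alternating hit/miss trials at 8% contrast with given hit RTs."""
    trials = []
    frame = 50
    idx = 0
    for rt in rts:
        trials.append(TrialRecord(idx, StimulusCondition(0.0, 8.0), frame,
                                  frame + max(1, int(round(rt * fs))), "hit",
                                  reaction_time=rt))
        idx += 1
        frame += 60
        trials.append(TrialRecord(idx, StimulusCondition(0.0, 8.0), frame,
                                  frame + 30, "miss"))
        idx += 1
        frame += 60
    soma = np.full((2, n_frames), 100.0)
    return SessionData(frame_rate=fs, soma_fluorescence=soma, trials=trials)


class TestExtractTrialResponses:
    def test_constant_dff_gives_constant_response(self):
        session = _session_for_extraction([1.0, 2.0])
        dff = np.full((2, 600), 0.2)
        resp = extract_trial_responses(session, dff, AnalysisConfig())
        np.testing.assert_allclose(resp.values, 0.2)

    def test_fast_lick_excluded(self):
        session = _session_for_extraction([0.1, 1.0])
        dff = np.zeros((2, 600))
        resp = extract_trial_responses(session, dff, AnalysisConfig())
        assert len(resp.excluded) == 1
        assert resp.excluded[0].exclusion_reason == "fast_lick"
        assert resp.n_trials == 3

    def test_miss_duration_matched_to_single_hit_rt(self):
        session = _session_for_extraction([1.0])
        dff = np.zeros((2, 600))
        resp = extract_trial_responses(session, dff, AnalysisConfig())
        miss = [t for t in resp.trial_refs if t.outcome == "miss"][0]
        assert miss.analysis_offset_frame - miss.onset_frame == 10  # 1.0 s

    def test_column_order_preserved(self):
        session = _session_for_extraction([0.1, 1.0, 2.0])
        dff = np.zeros((2, 600))
        resp = extract_trial_responses(session, dff, AnalysisConfig())
        indices = [t.trial_index for t in resp.trial_refs]
        assert indices == sorted(indices)

    def test_miss_matching_reproducible_given_seed(self):
        session1 = _session_for_extraction([0.8, 1.6, 2.4])
        session2 = _session_for_extraction([0.8, 1.6, 2.4])
        dff = np.zeros((2, 600))
        cfg = AnalysisConfig(rng_seed=5)
        r1 = extract_trial_responses(session1, dff, cfg)
        r2 = extract_trial_responses(session2, dff, cfg)
        offs1 = [t.analysis_offset_frame for t in r1.trial_refs]
        offs2 = [t.analysis_offset_frame for t in r2.trial_refs]
        assert offs1 == offs2

    def test_analysis_window_precedes_reward_frames(self, small_prep):
        for tr in small_prep.responses.trial_refs:
            assert tr.analysis_offset_frame <= tr.offset_frame


def _responses(values, contrasts=None):
    values = np.asarray(values, float)
    n_trials = values.shape[1]
    contrasts = contrasts or [8.0] * n_trials
    trials = [TrialRecord(i, StimulusCondition(0.0, c), 10 * i, 10 * i + 5,
                          "miss" if c else "correct_rejection")
              for i, c in enumerate(contrasts)]
    return TrialResponseMatrix(values=values, trial_refs=trials,
                               neuron_ids=np.arange(values.shape[0]))


class TestZScore:
    def test_simple_row(self):
        z = zscore_responses(_responses([[1.0, 2.0, 3.0],
                                         [0.0, 1.0, 2.0]]))
        np.testing.assert_allclose(z.values[0], [-1.0, 0.0, 1.0])

    def test_zero_variance_row_dropped(self):
        z = zscore_responses(_responses([[1.0, 1.0, 1.0],
                                         [0.0, 1.0, 2.0]]))
        assert list(z.dropped_neurons) == [0]
        assert z.values.shape[0] == 1

    def test_global_rows_standardized(self, small_prep):
        z = small_prep.zscores
        np.testing.assert_allclose(z.values.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.values.std(axis=1, ddof=1), 1.0,
                                   atol=1e-10)

    def test_per_contrast_scope(self, rng):
        vals = rng.normal(size=(3, 24))
        contrasts = ([0.5] * 8 + [8.0] * 8 + [32.0] * 8)
        z = zscore_responses(_responses(vals, contrasts),
                             scope="per_contrast")
        for c in (0.5, 8.0, 32.0):
            cols = np.array(contrasts) == c
            np.testing.assert_allclose(z.values[:, cols].mean(axis=1), 0.0,
                                       atol=1e-10)


def _tuned_responses(pref, n_trials_per_ori=6, noise=0.0, rng=None,
                     n_blocks=3):
    """One neuron per entry of pref, responding to its own orientation."""
    rng = rng or np.random.default_rng(0)
    oris = [0.0, 45.0, 90.0, 135.0]
    trials, cols = [], []
    idx = 0
    for rep in range(n_trials_per_ori):
        for o in oris:
            trials.append(TrialRecord(
                idx, StimulusCondition(o, 8.0), 10 * idx, 10 * idx + 5,
                "miss", block_index=rep % n_blocks))
            col = np.array([1.0 if p == o else 0.0 for p in pref])
            cols.append(col + noise * rng.normal(size=len(pref)))
            idx += 1
    return TrialResponseMatrix(values=np.column_stack(cols),
                               trial_refs=trials,
                               neuron_ids=np.arange(len(pref)))


class TestPreferredOrientation:
    def test_pure_tuning_recovered(self):
        resp = _tuned_responses([90.0, 0.0, 135.0])
        t = assign_preferred_orientation(resp)
        assert list(t.preferred_orientation) == [90.0, 0.0, 135.0]
        assert t.consistent.all()

    def test_one_third_disagreement_is_still_consistent(self):
        """Preferences {0, 0, 90} over 3 blocks: disagreement exactly 1/3,
        which does not exceed the rejection boundary."""
        resp = _tuned_responses([0.0, 45.0], n_trials_per_ori=3, n_blocks=3)
        vals = resp.values.copy()
        blocks = resp.column_attr(lambda tr: tr.block_index)
        oris = resp.orientations()
        # in block 2, neuron 0 responds to 90 instead of 0
        vals[0, (blocks == 2) & (oris == 0.0)] = 0.0
        vals[0, (blocks == 2) & (oris == 90.0)] = 2.0
        resp.values = vals
        t = assign_preferred_orientation(resp)
        assert t.consistent[0]

    def test_untuned_neurons_mostly_inconsistent(self, rng):
        n_inconsistent = 0
        trials = 60
        for _ in range(trials):
            resp = _tuned_responses([0.0, 0.0], noise=50.0, rng=rng,
                                    n_trials_per_ori=6, n_blocks=6)
            t = assign_preferred_orientation(resp)
            n_inconsistent += int(not t.consistent[0])
        assert n_inconsistent > trials / 2

    def test_tie_breaks_to_lowest_orientation(self):
        resp = _tuned_responses([0.0])
        vals = resp.values.copy()
        oris = resp.orientations()
        vals[0, :] = 0.0
        vals[0, oris == 45.0] = 1.0
        vals[0, oris == 135.0] = 1.0
        resp.values = vals
        t = assign_preferred_orientation(resp)
        assert t.preferred_orientation[0] == 45.0
        assert 0 in t.ties
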