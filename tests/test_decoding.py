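import numpy as np
import pytest
from sklearn.naive_bayes import GaussianNB

from hetpop.decoding import (
    RESPONSE_ANGLES,
    _log_gauss,
    angular_index,
    chi_square_correspondence,
    decode_orientation,
    decode_stimulus_presence,
    decode_stimulus_type,
    decoding_vs_metric_split,
    loo_gaussian_nb,
    predictive_decode_response_type,
    presence_behavior_similarity,
)
from hetpop.preprocess import TrialResponseMatrix, TuningAssignment
from hetpop.session import StimulusCondition, TrialRecord


class TestLikelihoods:
    def test_gaussian_density_oracle(self):
        """Observation 1.5 between N(0,1) and N(2,1): the 'present'
        class density 0.3521 beats the 'absent' density 0.1295."""
        absent = np.exp(_log_gauss(1.5, 0.0, 1.0))
        present = np.exp(_log_gauss(1.5, 2.0, 1.0))
        assert absent == pytest.approx(0.12952, abs=1e-4)
        assert present == pytest.approx(0.35207, abs=1e-4)
        assert present > absent

    def test_equidistant_observation_densities_tie(self):
        assert _log_gauss(1.0, 0.0, 1.0) == pytest.approx(
            _log_gauss(1.0, 2.0, 1.0))

    def test_sigma_floor(self):
        assert np.isfinite(_log_gauss(1.0, 1.0, 0.0))


def _make_responses(values, oris, cons, outcomes=None):
    values = np.atleast_2d(np.asarray(values, float))
    trials = []
    for i, (o, c) in enumerate(zip(oris, cons)):
        out = outcomes[i] if outcomes else (
            "correct_rejection" if c == 0.0 else "miss")
        rt = 1.0 if out in ("hit", "false_alarm") else None
        trials.append(TrialRecord(i, StimulusCondition(o, c), 10 * i,
                                  10 * i + 5, out, reaction_time=rt))
    return TrialResponseMatrix(values=values, trial_refs=trials,
                               neuron_ids=np.arange(values.shape[0]))


class TestLooGaussianNB:
    def test_matches_sklearn_on_separable_data(self, rng):
        """Held-out density evaluation agrees with an independently fit
        sklearn GaussianNB on each leave-one-out split."""
        X = np.vstack([rng.normal(0, 1, (6, 3)), rng.normal(4, 1, (6, 3))])
        y = np.array(["a"] * 6 + ["b"] * 6, dtype=object)
        res = loo_gaussian_nb(X.T, y)
        for t in range(12):
            train = np.arange(12) != t
            clf = GaussianNB(var_smoothing=0.0)
            clf.fit(X[train], y[train])
            # sklearn uses ML (population) variance; refit variance with
            # ddof=1 per our convention before comparing read-outs
            for k, c in enumerate(clf.classes_):
                sub = X[train][y[train] == c]
                clf.var_[k] = sub.var(axis=0, ddof=1)
            assert res.decoded[t] == clf.predict(X[t][None, :])[0]

    def test_loo_excludes_held_out_trial(self, rng):
        """Brute-force oracle with explicit exclusion of the held-out
        trial matches decode output (mutation audit of the LOO split)."""
        X = rng.normal(size=(2, 20))
        y = np.array(["a", "b"] * 10, dtype=object)
        res = loo_gaussian_nb(X, y)
        for t in range(20):
            lls = []
            for c in ("a", "b"):
                cols = [i for i in range(20) if y[i] == c and i != t]
                mu = X[:, cols].mean(axis=1)
                sd = X[:, cols].std(axis=1, ddof=1)
                lls.append(_log_gauss(X[:, t], mu, sd).sum())
            assert res.decoded[t] == ("a", "b")[int(np.argmax(lls))]

    def test_undersampled_class_raises(self):
        with pytest.raises(ValueError):
            loo_gaussian_nb(np.ones((1, 3)), np.array(["a", "a", "b"]))


class TestPresenceDecoding:
    def _session(self, rng, signal=3.0):
        oris, cons, vals, outcomes = [], [], [], []
        for rep in range(6):
            for o in (0.0, 90.0):
                for c in (0.0, 8.0, 100.0):
                    oris.append(o)
                    cons.append(c)
                    drive = signal * (c / 100.0)
                    vec = np.array([drive if p == o else 0.0
                                    for p in (0.0, 0.0, 90.0, 90.0)])
                    vals.append(vec + 0.3 * rng.normal(size=4))
                    if c == 0.0:
                        outcomes.append("correct_rejection")
                    else:
                        outcomes.append("hit" if c == 100.0 else "miss")
        resp = _make_responses(np.column_stack(vals), oris, cons, outcomes)
        tuning = TuningAssignment(
            preferred_orientation=np.array([0.0, 0.0, 90.0, 90.0]),
            per_block=None, consistent=np.ones(4, bool))
        return resp, tuning

    def test_full_contrast_decoded_present(self, rng):
        resp, tuning = self._session(rng)
        res = decode_stimulus_presence(resp, tuning)
        cons = resp.contrasts()
        full = [d for d, c in zip(res.decoded, cons) if c == 100.0]
        blank = [d for d, c in zip(res.decoded, cons) if c == 0.0]
        assert np.mean([d == "present" for d in full]) > 0.8
        assert np.mean([d == "absent" for d in blank]) > 0.8

    def test_tie_breaks_toward_absent(self, rng):
        resp, tuning = self._session(rng, signal=0.0)
        # make every response identical: likelihoods tie exactly
        resp.values[:] = 1.0
        res = decode_stimulus_presence(resp, tuning)
        decided = [d for d in res.decoded if d is not None]
        assert decided and all(d == "absent" for d in decided)


class TestSimilarityAndChi2:
    def test_identical_curves(self, rng):
        out = presence_behavior_similarity([0.1, 0.4, 0.8, 0.9],
                                           [0.1, 0.4, 0.8, 0.9],
                                           iterations=200, rng=rng)
        assert out["similarity"] == pytest.approx(1.0)
        assert abs(out["shuffled_similarity"]) < 0.2

    def test_antimonotone_curves(self, rng):
        out = presence_behavior_similarity([0.9, 0.5, 0.1],
                                           [0.1, 0.5, 0.9],
                                           iterations=50, rng=rng)
        assert out["similarity"] == pytest.approx(-1.0)

    def test_chi2_hand_oracle(self):
        dec = np.array([True] * 40 + [False] * 40)
        hit = np.array([True] * 30 + [False] * 10
                       + [True] * 10 + [False] * 30)
        out = chi_square_correspondence(dec, hit)
        assert out["chi2"] == pytest.approx(20.0)

    def test_perfect_concordance_is_n(self):
        dec = np.array([True] * 25 + [False] * 25)
        out = chi_square_correspondence(dec, dec)
        assert out["chi2"] == pytest.approx(50.0)

    def test_empty_margin_raises(self):
        with pytest.raises(ValueError):
            chi_square_correspondence(np.array([True, True]),
                                      np.array([True, False]))


class TestOrientationDecoding:
    def _tuned(self, rng, noise=0.05, reps=4):
        oris, cons, vals = [], [], []
        for rep in range(reps):
            for o in (0.0, 45.0, 90.0, 135.0):
                oris.append(o)
                cons.append(32.0)
                vec = np.array([2.0 if p == o else 0.0
                                for p in (0.0, 45.0, 90.0, 135.0)])
                vals.append(vec + noise * rng.normal(size=4))
        return _make_responses(np.column_stack(vals), oris, cons)

    def test_separable_classes_fully_decoded(self, rng):
        res = decode_orientation(self._tuned(rng), 32.0)
        assert res.accuracy == 1.0

    def test_shuffled_labels_near_chance(self):
        accs = []
        for s in range(15):
            rng = np.random.default_rng(200 + s)
            resp = self._tuned(rng, noise=0.05, reps=6)
            perm = rng.permutation(resp.n_trials)
            resp.values = resp.values[:, perm]   # decouple labels
            accs.append(decode_orientation(resp, 32.0).accuracy)
        se = np.std(accs) / np.sqrt(len(accs))
        assert np.mean(accs) == pytest.approx(0.25, abs=max(3 * se, 0.08))


class TestMetricSplit:
    def test_hand_fixture(self):
        correct = np.array([1, 1, 1, 0, 1, 0, 0, 0], float)
        metric = np.array([4.0, 3.0, 2.5, 2.0, 1.5, 1.0, 0.5, 0.0])
        out = decoding_vs_metric_split(correct, metric,
                                       np.full(8, 8.0))
        assert out["high_accuracy"] == pytest.approx(0.75)
        assert out["low_accuracy"] == pytest.approx(0.25)
        assert out["pct_increase"] == pytest.approx(200.0)

    def test_independent_metric_near_zero(self, rng):
        diffs = []
        for _ in range(200):
            correct = rng.random(40) < 0.5
            metric = rng.normal(size=40)
            out = decoding_vs_metric_split(correct.astype(float), metric,
                                           np.full(40, 8.0))
            diffs.append(out["high_accuracy"] - out["low_accuracy"])
        assert abs(np.mean(diffs)) < 0.05

    def test_zero_low_accuracy_flagged(self):
        out = decoding_vs_metric_split(np.array([0, 0, 1, 1.0]),
                                       np.array([0.0, 1.0, 2.0, 3.0]),
                                       np.full(4, 8.0))
        assert out["undefined"] and np.isnan(out["pct_increase"])


class TestStimulusTypeDecoding:
    def test_class_count_is_21(self, rng):
        oris, cons, vals = [], [], []
        for rep in range(3):
            for o in (0.0, 45.0, 90.0, 135.0):
                for c in (0.0, 0.5, 2.0, 8.0, 32.0, 100.0):
                    oris.append(o)
                    cons.append(c)
                    vec = np.array([5.0 * (c / 100.0) if p == o else 0.0
                                    for p in (0.0, 45.0, 90.0, 135.0)])
                    vals.append(vec + 0.01 * rng.normal(size=4))
        resp = _make_responses(np.column_stack(vals), oris, cons)
        res = decode_stimulus_type(resp)
        # 4 orientations x 5 nonzero contrasts + 1 pooled probe class
        assert len(res.classes) == 21

    def test_separable_types_highly_decodable(self, rng):
        oris, cons, vals = [], [], []
        for rep in range(3):
            for o in (0.0, 90.0):
                for c in (8.0, 100.0):
                    oris.append(o)
                    cons.append(c)
                    vec = np.array([c if p == o else 0.0
                                    for p in (0.0, 90.0)])
                    vals.append(vec + 0.01 * rng.normal(size=2))
        resp = _make_responses(np.column_stack(vals), oris, cons)
        res = decode_stimulus_type(resp)
        assert res.accuracy == 1.0


class TestPredictiveDecoding:
    def test_uniform_likelihoods_give_zero_index(self):
        _, mag, idx = angular_index(np.full(3, 1.0 / 3.0),
                                    ["miss", "slow", "fast"], "miss")
        assert mag == pytest.approx(0.0, abs=1e-12)
        assert idx == pytest.approx(0.0, abs=1e-12)

    def test_certain_correct_prediction(self):
        _, _, idx = angular_index(np.array([1.0, 0.0, 0.0]),
                                  ["miss", "slow", "fast"], "miss")
        assert idx == pytest.approx(1.0)

    def test_certain_wrong_prediction(self):
        _, _, idx = angular_index(np.array([0.0, 1.0, 0.0]),
                                  ["miss", "slow", "fast"], "miss")
        assert idx == pytest.approx(np.cos(2 * np.pi / 3))

    def test_informative_scalar_positive_index(self, rng):
        x = np.concatenate([rng.normal(0, 0.3, 20),
                            rng.normal(2, 0.3, 20),
                            rng.normal(4, 0.3, 20)])
        labels = np.array(["miss"] * 20 + ["slow"] * 20 + ["fast"] * 20,
                          dtype=object)
        res = predictive_decode_response_type(x, labels)
        assert res.mean_index > 0.5

    def test_angles_are_two_thirds_pi_apart(self):
        angles = sorted(RESPONSE_ANGLES.values())
        diffs = np.diff(angles)
        np.testing.assert_allclose(diffs, 2 * np.pi / 3)
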