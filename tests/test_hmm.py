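import json

import numpy as np
import pytest
from scipy.stats import norm

from eegmse.hmm import (
    BakisGaussianHMM,
    GaussianHMMParams,
    HMMEmotionClassifier,
    classify,
    forward_loglik,
)
from oracles import brute_forward_loglik


def _random_params(rng, q, d):
    a = np.triu(rng.random((q, q))) + 0.1 * np.eye(q)
    a /= a.sum(axis=1, keepdims=True)
    pi = rng.random(q)
    pi /= pi.sum()
    return GaussianHMMParams(
        pi, a, rng.normal(size=(q, d)), 0.2 + rng.random((q, d))
    )


class TestForward:
    def test_single_state_reduces_to_iid_gaussian(self, rng):
        p = GaussianHMMParams(
            np.array([1.0]), np.array([[1.0]]),
            np.array([[0.5, -0.5]]), np.array([[1.0, 2.0]]),
        )
        seq = rng.standard_normal((10, 2))
        expected = float(
            norm.logpdf(seq, loc=p.means[0], scale=np.sqrt(p.variances[0])).sum()
        )
        assert forward_loglik(p, seq) == pytest.approx(expected, abs=1e-10)

    def test_matches_exhaustive_path_enumeration(self, rng):
        for _ in range(30):
            q = int(rng.integers(1, 4))
            d = int(rng.integers(1, 3))
            t = int(rng.integers(1, 7))
            p = _random_params(rng, q, d)
            seq = rng.normal(size=(t, d))
            want = brute_forward_loglik(
                p.startprob, p.transmat, p.means, p.variances, seq
            )
            assert forward_loglik(p, seq) == pytest.approx(want, abs=1e-8)

    def test_matches_hmmlearn(self, rng):
        """Independent cross-check against the reference HMM library."""
        from hmmlearn.hmm import GaussianHMM

        for _ in range(5):
            q = int(rng.integers(2, 4))
            p = _random_params(rng, q, 3)
            seq = rng.normal(size=(12, 3))
            ref = GaussianHMM(n_components=q, covariance_type="diag", init_params="")
            ref.startprob_ = p.startprob
            ref.transmat_ = p.transmat
            ref.means_ = p.means
            ref.covars_ = p.variances
            assert forward_loglik(p, seq) == pytest.approx(
                float(ref.score(seq)), abs=1e-6
            )

    def test_appending_frames_never_raises_loglik_for_subunit_densities(self, rng):
        """With every emission density bounded by 1 (variances >= 1/2pi),
        log P(O_{1:T}) is non-increasing in T."""
        p = GaussianHMMParams(
            np.array([0.6, 0.4]),
            np.array([[0.5, 0.5], [0.0, 1.0]]),
            np.array([[0.0], [2.0]]),
            np.array([[1.0], [1.5]]),
        )
        seq = rng.normal(size=(8, 1))
        lls = [forward_loglik(p, seq[: t + 1]) for t in range(8)]
        assert all(b <= a + 1e-12 for a, b in zip(lls, lls[1:]))

    def test_empty_sequence_rejected(self, rng):
        p = _random_params(rng, 2, 2)
        with pytest.raises(ValueError):
            forward_loglik(p, np.empty((0, 2)))

    def test_dimension_mismatch_rejected(self, rng):
        p = _random_params(rng, 2, 2)
        with pytest.raises(ValueError):
            forward_loglik(p, rng.normal(size=(5, 3)))


class TestParamsValidation:
    def test_lower_triangle_rejected(self):
        with pytest.raises(ValueError, match="Bakis"):
            GaussianHMMParams(
                np.array([1.0, 0.0]),
                np.array([[0.5, 0.5], [0.3, 0.7]]),
                np.zeros((2, 1)), np.ones((2, 1)),
            )

    def test_unnormalized_rows_rejected(self):
        with pytest.raises(ValueError):
            GaussianHMMParams(
                np.array([1.0, 0.0]),
                np.array([[0.5, 0.4], [0.0, 1.0]]),
                np.zeros((2, 1)), np.ones((2, 1)),
            )


class TestBaumWelch:
    def test_monotone_loglik_and_bakis_preserved(self, bakis_truth):
        seqs = BakisGaussianHMM.from_params(bakis_truth).sample(
            30, 40, random_state=0
        )
        snapshots = []
        est = BakisGaussianHMM(n_states=3)
        est.fit(list(seqs), callback=lambda it, p, ll: snapshots.append(p))
        trace = np.array(est.loglik_trace_)
        assert np.all(np.diff(trace) >= -1e-8 * np.abs(trace[:-1]))
        for p in snapshots:
            assert np.all(np.tril(p.transmat, k=-1) == 0.0)
            np.testing.assert_allclose(p.transmat.sum(axis=1), 1.0, atol=1e-10)

    def test_single_state_converges_to_pooled_moments(self, rng):
        seqs = [rng.normal(2.0, 1.5, size=(20, 2)) for _ in range(5)]
        est = BakisGaussianHMM(n_states=1, max_iter=5).fit(seqs)
        allframes = np.concatenate(seqs)
        np.testing.assert_allclose(est.means_[0], allframes.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(
            est.variances_[0], allframes.var(axis=0), atol=1e-8
        )

    def test_parameter_recovery(self, bakis_truth):
        seqs = BakisGaussianHMM.from_params(bakis_truth).sample(
            100, 60, random_state=1
        )
        est = BakisGaussianHMM(n_states=3).fit(list(seqs))
        assert np.abs(est.means_ - bakis_truth.means).max() < 0.1

    def test_sequence_order_invariance(self, bakis_truth, rng):
        seqs = list(
            BakisGaussianHMM.from_params(bakis_truth).sample(20, 30, random_state=2)
        )
        a = BakisGaussianHMM(n_states=3).fit(seqs)
        shuffled = [seqs[i] for i in rng.permutation(len(seqs))]
        b = BakisGaussianHMM(n_states=3).fit(shuffled)
        np.testing.assert_allclose(a.means_, b.means_, atol=1e-8)
        np.testing.assert_allclose(a.transmat_, b.transmat_, atol=1e-8)

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(ValueError):
            BakisGaussianHMM(n_states=5).fit([rng.normal(size=(2, 2))])

    def test_nonfinite_rejected(self):
        bad = np.full((10, 2), np.nan)
        with pytest.raises(ValueError):
            BakisGaussianHMM(n_states=2).fit([bad])

    def test_mixtures_unsupported(self, rng):
        with pytest.raises(ValueError, match="n_mix"):
            BakisGaussianHMM(n_states=2, n_mix=2).fit(
                [rng.normal(size=(10, 2))]
            )

    def test_json_roundtrip(self, bakis_truth, tmp_path):
        seqs = BakisGaussianHMM.from_params(bakis_truth).sample(
            10, 30, random_state=3
        )
        est = BakisGaussianHMM(n_states=3).fit(list(seqs))
        path = str(tmp_path / "model.json")
        est.to_json(path)
        again = BakisGaussianHMM.from_json(path)
        assert est.score(seqs[0]) == pytest.approx(again.score(seqs[0]))
        with open(path) as fh:
            payload = json.load(fh)
        assert payload["n_states"] == 3 and payload["n_features"] == 2


class TestClassification:
    def _two_models(self, bakis_truth):
        high = BakisGaussianHMM.from_params(bakis_truth)
        low_params = GaussianHMMParams(
            bakis_truth.startprob,
            bakis_truth.transmat,
            bakis_truth.means - 4.0,
            bakis_truth.variances,
        )
        return high, BakisGaussianHMM.from_params(low_params)

    def test_sequence_from_high_model_classified_high(self, bakis_truth):
        high, low = self._two_models(bakis_truth)
        for seq in high.sample(10, 30, random_state=4):
            label, scores = classify(seq, model_high=high, model_low=low)
            assert label == "high"
            assert scores[0] > scores[1]

    def test_tie_breaks_low_with_warning(self, bakis_truth):
        high = BakisGaussianHMM.from_params(bakis_truth)
        seq = high.sample(1, 20, random_state=5)[0]
        with pytest.warns(UserWarning, match="tied"):
            label, scores = classify(seq, model_high=high, model_low=high)
        assert label == "low" and scores[0] == scores[1]

    def test_decision_consistent_with_scores(self, bakis_truth, rng):
        high, low = self._two_models(bakis_truth)
        for _ in range(5):
            seq = rng.normal(size=(15, 2))
            label, (s_h, s_l) = classify(seq, model_high=high, model_low=low)
            assert label == ("high" if s_h > s_l else "low")

    def test_classifier_estimator_recovers_labels(self, bakis_truth):
        high, low = self._two_models(bakis_truth)
        seqs = list(high.sample(12, 40, random_state=6)) + list(
            low.sample(12, 40, random_state=7)
        )
        y = np.array([1] * 12 + [0] * 12)
        clf = HMMEmotionClassifier(n_states=3).fit(seqs, y)
        test = list(high.sample(5, 40, random_state=8)) + list(
            low.sample(5, 40, random_state=9)
        )
        np.testing.assert_array_equal(
            clf.predict(test), [1] * 5 + [0] * 5
        )

    def test_single_class_training_rejected(self, bakis_truth):
        high = BakisGaussianHMM.from_params(bakis_truth)
        seqs = list(high.sample(4, 20, random_state=10))
        with pytest.raises(ValueError, match="both classes"):
            HMMEmotionClassifier().fit(seqs, np.ones(4))
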