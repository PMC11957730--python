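import numpy as np
import pytest

from erpmvpa.decoding import (
    DecoderConfig,
    DecodingInfeasibleError,
    decode_timecourse,
    decode_timepoint,
    subaverage_split,
    train_linear,
)
from erpmvpa.io import ParameterError
from erpmvpa.simulate import simulate_epochs


class TestSubaverageSplit:
    def test_default_scheme_on_10_trials(self, rng):
        cfg = DecoderConfig(n_permutations=1)
        exemplars, tests = subaverage_split([np.arange(10)], cfg, rng)
        ex, test = exemplars[0], tests[0]
        assert len(ex) == 4
        assert all(len(s) == 2 for s in ex)
        assert len(test) == 2

    def test_training_and_test_disjoint(self, rng):
        cfg = DecoderConfig(n_permutations=1)
        for _ in range(50):
            exemplars, tests = subaverage_split(
                [np.arange(10), np.arange(12)], cfg, rng
            )
            for ex, test in zip(exemplars, tests):
                used = np.concatenate(ex)
                assert len(np.intersect1d(used, test)) == 0
                assert len(np.unique(used)) == len(used)  # subsets disjoint

    def test_too_few_trials_names_class(self, rng):
        cfg = DecoderConfig(n_permutations=1)
        with pytest.raises(DecodingInfeasibleError, match="android"):
            subaverage_split(
                [np.arange(10), np.arange(4)], cfg, rng,
                class_names=["human", "android"],
            )

    def test_test_set_membership_uniform(self, rng):
        # With 10 trials, 4 disjoint subsets of 2 leave 2 test trials; by
        # exchangeability each trial is in the test set with probability 0.2.
        cfg = DecoderConfig(n_permutations=1)
        counts = np.zeros(10)
        n_draws = 10000
        for _ in range(n_draws):
            _, (test,) = subaverage_split([np.arange(10)], cfg, rng)
            counts[test] += 1
        freq = counts / n_draws
        assert np.allclose(freq, 0.2, atol=0.02)

    def test_overlapping_mode_complement_test(self, rng):
        cfg = DecoderConfig(n_permutations=1, disjoint=False)
        exemplars, tests = subaverage_split([np.arange(20)], cfg, rng)
        used = np.unique(np.concatenate(exemplars[0]))
        assert np.array_equal(np.sort(np.concatenate([used, tests[0]])), np.arange(20))


class TestTrainLinear:
    def test_separable_clusters_classified(self, rng):
        Xa = rng.normal(size=(4, 5)) + 10
        Xb = rng.normal(size=(4, 5)) - 10
        X = np.vstack([Xa, Xb])
        y = np.array(["a"] * 4 + ["b"] * 4)
        f = train_linear(X, y)
        assert list(f.predict(Xa)) == ["a"] * 4
        assert list(f.predict(Xb)) == ["b"] * 4

    def test_label_swap_negates_decision(self, rng):
        X = rng.normal(size=(8, 3))
        y = np.array(["a"] * 4 + ["b"] * 4)
        y_swapped = np.where(y == "a", "b", "a")
        f1 = train_linear(X, y)
        f2 = train_linear(X, y_swapped)
        T = rng.normal(size=(6, 3))
        assert np.allclose(f1.decision(T), -f2.decision(T), atol=1e-6)

    def test_two_point_max_margin_boundary_at_zero(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array(["neg", "pos"])
        f = train_linear(X, y)
        assert f.decision(np.array([[0.0]]))[0] == pytest.approx(0.0, abs=1e-9)
        assert f.predict(np.array([[0.5]]))[0] == "pos"
        assert f.predict(np.array([[-0.5]]))[0] == "neg"

    def test_identical_exemplar_sets_flagged_degenerate(self, rng):
        Xa = rng.normal(size=(4, 3))
        X = np.vstack([Xa, Xa])
        y = np.array(["a"] * 4 + ["b"] * 4)
        f = train_linear(X, y)
        assert f.degenerate
        assert np.allclose(f.decision(rng.normal(size=(5, 3))), 0.0)

    def test_agrees_with_libsvm_reference(self, rng):
        # Independent oracle: sklearn's SVC wraps libsvm; our SMO solver must
        # reproduce its solution on random soft-margin problems.
        SVC = pytest.importorskip("sklearn.svm").SVC
        for trial in range(25):
            n = int(rng.integers(4, 12))
            d = int(rng.integers(1, 6))
            X = rng.normal(size=(2 * n, d))
            y = np.array(["a"] * n + ["b"] * n)
            f = train_linear(X, y)
            ref = SVC(kernel="linear", C=1.0, tol=1e-6).fit(X, (y == "a").astype(int))
            # sklearn's positive class is label 1 == "a", matching our convention
            assert np.allclose(f.w, ref.coef_.ravel(), atol=1e-5)
            assert f.b == pytest.approx(ref.intercept_[0], abs=1e-5)


class TestDecodeTimepoint:
    def test_shuffled_labels_give_chance(self, rng):
        cfg = DecoderConfig(n_permutations=100, seed=0)
        labels = np.array(["a"] * 30 + ["b"] * 30)
        accs = [
            decode_timepoint(rng.normal(size=(60, 16)), labels, cfg, rng)
            for _ in range(10)
        ]
        assert np.mean(accs) == pytest.approx(0.5, abs=0.03)

    def test_huge_offset_perfectly_decoded(self, rng):
        cfg = DecoderConfig(n_permutations=50, seed=0)
        X = rng.normal(size=(40, 8))
        X[20:] += 100.0
        labels = np.array(["a"] * 20 + ["b"] * 20)
        assert decode_timepoint(X, labels, cfg, rng) == 1.0

    def test_channel_permutation_invariance(self, rng):
        # A consistent relabelling of channels leaves the linear kernel, and
        # hence every decision, exactly unchanged.
        cfg = DecoderConfig(n_permutations=50, seed=0)
        X = rng.normal(size=(30, 12))
        labels = np.array(["a"] * 15 + ["b"] * 15)
        perm = rng.permutation(12)
        a1 = decode_timepoint(X, labels, cfg, np.random.default_rng(3))
        a2 = decode_timepoint(X[:, perm], labels, cfg, np.random.default_rng(3))
        assert a1 == a2

    def test_class_imbalance_keeps_chance_anchor(self, rng):
        cfg = DecoderConfig(n_permutations=100, seed=0)
        labels = np.array(["a"] * 40 + ["b"] * 20)  # 2:1 imbalance, no signal
        accs = [
            decode_timepoint(rng.normal(size=(60, 16)), labels, cfg, rng)
            for _ in range(10)
        ]
        assert np.mean(accs) == pytest.approx(0.5, abs=0.03)

    def test_permutation_count_convergence(self, rng):
        X = rng.normal(size=(60, 16))
        X[30:, :4] += 1.0
        labels = np.array(["a"] * 30 + ["b"] * 30)
        a1k = decode_timepoint(
            X, labels, DecoderConfig(n_permutations=1000), np.random.default_rng(1)
        )
        a4k = decode_timepoint(
            X, labels, DecoderConfig(n_permutations=4000), np.random.default_rng(2)
        )
        assert abs(a1k - a4k) < 0.01


class TestDecodeTimecourse:
    def test_shapes_and_determinism(self, tiny_cfg):
        sets = simulate_epochs(tiny_cfg, ("human", "android"))
        cfg = DecoderConfig(n_permutations=20, seed=5)
        r1 = decode_timecourse(sets, ("human", "android"), cfg, time_decim=10)
        r2 = decode_timecourse(sets, ("human", "android"), cfg, time_decim=10)
        n_t = len(sets[0].times[::10])
        assert r1.accuracy.shape == (len(sets), n_t)
        assert np.array_equal(r1.accuracy, r2.accuracy)
        assert np.allclose(r1.group_mean, r1.accuracy.mean(axis=0))
        assert len(r1.bf_vs_chance) == n_t
        assert np.all((r1.accuracy >= 0) & (r1.accuracy <= 1))

    def test_needs_two_participants(self, tiny_cfg):
        sets = simulate_epochs(tiny_cfg, ("human", "android"))[:1]
        with pytest.raises(ParameterError):
            decode_timecourse(sets, ("human", "android"), DecoderConfig(n_permutations=5))
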