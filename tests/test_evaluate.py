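import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegauth import (chance_level, confusion_matrix, far_frr, far_frr_curve,
                     macro_metrics, roc_det_curves)
from eegauth.authenticate import AuthDecision
from eegauth.classify import FfnnConfig


def _decision(verdict):
    return AuthDecision(vote_counts=np.array([1]), majority_label=1,
                        majority_count=1, beta=1.0, theta=0.5, claimed_label=1,
                        claimed_match=True, verdict=verdict)


def brute_force_macro(counts):
    """Oracle: per-class one-vs-rest ratios computed cell by cell."""
    k = counts.shape[0]
    total = counts.sum()
    accs, precs, recs, specs = [], [], [], []
    for c in range(k):
        tp = counts[c, c]
        fn = counts[c].sum() - tp
        fp = counts[:, c].sum() - tp
        tn = total - tp - fn - fp
        accs.append((tp + tn) / total)
        if tp + fp > 0:
            precs.append(tp / (tp + fp))
        if tp + fn > 0:
            recs.append(tp / (tp + fn))
        if tn + fp > 0:
            specs.append(tn / (tn + fp))
    return (100 * np.mean(accs), 100 * np.mean(precs), 100 * np.mean(recs),
            100 * np.mean(specs))


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        cm = confusion_matrix([1, 2, 3, 1], [1, 2, 3, 1], k=3)
        np.testing.assert_array_equal(cm.counts, np.diag([2, 1, 1]))

    def test_hand_enumeration(self):
        cm = confusion_matrix([1, 1, 2], [1, 2, 2], k=2)
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])

    def test_prediction_order_irrelevant(self):
        a = confusion_matrix([1, 2, 1], [2, 1, 1], k=2)
        b = confusion_matrix([1, 1, 2], [2, 1, 1], k=2)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion_matrix([1, 4], [1, 1], k=3)


class TestMacroMetrics:
    def test_diagonal_matrix_perfect_scores(self):
        from eegauth.evaluate import ConfusionMatrix

        cm = ConfusionMatrix(np.diag([3, 4, 5]), np.arange(1, 4))
        rep = macro_metrics(cm)
        assert rep.accuracy == rep.precision == rep.recall == 100.0
        assert rep.specificity == 100.0
        assert rep.f1 == pytest.approx(1.0)
        assert rep.overall_accuracy == 1.0

    def test_hand_oracle_two_class(self):
        cm = confusion_matrix([1, 1, 2], [1, 2, 2], k=2)
        rep = macro_metrics(cm)
        assert rep.precision == pytest.approx(75.0)
        assert rep.recall == pytest.approx(75.0)
        assert rep.f1 == pytest.approx(0.75)

    def test_all_one_class_balanced_recall_half(self):
        cm = confusion_matrix([1, 1, 2, 2], [1, 1, 1, 1], k=2)
        rep = macro_metrics(cm)
        assert rep.recall == pytest.approx(50.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 100_000), k=st.integers(2, 6))
    def test_matches_per_class_brute_force(self, seed, k):
        from eegauth.evaluate import ConfusionMatrix

        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 30, size=(k, k))
        counts[np.arange(k), np.arange(k)] += 1  # every class present
        rep = macro_metrics(ConfusionMatrix(counts, np.arange(1, k + 1)))
        acc, prec, rec, spec = brute_force_macro(counts)
        assert rep.accuracy == pytest.approx(acc)
        assert rep.precision == pytest.approx(prec)
        assert rep.recall == pytest.approx(rec)
        assert rep.specificity == pytest.approx(spec)
        f1 = 2 * (rec / 100) * (prec / 100) / (rec / 100 + prec / 100)
        assert rep.f1 == pytest.approx(f1)


class TestFarFrr:
    def test_all_correct(self):
        decs = [_decision("genuine"), _decision("imposter")]
        rates = far_frr(decs, [True, False])
        assert rates.far == 0.0 and rates.frr == 0.0

    def test_hand_arithmetic_both_conventions(self):
        decs = ([_decision("genuine")] * 8 + [_decision("imposter")] * 92 +
                [_decision("imposter")] * 5 + [_decision("genuine")] * 95)
        genuine = [False] * 100 + [True] * 100
        rates = far_frr(decs, genuine)
        assert rates.far == pytest.approx(0.08)
        assert rates.frr == pytest.approx(0.05)
        literal = far_frr(decs, genuine, pooled_attempts=True)
        assert literal.far == pytest.approx(0.04)
        assert literal.frr == pytest.approx(0.025)

    def test_sweep_monotone_and_limits(self):
        rng = np.random.default_rng(2)
        scores = np.concatenate([rng.uniform(0.4, 1.0, 50),
                                 rng.uniform(0.0, 0.6, 50)])
        genuine = np.array([True] * 50 + [False] * 50)
        thetas = np.linspace(0.0, 1.0, 25)
        sweep = far_frr_curve(scores, genuine, thetas)
        fars = [c[1] for c in sweep.curve]
        frrs = [c[2] for c in sweep.curve]
        assert all(a >= b for a, b in zip(fars, fars[1:]))   # non-increasing
        assert all(a <= b for a, b in zip(frrs, frrs[1:]))   # non-decreasing
        assert fars[0] == 1.0  # theta below every score accepts everyone


class TestRocDet:
    def test_perfect_separation(self):
        pairs = [(0.9, True), (0.8, True), (0.7, False), (0.6, False)]
        out = roc_det_curves(pairs)
        assert out["auc"] == pytest.approx(1.0)
        assert out["eer"] == pytest.approx(0.0)

    def test_uninformative_scores(self):
        pairs = [(0.5, True)] * 10 + [(0.5, False)] * 10
        assert roc_det_curves(pairs)["auc"] == pytest.approx(0.5)

    def test_interleaved_hand_case(self):
        pairs = [(0.9, True), (0.7, False), (0.8, True), (0.95, False)]
        assert roc_det_curves(pairs)["auc"] == pytest.approx(0.5)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 100_000), n_g=st.integers(1, 20),
           n_i=st.integers(1, 20))
    def test_auc_equals_mann_whitney_pair_count(self, seed, n_g, n_i):
        rng = np.random.default_rng(seed)
        # coarse grid forces ties, exercising the 0.5 credit
        g = rng.integers(0, 6, n_g) / 5.0
        i = rng.integers(0, 6, n_i) / 5.0
        pairs = [(s, True) for s in g] + [(s, False) for s in i]
        auc = roc_det_curves(pairs)["auc"]
        wins = sum((a > b) + 0.5 * (a == b) for a in g for b in i)
        assert auc == pytest.approx(wins / (n_g * n_i))

    def test_det_is_fnr_view_of_roc(self):
        pairs = [(0.9, True), (0.4, True), (0.6, False), (0.2, False)]
        out = roc_det_curves(pairs)
        for (f1, tpr), (f2, fnr) in zip(out["roc"], out["det"]):
            assert f1 == f2 and fnr == pytest.approx(1 - tpr)


class TestChanceLevel:
    def _toy(self):
        rng = np.random.default_rng(3)
        x = np.vstack([rng.normal(c, 1.0, (30, 4)) for c in (-2, 0, 2)])
        y = np.repeat([1, 2, 3], 30)
        return x, y

    def test_single_shuffle_deterministic(self):
        x, y = self._toy()
        cfg = FfnnConfig(epochs=5, seed=0)
        a = chance_level(x, y, x, y, config=cfg, n_shuffles=1, seed=4)
        b = chance_level(x, y, x, y, config=cfg, n_shuffles=1, seed=4)
        assert a["accuracies"] == b["accuracies"]

    def test_real_model_beats_shuffled_distribution(self):
        from eegauth.classify import predict, train_ffnn

        x, y = self._toy()
        cfg = FfnnConfig(epochs=20, seed=0)
        dist = chance_level(x, y, x, y, config=cfg, n_shuffles=10, seed=5)
        real = np.mean(predict(train_ffnn(x, y, cfg), x).predicted_labels == y)
        assert real > max(dist["accuracies"])

    def test_test_set_untouched(self):
        x, y = self._toy()
        xt = x.copy()
        chance_level(x, y, xt, y, config=FfnnConfig(epochs=2, seed=0),
                     n_shuffles=2, seed=6)
        np.testing.assert_array_equal(x, xt)
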