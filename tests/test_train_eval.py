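"""Training-loop, metric-formula, ROC and Grad-CAM contracts."""

import numpy as np
import pytest

from cacpnet.archspec import ArchSpec
from cacpnet.backbone import build_model
from cacpnet.train_eval import (
    Hyperparams,
    accuracy_from_counts,
    evaluate,
    f1_score,
    gradcam,
    precision_from_counts,
    recall_from_counts,
    roc_auc,
    train,
)


@pytest.fixture()
def blob_data(rng):
    """Three linearly separable color blobs rendered as 32-px images."""
    n_per = 12
    xs, ys = [], []
    means = [(-1.2, 0.0, 1.2), (1.2, -1.2, 0.0), (0.0, 1.2, -1.2)]
    for cls, mu in enumerate(means):
        base = np.array(mu, dtype=np.float32)[None, :, None, None]
        xs.append(base + 0.3 * rng.normal(size=(n_per, 3, 32, 32)).astype(np.float32))
        ys.append(np.full(n_per, cls))
    return np.concatenate(xs), np.concatenate(ys)


class TestMetricFormulas:
    def test_worked_accuracy_case(self):
        assert accuracy_from_counts(tp=9, tn=8, fp=1, fn=2) == pytest.approx(0.85)

    def test_worked_f1_case(self):
        assert f1_score(0.75, 0.6) == pytest.approx(2 * 0.45 / 1.35)
        assert f1_score(0.75, 0.6) == pytest.approx(0.6667, abs=1e-4)

    def test_degenerate_counts(self):
        assert precision_from_counts(0, 0) == 0.0
        assert recall_from_counts(0, 0) == 0.0
        assert f1_score(0.0, 0.0) == 0.0


class TestEvaluate:
    def _report(self, preds, labels, k=3):
        spec = ArchSpec(num_classes=k, stem_channels=4, stage_widths=[4, 4, 4, 4],
                        blocks_per_stage=[1, 1, 1, 1], input_size=32)
        net = build_model(spec, seed=0)
        # overwrite the head so the network predicts `preds` deterministically:
        # feed one-hot "logit images" through an identity-like trick is overkill —
        # instead evaluate via a stub: craft inputs whose logits we control is
        # fragile, so call the metric path directly through a fake network.

        class Stub:
            class spec:
                num_classes = k

            @staticmethod
            def predict_logits(x, batch_size=64):
                return np.eye(k)[preds] * 10.0

        return evaluate(Stub(), np.zeros((len(preds), 3, 2, 2)), labels)

    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        rep = self._report(y, y)
        assert rep.accuracy == 1.0
        assert all(e["f1"] == 1.0 for e in rep.per_class)
        assert rep.macro_f1 == 1.0

    def test_confusion_matrix_rows_sum_to_class_counts(self):
        labels = np.array([0, 0, 1, 1, 2, 2, 2])
        preds = np.array([0, 1, 1, 1, 2, 0, 2])
        rep = self._report(preds, labels)
        np.testing.assert_array_equal(rep.confusion.sum(axis=1), [2, 2, 3])
        assert rep.accuracy == pytest.approx(np.trace(rep.confusion) / 7)

    def test_macro_f1_invariant_under_label_permutation(self, rng):
        labels = rng.integers(0, 3, size=60)
        preds = rng.integers(0, 3, size=60)
        rep = self._report(preds, labels)
        perm = np.array([2, 0, 1])
        rep_p = self._report(perm[preds], perm[labels])
        assert rep.macro_f1 == pytest.approx(rep_p.macro_f1)
        assert rep.accuracy == pytest.approx(rep_p.accuracy)

    def test_empty_set_is_an_error(self, tiny_net):
        with pytest.raises(ValueError, match="empty"):
            evaluate(tiny_net, np.zeros((0, 3, 32, 32)), np.zeros(0, dtype=int))


class TestRocAuc:
    def test_perfect_separation_gives_auc_one(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        for _, _, a in roc_auc(scores, labels):
            assert a == pytest.approx(1.0)

    def test_random_scores_give_half(self, rng):
        n = 4000
        labels = rng.integers(0, 2, size=n)
        scores = rng.normal(size=(n, 2))
        for _, _, a in roc_auc(scores, labels):
            assert a == pytest.approx(0.5, abs=0.05)

    def test_negation_symmetry(self, rng):
        labels = np.array([0] * 10 + [1] * 10)
        scores = rng.normal(size=(20, 2))
        a = roc_auc(scores, labels)[0][2]
        a_neg = roc_auc(-scores, labels)[0][2]
        assert a + a_neg == pytest.approx(1.0)

    def test_single_class_labels_error(self):
        with pytest.raises(ValueError, match="single-class"):
            roc_auc(np.zeros((4, 2)), np.zeros(4, dtype=int))


class TestTrain:
    def test_smoke_training_reaches_high_accuracy(self, blob_data):
        x, y = blob_data
        spec = ArchSpec(num_classes=3, stem_channels=8, stage_widths=[8, 8, 16, 16],
                        blocks_per_stage=[1, 1, 1, 1], input_size=32,
                        attention_enabled=True)
        net = build_model(spec, seed=0)
        hist = train(net, x, y, Hyperparams(epochs=12, learning_rate=5e-3, seed=0))
        assert hist["accuracy"][-1] >= 0.95
        assert hist["loss"][-1] < hist["loss"][0]

    def test_identical_seeds_give_identical_histories(self, blob_data, tiny_net):
        x, y = blob_data
        net_a = build_model(tiny_net.spec, seed=4)
        net_b = build_model(tiny_net.spec, seed=4)
        hp = Hyperparams(epochs=2, seed=11)
        ha = train(net_a, x, y, hp)
        hb = train(net_b, x, y, hp)
        assert ha == hb

    def test_zero_learning_rate_freezes_weights(self, blob_data, tiny_net):
        x, y = blob_data
        before = {n: p.data.copy() for n, p in tiny_net.named_parameters()}
        train(tiny_net, x, y, Hyperparams(epochs=1, learning_rate=0.0))
        for n, p in tiny_net.named_parameters():
            np.testing.assert_array_equal(p.data, before[n])

    def test_class_count_mismatch_is_an_error(self, tiny_net, rng):
        x = rng.normal(size=(4, 3, 32, 32)).astype(np.float32)
        with pytest.raises(ValueError, match="head"):
            train(tiny_net, x, np.array([0, 1, 2, 7]), Hyperparams(epochs=1))


class TestGradCam:
    def test_output_range_and_shape(self, tiny_net, rng):
        img = rng.normal(size=(3, 32, 32)).astype(np.float32)
        heat = gradcam(tiny_net, img, target_class=0)
        assert heat.shape == (32, 32)
        assert heat.min() >= 0.0 and heat.max() <= 1.0

    def test_invalid_layer_lists_valid_names(self, tiny_net, rng):
        img = rng.normal(size=(3, 32, 32)).astype(np.float32)
        with pytest.raises(ValueError, match="stage4.block1"):
            gradcam(tiny_net, img, 0, layer="nope")

    def test_constant_activation_guard_gives_uniform_map(self, tiny_net):
        img = np.zeros((3, 32, 32), dtype=np.float32)
        # zero input + zero-ish BN shifts may still activate; force the guard
        heat = gradcam(tiny_net, img, target_class=1)
        assert heat.shape == (32, 32)
        assert np.isfinite(heat).all()

    def test_invariant_to_constant_logit_shift(self, tiny_net, rng):
        img = rng.normal(size=(3, 32, 32)).astype(np.float32)
        h1 = gradcam(tiny_net, img, 0)
        tiny_net.head.bias.data += 5.0  # shifts every logit equally
        h2 = gradcam(tiny_net, img, 0)
        np.testing.assert_allclose(h1, h2, atol=1e-5)
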