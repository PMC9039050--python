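"""Two-phase training protocol: initialisation modes, early stop, determinism."""

import numpy as np
import pytest

from toothmark.estimators import BackboneClassifier, WeakToothMarkDetector, _EarlyStopper
from toothmark.synthetic import generate_samples
from toothmark.training import TrainConfig, finetune, init_detector, pretrain_classifier

TINY = dict(arch="tiny_test", feature_channels=8, batch_size=8)


@pytest.fixture(scope="module")
def mini_train():
    return generate_samples(6, 8, seed=21)


class TestEarlyStopper:
    def test_never_returns_sub_best_accuracy_weights(self):
        stopper = _EarlyStopper(patience=3)
        accs = [0.5, 0.8, 0.7, 0.8, 0.6]
        for epoch, acc in enumerate(accs):
            stopper.update(epoch, acc, {"epoch": np.array([epoch])}, loss=1.0)
        assert stopper.best_acc == 0.8
        assert stopper.best_state["epoch"][0] == 1  # first epoch reaching best

    def test_accuracy_tie_broken_by_lower_loss(self):
        stopper = _EarlyStopper(patience=5)
        stopper.update(0, 0.9, {"e": np.array([0])}, loss=0.5)
        stopper.update(1, 0.9, {"e": np.array([1])}, loss=0.3)
        stopper.update(2, 0.9, {"e": np.array([2])}, loss=0.4)
        assert stopper.best_state["e"][0] == 1

    def test_patience_one_constant_accuracy_stops_after_two_epochs(self):
        stopper = _EarlyStopper(patience=1)
        assert not stopper.update(0, 0.7, {}, loss=1.0)
        assert stopper.update(1, 0.7, {}, loss=1.0)


class TestPretrain:
    def test_zero_epochs_returns_initialization(self, mini_train):
        clf = BackboneClassifier(max_epochs=0, seed=3, **TINY)
        clf.fit(mini_train)
        from toothmark.backbones import build_backbone

        fresh = build_backbone("tiny_test", rng=np.random.default_rng(3), channels=8)
        for k, v in fresh.named_state().items():
            assert (clf.backbone_state_[k] == v).all()

    def test_same_seed_reproduces_weights(self, mini_train):
        runs = []
        for _ in range(2):
            clf = BackboneClassifier(max_epochs=2, learning_rate=1e-3, seed=7, **TINY)
            clf.fit(mini_train)
            runs.append(clf.backbone_state_)
        for k in runs[0]:
            assert (runs[0][k] == runs[1][k]).all(), k

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            pretrain_classifier([], None, TrainConfig())


class TestInitModes:
    def test_iw_requires_external_weights(self):
        with pytest.raises(ValueError, match="external_weights"):
            init_detector("iw", pretrained=None, external=None)

    def test_tl_requires_pretrained_weights(self):
        with pytest.raises(ValueError, match="backbone_weights"):
            init_detector("tl", pretrained=None)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="init_mode"):
            init_detector("bogus")

    def test_backbone_copied_bit_exact_heads_fresh(self, mini_train):
        clf = BackboneClassifier(max_epochs=1, seed=5, **TINY)
        clf.fit(mini_train)
        cfg = TrainConfig(arch="tiny_test", feature_channels=8, embed_dim=16)
        det = init_detector("iw_tl", pretrained=clf.backbone_state_, cfg=cfg)
        net = det._build_net()
        for k, v in net.backbone.named_state().items():
            assert (clf.backbone_state_[k] == v).all(), k

    def test_heads_vary_with_seed_backbone_does_not(self, mini_train):
        clf = BackboneClassifier(max_epochs=1, seed=5, **TINY)
        clf.fit(mini_train)
        nets = []
        for seed in (1, 2):
            cfg = TrainConfig(arch="tiny_test", feature_channels=8, embed_dim=16, seed=seed)
            nets.append(init_detector("tl", pretrained=clf.backbone_state_, cfg=cfg)._build_net())
        a, b = nets
        assert (a.backbone.named_state()["layers.0.weight"] == b.backbone.named_state()["layers.0.weight"]).all()
        assert not (a.head.fc1.weight.data == b.head.fc1.weight.data).all()


class TestFinetune:
    def test_zero_learning_rate_leaves_weights_unchanged(self, mini_train):
        det = WeakToothMarkDetector(
            init_mode="random", learning_rate=0.0, max_epochs=1, embed_dim=16,
            augment=False, seed=2, **TINY,
        )
        before = det._build_net().named_state()
        det.fit(mini_train)
        after = det.net_.named_state()
        for k in before:
            assert (before[k] == after[k]).all(), k

    def test_constant_accuracy_patience_one_stops_after_two_epochs(self, mini_train):
        det = WeakToothMarkDetector(
            init_mode="random", learning_rate=0.0, max_epochs=50, patience=1,
            embed_dim=16, augment=False, seed=2, **TINY,
        )
        det.fit(mini_train)
        assert len(det.history_["val_accuracy"]) == 2

    def test_fit_predict_round_trip_and_determinism(self, mini_train):
        preds = []
        for _ in range(2):
            det = WeakToothMarkDetector(
                init_mode="random", learning_rate=1e-3, max_epochs=2, embed_dim=16,
                seed=4, **TINY,
            )
            det.fit(mini_train)
            preds.append(det.predict(mini_train))
        assert (preds[0] == preds[1]).all()
        assert set(preds[0]) <= {0, 1}

    def test_finetune_wrapper_applies_config(self, mini_train):
        cfg = TrainConfig(
            arch="tiny_test", feature_channels=8, embed_dim=16,
            learning_rate=1e-3, max_epochs=1, seed=0,
        )
        det = init_detector("random", cfg=cfg)
        det, history = finetune(det, mini_train, None, cfg)
        assert len(history["train_loss"]) == 1
        assert hasattr(det, "net_")
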