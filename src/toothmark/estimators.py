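"""Scikit-learn style estimators wrapping the two training phases.

:class:`BackboneClassifier` is the phase-one image-level classifier: a
backbone, global average pooling and a linear softmax head, trained
with cross-entropy on image labels only.  Its fitted backbone weights
initialise phase two.

:class:`WeakToothMarkDetector` is the weakly supervised detector: the
backbone (optionally initialised from a pretrained classifier), region
proposals along the tongue edges, SPP region features and the
two-stream scoring head, trained end to end with per-class binary
cross-entropy on the image-level score.  ``predict`` gives image labels
and ``detect`` gives tooth-mark boxes, although only image labels were
ever supervised.

Both estimators follow sklearn conventions (``get_params`` /
``set_params``, fitted attributes with trailing underscores) and accept
a list of :class:`~toothmark.preprocess.TongueSample` as ``X``.
"""

from __future__ import annotations

import copy
import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from . import nn
from .backbones import build_backbone, feature_channels
from .model import ToothMarkNet, bce_loss, predict_image, select_boxes
from .preprocess import PreprocessConfig, TongueSample, augment_pair, prepare_input
from .srp import DegenerateMaskError, SRPParams, propose_regions

__all__ = ["BackboneClassifier", "WeakToothMarkDetector"]


def _as_samples(X) -> list[TongueSample]:
    samples = list(X)
    if not samples:
        raise ValueError("empty training set")
    if not all(isinstance(s, TongueSample) for s in samples):
        raise TypeError("X must be a sequence of TongueSample")
    return samples


def _prepare_all(samples: list[TongueSample], cfg: PreprocessConfig):
    images, masks = [], []
    for s in samples:
        img, msk = prepare_input(s, cfg)
        images.append(img)
        masks.append(msk)
    return images, masks


def _labels(samples: list[TongueSample], y) -> np.ndarray:
    if y is None:
        return np.array([s.label for s in samples], dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if len(y) != len(samples):
        raise ValueError("X and y length mismatch")
    return y


class _EarlyStopper:
    """Track best validation accuracy; stop after ``patience`` flat epochs.

    Ties in validation accuracy are broken toward lower validation loss,
    so the returned weights never come from an epoch with sub-best
    accuracy, but among equally accurate epochs the best-calibrated one
    wins.  The patience counter watches accuracy only.
    """

    def __init__(self, patience: int) -> None:
        self.patience = patience
        self.best_acc = -np.inf
        self.best_loss = np.inf
        self.best_state: dict | None = None
        self.best_epoch = -1
        self.stale = 0

    def update(self, epoch: int, acc: float, state: dict, loss: float = np.inf) -> bool:
        """Record the epoch; return True when training should stop."""
        improved_acc = acc > self.best_acc
        if improved_acc or (acc == self.best_acc and loss < self.best_loss):
            self.best_acc = acc
            self.best_loss = loss
            self.best_state = copy.deepcopy(state)
            self.best_epoch = epoch
        if improved_acc:
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


class BackboneClassifier(ClassifierMixin, BaseEstimator):
    """Image-level tongue classifier used to pretrain the backbone.

    Parameters mirror the study defaults: Adam with learning rate 1e-4,
    weight decay 1e-4, batch size 32, early stopping after 10 epochs
    without validation-accuracy improvement.
    """

    def __init__(
        self,
        arch: str = "tiny_test",
        feature_channels: int | None = None,
        learning_rate: float = 1e-4,
        weight_decay: float = 1e-4,
        batch_size: int = 32,
        max_epochs: int = 200,
        patience: int = 10,
        seed: int = 0,
        init_weights: dict | None = None,
        input_size: int = 224,
        augment: bool = True,
        rotation_max_deg: float = 15.0,
        hflip_prob: float = 0.5,
        vflip_prob: float = 0.5,
        validation_fraction: float = 0.2,
    ) -> None:
        self.arch = arch
        self.feature_channels = feature_channels
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed
        self.init_weights = init_weights
        self.input_size = input_size
        self.augment = augment
        self.rotation_max_deg = rotation_max_deg
        self.hflip_prob = hflip_prob
        self.vflip_prob = vflip_prob
        self.validation_fraction = validation_fraction

    # ------------------------------------------------------------------
    def _preprocess_cfg(self) -> PreprocessConfig:
        return PreprocessConfig(
            input_size=self.input_size,
            rotation_max_deg=self.rotation_max_deg,
            hflip_prob=self.hflip_prob,
            vflip_prob=self.vflip_prob,
            augment_seed=self.seed,
        )

    def _build(self, rng: np.random.Generator):
        cf = feature_channels(self.arch, self.feature_channels)
        backbone = build_backbone(self.arch, self.init_weights, rng=rng, channels=cf)
        head = nn.Sequential(nn.GlobalAvgPool(), nn.Linear(cf, 2, rng=rng))
        return backbone, head

    @staticmethod
    def _forward(backbone, head, batch, training):
        return head.forward(backbone.forward(batch, training), training)

    def fit(self, X, y=None, validation_data=None):
        """Train on TongueSamples; ``validation_data`` overrides the split."""
        samples = _as_samples(X)
        labels = _labels(samples, y)
        cfg = self._preprocess_cfg()
        rng = np.random.default_rng(self.seed)
        backbone, head = self._build(rng)
        params = backbone.parameters() + head.parameters()
        opt = nn.Adam(params, lr=self.learning_rate, weight_decay=self.weight_decay)

        images, masks = _prepare_all(samples, cfg)
        if validation_data is not None:
            val_samples = _as_samples(validation_data)
            val_images, _ = _prepare_all(val_samples, cfg)
            val_labels = _labels(val_samples, None)
            tr_idx = np.arange(len(samples))
        elif self.validation_fraction > 0 and len(samples) >= 5:
            tr_idx, va_idx = train_test_split(
                np.arange(len(samples)),
                test_size=self.validation_fraction,
                random_state=self.seed % (2**32),
                stratify=labels if len(np.unique(labels)) > 1 else None,
            )
            val_images = [images[i] for i in va_idx]
            val_labels = labels[va_idx]
        else:
            tr_idx = np.arange(len(samples))
            val_images, val_labels = images, labels

        stopper = _EarlyStopper(self.patience)
        history = {"train_loss": [], "val_accuracy": []}
        state = lambda: {**backbone.named_state("backbone."), **head.named_state("head.")}  # noqa: E731

        for epoch in range(self.max_epochs):
            order = rng.permutation(tr_idx)
            total, count = 0.0, 0
            for start in range(0, len(order), self.batch_size):
                idx = order[start : start + self.batch_size]
                batch_imgs = []
                for i in idx:
                    img = images[i]
                    if self.augment:
                        img, _ = augment_pair(img, masks[i], cfg, rng)
                    batch_imgs.append(img)
                batch = ToothMarkNet.to_batch(batch_imgs)
                t = labels[idx]
                logits = self._forward(backbone, head, batch, True)
                p = np.exp(logits - logits.max(axis=1, keepdims=True))
                p /= p.sum(axis=1, keepdims=True)
                total += float(-np.log(np.maximum(p[np.arange(len(idx)), t], 1e-12)).sum())
                count += len(idx)
                dlogits = p.copy()
                dlogits[np.arange(len(idx)), t] -= 1.0
                dlogits /= len(idx)
                backbone.backward(head.backward(dlogits.astype(np.float32)))
                opt.step()
                for prm in params:
                    prm.grad[...] = 0.0
            val_acc, val_loss = self._evaluate(backbone, head, val_images, val_labels)
            history["train_loss"].append(total / max(count, 1))
            history["val_accuracy"].append(val_acc)
            if stopper.update(epoch, val_acc, state(), val_loss):
                break

        if stopper.best_state is not None:
            backbone.load_state(stopper.best_state, "backbone.")
            head.load_state(stopper.best_state, "head.")
        self.backbone_ = backbone
        self.head_ = head
        self.backbone_state_ = backbone.named_state()
        self.classes_ = np.array([0, 1])
        self.history_ = history
        self.best_epoch_ = stopper.best_epoch
        self.n_features_in_ = 1
        return self

    def _evaluate(self, backbone, head, images, labels) -> tuple[float, float]:
        if len(images) == 0:
            return 0.0, np.inf
        preds, losses = [], []
        for start in range(0, len(images), self.batch_size):
            t = labels[start : start + self.batch_size]
            batch = ToothMarkNet.to_batch(images[start : start + self.batch_size])
            logits = self._forward(backbone, head, batch, False)
            p = np.exp(logits - logits.max(axis=1, keepdims=True))
            p /= p.sum(axis=1, keepdims=True)
            losses.extend(-np.log(np.maximum(p[np.arange(len(t)), t], 1e-12)))
            preds.extend(np.argmax(logits, axis=1))
        return float(np.mean(np.asarray(preds) == labels)), float(np.mean(losses))

    def predict(self, X):
        samples = _as_samples(X)
        cfg = self._preprocess_cfg()
        images, _ = _prepare_all(samples, cfg)
        preds = []
        for start in range(0, len(images), self.batch_size):
            batch = ToothMarkNet.to_batch(images[start : start + self.batch_size])
            logits = self._forward(self.backbone_, self.head_, batch, False)
            preds.extend(np.argmax(logits, axis=1))
        return np.asarray(preds, dtype=np.int64)


class WeakToothMarkDetector(ClassifierMixin, BaseEstimator):
    """Weakly supervised tooth-mark classifier-localizer.

    ``init_mode`` selects how the backbone is initialised:

    * ``"iw"`` — generic-image weights (``external_weights``) only;
    * ``"tl"`` — weights of a tongue classifier trained from random
      initialisation (``backbone_weights``);
    * ``"iw_tl"`` — weights of a tongue classifier that itself started
      from generic-image weights (``backbone_weights``); the proposed
      configuration;
    * ``"random"`` — no transfer, fresh random backbone.

    SPP/FC/scoring-head weights are always freshly initialised from
    ``seed``.
    """

    def __init__(
        self,
        arch: str = "tiny_test",
        feature_channels: int | None = None,
        embed_dim: int = 4096,
        dropout: float = 0.5,
        spp_levels: tuple[int, ...] = (1, 2),
        input_size: int = 224,
        box_size: int = 32,
        step_fraction: float = 2.0 / 3.0,
        trim_count: int = 1,
        init_mode: str = "iw_tl",
        backbone_weights: dict | None = None,
        external_weights: dict | None = None,
        learning_rate: float = 1e-4,
        weight_decay: float = 1e-4,
        batch_size: int = 32,
        max_epochs: int = 200,
        patience: int = 10,
        seed: int = 0,
        augment: bool = True,
        rotation_max_deg: float = 15.0,
        hflip_prob: float = 0.5,
        vflip_prob: float = 0.5,
        validation_fraction: float = 0.2,
        freeze_backbone: bool = False,
        on_empty_regions: str = "skip",
    ) -> None:
        self.arch = arch
        self.feature_channels = feature_channels
        self.embed_dim = embed_dim
        self.dropout = dropout
        self.spp_levels = spp_levels
        self.input_size = input_size
        self.box_size = box_size
        self.step_fraction = step_fraction
        self.trim_count = trim_count
        self.init_mode = init_mode
        self.backbone_weights = backbone_weights
        self.external_weights = external_weights
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed
        self.augment = augment
        self.rotation_max_deg = rotation_max_deg
        self.hflip_prob = hflip_prob
        self.vflip_prob = vflip_prob
        self.validation_fraction = validation_fraction
        self.freeze_backbone = freeze_backbone
        self.on_empty_regions = on_empty_regions

    # ------------------------------------------------------------------
    def _preprocess_cfg(self) -> PreprocessConfig:
        return PreprocessConfig(
            input_size=self.input_size,
            rotation_max_deg=self.rotation_max_deg,
            hflip_prob=self.hflip_prob,
            vflip_prob=self.vflip_prob,
            augment_seed=self.seed,
        )

    def _srp_params(self) -> SRPParams:
        return SRPParams(
            box_size=self.box_size,
            step_fraction=self.step_fraction,
            trim_count=self.trim_count,
        )

    def _initial_backbone_weights(self) -> dict | None:
        mode = self.init_mode
        if mode == "random":
            return None
        if mode == "iw":
            if self.external_weights is None:
                raise ValueError("init_mode='iw' requires external_weights")
            return self.external_weights
        if mode in ("tl", "iw_tl"):
            if self.backbone_weights is None:
                raise ValueError(f"init_mode={mode!r} requires backbone_weights")
            return self.backbone_weights
        raise ValueError(f"unknown init_mode {mode!r}")

    def _build_net(self) -> ToothMarkNet:
        # strip any pretrain-head entries; keep backbone.* only
        weights = self._initial_backbone_weights()
        if weights is not None:
            weights = {
                k.removeprefix("backbone."): v
                for k, v in weights.items()
                if not k.startswith("head.")
            }
        return ToothMarkNet(
            arch=self.arch,
            feature_channels_override=self.feature_channels,
            embed_dim=self.embed_dim,
            spp_levels=tuple(self.spp_levels),
            input_size=self.input_size,
            seed=self.seed,
            dropout=self.dropout,
            backbone_weights=weights,
        )

    def _regions(self, masked_image):
        return propose_regions(masked_image, self._srp_params())

    def fit(self, X, y=None, validation_data=None):
        samples = _as_samples(X)
        labels = _labels(samples, y)
        cfg = self._preprocess_cfg()
        srp = self._srp_params()
        rng = np.random.default_rng(self.seed)
        net = self._build_net()
        if self.freeze_backbone:
            params = net.head.parameters()
        else:
            params = net.parameters()
        opt = nn.Adam(params, lr=self.learning_rate, weight_decay=self.weight_decay)

        images, masks = _prepare_all(samples, cfg)
        if validation_data is not None:
            val_samples = _as_samples(validation_data)
            val_images, _ = _prepare_all(val_samples, cfg)
            val_labels = _labels(val_samples, None)
            tr_idx = np.arange(len(samples))
        elif self.validation_fraction > 0 and len(samples) >= 5:
            tr_idx, va_idx = train_test_split(
                np.arange(len(samples)),
                test_size=self.validation_fraction,
                random_state=self.seed % (2**32),
                stratify=labels if len(np.unique(labels)) > 1 else None,
            )
            val_images = [images[i] for i in va_idx]
            val_labels = labels[va_idx]
        else:
            tr_idx = np.arange(len(samples))
            val_images, val_labels = images, labels

        stopper = _EarlyStopper(self.patience)
        history = {"train_loss": [], "val_accuracy": []}
        warned = False

        for epoch in range(self.max_epochs):
            order = rng.permutation(tr_idx)
            total, count = 0.0, 0
            for start in range(0, len(order), self.batch_size):
                idx = order[start : start + self.batch_size]
                batch_imgs, batch_regions, batch_labels = [], [], []
                for i in idx:
                    img, msk = images[i], masks[i]
                    if self.augment:
                        img, msk = augment_pair(img, msk, cfg, rng)
                    try:
                        regions = propose_regions(img, srp)
                    except DegenerateMaskError:
                        if self.on_empty_regions == "error":
                            raise
                        if not warned:
                            warnings.warn(
                                "skipping training image(s) with no candidate regions",
                                stacklevel=2,
                            )
                            warned = True
                        continue
                    batch_imgs.append(img)
                    batch_regions.append(regions)
                    batch_labels.append(labels[i])
                if not batch_imgs:
                    continue
                batch = ToothMarkNet.to_batch(batch_imgs)
                loss = net.train_batch(batch, batch_regions, np.asarray(batch_labels))
                total += loss * len(batch_imgs)
                count += len(batch_imgs)
                opt.step()
                net.zero_grad()
            val_acc, val_loss = self._evaluate(net, val_images, val_labels, srp)
            history["train_loss"].append(total / max(count, 1))
            history["val_accuracy"].append(val_acc)
            if stopper.update(epoch, val_acc, net.named_state(), val_loss):
                break

        if stopper.best_state is not None:
            net.load_state(stopper.best_state)
        self.net_ = net
        self.classes_ = np.array([0, 1])
        self.history_ = history
        self.best_epoch_ = stopper.best_epoch
        self.n_features_in_ = 1
        return self

    # -- inference -----------------------------------------------------
    def _forward_samples(self, X):
        samples = _as_samples(X)
        cfg = self._preprocess_cfg()
        srp = self._srp_params()
        images, _ = _prepare_all(samples, cfg)
        outputs = []
        for start in range(0, len(images), self.batch_size):
            chunk = images[start : start + self.batch_size]
            regions = [self._regions(img) for img in chunk]
            batch = ToothMarkNet.to_batch(chunk)
            outs = self.net_.forward(batch, regions, training=False)
            for out, regs in zip(outs, regions):
                out["regions"] = regs
                outputs.append(out)
        return outputs

    def _evaluate(self, net, images, labels, srp) -> tuple[float, float]:
        preds, losses = [], []
        for start in range(0, len(images), self.batch_size):
            chunk = images[start : start + self.batch_size]
            t = labels[start : start + self.batch_size]
            regions = [propose_regions(img, srp) for img in chunk]
            batch = ToothMarkNet.to_batch(chunk)
            outs = net.forward(batch, regions, training=False)
            preds.extend(predict_image(out["y"]) for out in outs)
            losses.extend(bce_loss(out["y"], int(tb)) for out, tb in zip(outs, t))
        if not preds:
            return 0.0, np.inf
        return float(np.mean(np.asarray(preds) == labels)), float(np.mean(losses))

    def image_scores(self, X) -> np.ndarray:
        """Raw image-level score vectors ``y`` (not a simplex), shape (N, C)."""
        return np.stack([out["y"] for out in self._forward_samples(X)])

    def predict(self, X) -> np.ndarray:
        return np.array(
            [predict_image(out["y"]) for out in self._forward_samples(X)], dtype=np.int64
        )

    def predict_proba(self, X) -> np.ndarray:
        y = self.image_scores(X)
        return y / y.sum(axis=1, keepdims=True)

    def detect(self, X, target_class: int = 1, only_positive: bool = True):
        """Predicted tooth-mark boxes per image.

        Returns one list of ``(CandidateRegion, score)`` per input,
        containing the regions whose detection-stream score for
        ``target_class`` exceeds 1/R.  With ``only_positive`` (default),
        images predicted non-tooth-marked yield an empty list.
        """
        results = []
        for out in self._forward_samples(X):
            pred = predict_image(out["y"])
            if only_positive and pred != target_class:
                results.append([])
            else:
                results.append(select_boxes(out["sigma_det"], out["regions"], target_class))
        return results

    def loss(self, X, y=None) -> float:
        """Mean image-level binary cross-entropy on a dataset."""
        samples = _as_samples(X)
        labels = _labels(samples, y)
        outs = self._forward_samples(samples)
        return float(
            np.mean([bce_loss(out["y"], int(t)) for out, t in zip(outs, labels)])
        )
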