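"""Two-phase training protocol as thin wrappers over the estimators.

Phase one trains an image-level tongue classifier
(:func:`pretrain_classifier`).  Phase two builds the weakly supervised
detector from one of three initialisations (:func:`init_detector`) and
fine-tunes it with image-level labels only (:func:`finetune`):

* **IW** — generic-image weights straight into the detector backbone;
* **TL** — weights of a tongue classifier pretrained from random
  initialisation;
* **IW+TL** — weights of a tongue classifier that itself started from
  generic-image weights (the proposed configuration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import BackboneClassifier, WeakToothMarkDetector
from .preprocess import TongueSample

__all__ = ["TrainConfig", "pretrain_classifier", "init_detector", "finetune"]

INIT_MODES = ("iw", "tl", "iw_tl", "random")


@dataclass
class TrainConfig:
    """Optimisation settings (defaults follow the study protocol)."""

    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 32
    early_stop_patience: int = 10
    max_epochs: int = 200
    seed: int = 0
    init_mode: str = "iw_tl"
    arch: str = "tiny_test"
    feature_channels: int | None = None
    embed_dim: int = 4096
    augment: bool = True
    freeze_backbone: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.init_mode not in INIT_MODES:
            raise ValueError(f"init_mode must be one of {INIT_MODES}")


def pretrain_classifier(
    train: list[TongueSample],
    val: list[TongueSample] | None,
    cfg: TrainConfig,
    init_weights: dict | None = None,
) -> tuple[dict, list[float], BackboneClassifier]:
    """Phase one: train the image-level classifier, return backbone weights.

    Returns ``(backbone_state, val_accuracy_curve, fitted_estimator)``;
    the temporary pooling/FC head is not part of the returned state.
    """
    if not train:
        raise ValueError("empty training split")
    clf = BackboneClassifier(
        arch=cfg.arch,
        feature_channels=cfg.feature_channels,
        learning_rate=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
        batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs,
        patience=cfg.early_stop_patience,
        seed=cfg.seed,
        init_weights=init_weights,
        augment=cfg.augment,
        **cfg.extra,
    )
    clf.fit(train, validation_data=val)
    return clf.backbone_state_, clf.history_["val_accuracy"], clf


def init_detector(
    mode: str,
    pretrained: dict | None = None,
    external: dict | None = None,
    cfg: TrainConfig | None = None,
) -> WeakToothMarkDetector:
    """Build an (unfitted) detector with the requested initialisation.

    ``pretrained`` are phase-one backbone weights; ``external`` are
    generic-image weights.  Missing required weights raise ValueError.
    """
    cfg = cfg or TrainConfig(init_mode=mode)
    det = WeakToothMarkDetector(
        arch=cfg.arch,
        feature_channels=cfg.feature_channels,
        embed_dim=cfg.embed_dim,
        init_mode=mode,
        backbone_weights=pretrained,
        external_weights=external,
        learning_rate=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
        batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs,
        patience=cfg.early_stop_patience,
        seed=cfg.seed,
        augment=cfg.augment,
        freeze_backbone=cfg.freeze_backbone,
        **cfg.extra,
    )
    det._initial_backbone_weights()  # validate mode/weights combination now
    return det


def finetune(
    det: WeakToothMarkDetector,
    train: list[TongueSample],
    val: list[TongueSample] | None,
    cfg: TrainConfig | None = None,
) -> tuple[WeakToothMarkDetector, dict]:
    """Phase two: fine-tune the detector with image-level labels only."""
    if cfg is not None:
        det.set_params(
            learning_rate=cfg.learning_rate,
            weight_decay=cfg.weight_decay,
            batch_size=cfg.batch_size,
            patience=cfg.early_stop_patience,
            max_epochs=cfg.max_epochs,
        )
    det.fit(train, validation_data=val)
    return det, det.history_


def external_generic_weights(cfg: TrainConfig, n_images: int = 64) -> dict:
    """Generic-image backbone weights from a synthetic shape-classification task.

    Stands in for large-corpus pretraining so the package never needs a
    download; deterministic given ``cfg.seed``.
    """
    from .synthetic import generate_generic_shapes

    shapes = generate_generic_shapes(n_images, seed=cfg.seed + 104729)
    state, _, _ = pretrain_classifier(shapes, None, cfg)
    return state
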