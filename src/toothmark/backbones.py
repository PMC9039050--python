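"""Convolutional feature extractors with a fixed 32x overall stride.

Both architectures map a ``(B, 3, 224, 224)`` input to a ``(B, C_f, 7, 7)``
feature map, the contract every downstream component (grid mapping, SPP
pooling) relies on:

``resnet34``
    The classic 34-layer residual network with the global-average-pool
    and final fully connected classifier removed, so the last batch-norm
    output (512 channels) is the feature map.
``tiny_test``
    A four-layer strided CNN with the same 32x stride, small enough to
    train from scratch on a CPU in seconds.  Used for desk-scale
    experiments and throughout the test suite.
"""

from __future__ import annotations

import numpy as np

from .nn import BatchNorm2d, Conv2d, MaxPool2d, Module, ReLU, ResidualBlock, Sequential

BACKBONE_STRIDE = 32

_ARCH_CHANNELS = {"resnet34": 512, "tiny_test": 64}


def feature_channels(arch: str, override: int | None = None) -> int:
    if arch == "tiny_test" and override is not None:
        return override
    return _ARCH_CHANNELS[arch]


def _basic_block(
    cin: int, cout: int, stride: int, rng: np.random.Generator
) -> ResidualBlock:
    main = Sequential(
        Conv2d(cin, cout, 3, stride=stride, padding=1, bias=False, rng=rng),
        BatchNorm2d(cout),
        ReLU(),
        Conv2d(cout, cout, 3, stride=1, padding=1, bias=False, rng=rng),
        BatchNorm2d(cout),
    )
    shortcut = None
    if stride != 1 or cin != cout:
        shortcut = Sequential(
            Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng),
            BatchNorm2d(cout),
        )
    return ResidualBlock(main, shortcut)


def _resnet34(rng: np.random.Generator) -> Sequential:
    layers: list[Module] = [
        Conv2d(3, 64, 7, stride=2, padding=3, bias=False, rng=rng),
        BatchNorm2d(64),
        ReLU(),
        MaxPool2d(3, stride=2, padding=1),
    ]
    cin = 64
    for cout, blocks, first_stride in ((64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)):
        for b in range(blocks):
            layers.append(_basic_block(cin, cout, first_stride if b == 0 else 1, rng))
            cin = cout
    return Sequential(*layers)


def _tiny(rng: np.random.Generator, channels: int) -> Sequential:
    # receptive field kept at 37 px (~ one candidate box) so a feature
    # cell describes its own neighbourhood rather than half the tongue
    return Sequential(
        Conv2d(3, 16, 5, stride=4, padding=2, rng=rng),
        ReLU(),
        Conv2d(16, 32, 3, stride=2, padding=1, rng=rng),
        ReLU(),
        Conv2d(32, 64, 2, stride=2, padding=0, rng=rng),
        ReLU(),
        Conv2d(64, channels, 2, stride=2, padding=0, rng=rng),
        ReLU(),
    )


def build_backbone(
    arch: str = "tiny_test",
    init_weights: dict[str, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
    channels: int | None = None,
) -> Sequential:
    """Construct a feature extractor; optionally load weights by name/shape.

    Parameters
    ----------
    arch:
        ``"resnet34"`` or ``"tiny_test"``.
    init_weights:
        Named state dict (as produced by ``Module.named_state``); a shape
        mismatch raises ``ValueError``.
    channels:
        Output channel count, configurable for ``tiny_test`` only.
    """
    if arch not in _ARCH_CHANNELS:
        raise ValueError(f"unknown backbone arch {arch!r}")
    rng = rng or np.random.default_rng(0)
    if arch == "resnet34":
        net = _resnet34(rng)
    else:
        net = _tiny(rng, feature_channels(arch, channels))
    if init_weights is not None:
        net.load_state(init_weights)
    return net
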