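"""Two-stream weakly supervised scoring network for tooth-mark detection.

The network shares one backbone forward pass per image: the 224x224
masked tongue image becomes a 7x7x``C_f`` feature map (32x stride).
Each candidate region from the edge-scan proposer is mapped onto the
feature grid, pooled by a small spatial pyramid (1x1 and 2x2 max-pool
bins) to a fixed-length vector, embedded by two FC+ReLU layers, and
scored by two parallel linear heads:

* the **classification stream** softmax-normalises the ``C x R`` logits
  over *classes* within each region ("what is in this region?"),
* the **detection stream** softmax-normalises over *regions* within
  each class ("which region shows this class?").

Their elementwise (Hadamard) product summed over regions gives the
image-level score vector ``y`` with every component in (0, 1), trained
with per-class binary cross-entropy against the image-level label only.
At inference, regions whose detection-stream score for the tooth-mark
class exceeds ``1/R`` are emitted as predicted tooth-mark boxes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .backbones import BACKBONE_STRIDE, build_backbone, feature_channels
from .srp import CandidateRegion, RegionSet

__all__ = [
    "GridMapping",
    "map_box_to_grid",
    "spp_pool",
    "softmax_over_classes",
    "softmax_over_regions",
    "image_score",
    "bce_loss",
    "predict_image",
    "select_boxes",
    "RegionScoringHead",
    "ToothMarkNet",
]


@dataclass(frozen=True)
class GridMapping:
    """Correspondence between input pixels and backbone feature cells."""

    input_size: int = 224
    stride: int = BACKBONE_STRIDE
    feature_channels: int = 512

    @property
    def grid(self) -> int:
        return self.input_size // self.stride

    def __post_init__(self) -> None:
        if self.input_size % self.stride:
            raise ValueError("input_size must be divisible by the backbone stride")


def map_box_to_grid(
    box: CandidateRegion | tuple[int, int, int, int], gm: GridMapping
) -> tuple[int, int, int, int]:
    """Feature-grid cell range ``(i0, j0, i1, j1)`` covering a pixel box.

    ``i`` indexes columns (x), ``j`` rows (y); the range is half-open
    and always nonempty: ``i0 = floor(x_min/stride)``,
    ``i1 = ceil((x_min+w)/stride)``, clipped to the grid.  A 32-pixel
    box on the 32-stride grid covers between 1x1 and 2x2 cells.
    """
    if isinstance(box, CandidateRegion):
        x, y, w, h = box.x_min, box.y_min, box.w, box.h
    else:
        x, y, w, h = box
    g, s = gm.grid, gm.stride
    i0 = min(max(x // s, 0), g - 1)
    j0 = min(max(y // s, 0), g - 1)
    i1 = min(math.ceil((x + w) / s), g)
    j1 = min(math.ceil((y + h) / s), g)
    return (i0, j0, max(i1, i0 + 1), max(j1, j0 + 1))


def _bin_edges(n_cells: int, n_bins: int) -> list[tuple[int, int]]:
    """Nonempty pyramid bin extents over ``n_cells`` cells."""
    return [
        (math.floor(b * n_cells / n_bins), max(math.ceil((b + 1) * n_cells / n_bins), math.floor(b * n_cells / n_bins) + 1))
        for b in range(n_bins)
    ]


def spp_pool(
    feature_map: np.ndarray,
    cells: tuple[int, int, int, int],
    levels: tuple[int, ...] = (1, 2),
) -> np.ndarray:
    """Max-pool a cell sub-grid into fixed pyramid bins.

    ``feature_map`` is channels-first ``(C_f, G, G)``; the output length
    is ``sum(n*n for n in levels) * C_f`` regardless of the region size.
    """
    vec, _ = _spp_pool_cached(feature_map, cells, levels)
    return vec


def _spp_pool_cached(feature_map, cells, levels):
    i0, j0, i1, j1 = cells
    sub = feature_map[:, j0:j1, i0:i1]
    C, gh, gw = sub.shape
    parts: list[np.ndarray] = []
    cache: list[tuple[int, int, int, np.ndarray]] = []  # (row0, col0, ncols, argmax)
    for n in levels:
        for r0, r1 in _bin_edges(gh, n):
            for c0, c1 in _bin_edges(gw, n):
                flat = sub[:, r0:r1, c0:c1].reshape(C, -1)
                am = flat.argmax(axis=1)
                parts.append(flat[np.arange(C), am])
                cache.append((j0 + r0, i0 + c0, c1 - c0, am))
    return np.concatenate(parts), cache


def _spp_backward(dpooled, cache, fmap_shape, dfmap) -> None:
    C = fmap_shape[0]
    chan = np.arange(C)
    nb = len(cache)
    d = dpooled.reshape(nb, C)
    for b, (r0, c0, ncols, am) in enumerate(cache):
        rows = r0 + am // ncols
        cols = c0 + am % ncols
        np.add.at(dfmap, (chan, rows, cols), d[b])


def _softmax(x: np.ndarray, axis: int) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_over_classes(logits: np.ndarray) -> np.ndarray:
    """Classification stream: columns (one per region) sum to 1 over classes."""
    return _softmax(logits, axis=0)


def softmax_over_regions(logits: np.ndarray) -> np.ndarray:
    """Detection stream: rows (one per class) sum to 1 over regions."""
    return _softmax(logits, axis=1)


def image_score(sigma_class: np.ndarray, sigma_det: np.ndarray) -> np.ndarray:
    """Image-level score ``y_c = sum_r sigma_class[c,r] * sigma_det[c,r]``.

    Each component lies strictly inside (0, 1) for R >= 1 finite logits
    (it is a convex combination of class probabilities over regions).
    """
    if sigma_class.shape != sigma_det.shape:
        raise ValueError(
            f"stream shapes disagree: {sigma_class.shape} vs {sigma_det.shape}"
        )
    return (sigma_class * sigma_det).sum(axis=1)


def bce_loss(y: np.ndarray, label: int) -> float:
    """Per-class binary cross-entropy of ``y`` against a one-hot label."""
    yc = np.clip(np.asarray(y, dtype=np.float64), 1e-12, 1.0 - 1e-12)
    t = np.zeros_like(yc)
    t[label] = 1.0
    return float(-(t * np.log(yc) + (1.0 - t) * np.log(1.0 - yc)).sum())


def predict_image(y: np.ndarray) -> int:
    """Argmax class; ties break toward class 0 (non-tooth-marked)."""
    return int(np.argmax(y))


def select_boxes(
    sigma_det: np.ndarray,
    regions: RegionSet | list[CandidateRegion],
    target_class: int = 1,
) -> list[tuple[CandidateRegion, float]]:
    """Regions whose detection-stream score exceeds the uniform level 1/R.

    Returns ``(region, score)`` pairs sorted by descending score; a
    uniform detection row selects nothing (no score strictly exceeds
    1/R).
    """
    region_list = list(regions)
    R = len(region_list)
    scores = sigma_det[target_class]
    if len(scores) != R:
        raise ValueError("sigma_det width does not match the region count")
    picked = [
        (region_list[r], float(scores[r])) for r in range(R) if scores[r] > 1.0 / R
    ]
    picked.sort(key=lambda rs: -rs[1])
    return picked


class RegionScoringHead(nn.Module):
    """SPP pooling -> two FC+ReLU layers -> two linear scoring heads."""

    def __init__(
        self,
        d_spp: int,
        embed_dim: int = 4096,
        n_classes: int = 2,
        spp_levels: tuple[int, ...] = (1, 2),
        dropout: float = 0.5,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.d_spp = d_spp
        self.embed_dim = embed_dim
        self.n_classes = n_classes
        self.spp_levels = tuple(spp_levels)
        self.fc1 = nn.Linear(d_spp, embed_dim, rng=rng)
        self.fc2 = nn.Linear(embed_dim, embed_dim, rng=rng)
        self.relu1 = nn.ReLU()
        self.relu2 = nn.ReLU()
        # dropout after each FC embedding layer keeps the detection
        # softmax diffuse early in training, which is what lets region
        # discrimination emerge before the region softmax sharpens
        self.drop1 = nn.Dropout(dropout, rng=np.random.default_rng(rng.integers(2**31)))
        self.drop2 = nn.Dropout(dropout, rng=np.random.default_rng(rng.integers(2**31)))
        self.head_class = nn.Linear(embed_dim, n_classes, rng=rng)
        self.head_det = nn.Linear(embed_dim, n_classes, rng=rng)
        self._cache: dict | None = None

    # -- region feature extraction -----------------------------------
    def pool_regions(
        self, feature_map: np.ndarray, regions: RegionSet | list, gm: GridMapping
    ) -> tuple[np.ndarray, list]:
        pooled, caches = [], []
        for box in regions:
            cells = map_box_to_grid(box, gm)
            vec, cache = _spp_pool_cached(feature_map, cells, self.spp_levels)
            pooled.append(vec)
            caches.append(cache)
        return np.stack(pooled).astype(np.float32), caches

    def embed(self, pooled: np.ndarray, training: bool = False) -> np.ndarray:
        """(R, d_spp) pooled vectors -> nonnegative (R, embed_dim) features."""
        h = self.relu1.forward(self.fc1.forward(pooled, training), training)
        h = self.drop1.forward(h, training)
        return self.relu2.forward(self.fc2.forward(h, training), training)

    def forward(
        self,
        feature_map: np.ndarray,
        regions: RegionSet | list,
        gm: GridMapping,
        training: bool = False,
    ) -> dict:
        pooled, spp_cache = self.pool_regions(feature_map, regions, gm)
        emb = self.embed(pooled, training)
        emb_heads = self.drop2.forward(emb, training)
        xc = self.head_class.forward(emb_heads, training).T  # (C, R)
        xd = self.head_det.forward(emb_heads, training).T
        sigma_class = softmax_over_classes(xc)
        sigma_det = softmax_over_regions(xd)
        y = image_score(sigma_class, sigma_det)
        out = {
            "pooled": pooled,
            "emb": emb,
            "x_class": xc,
            "x_det": xd,
            "sigma_class": sigma_class,
            "sigma_det": sigma_det,
            "y": y,
        }
        self._cache = {"spp": spp_cache, "fmap_shape": feature_map.shape, "out": out}
        return out

    def backward_from_y(self, dy: np.ndarray) -> np.ndarray:
        """Backprop d(loss)/dy through both streams; returns d(feature_map).

        Must be called directly after ``forward`` for the same image
        (layer caches are per-call).
        """
        cache = self._cache
        if cache is None:
            raise RuntimeError("backward_from_y called before forward")
        out = cache["out"]
        sc, sd = out["sigma_class"], out["sigma_det"]
        dsc = dy[:, None] * sd
        dsd = dy[:, None] * sc
        # softmax Jacobians: over classes (axis 0) and over regions (axis 1)
        dxc = sc * (dsc - (dsc * sc).sum(axis=0, keepdims=True))
        dxd = sd * (dsd - (dsd * sd).sum(axis=1, keepdims=True))
        demb = self.drop2.backward(
            self.head_class.backward(dxc.T) + self.head_det.backward(dxd.T)
        )
        dh = self.drop1.backward(self.fc2.backward(self.relu2.backward(demb)))
        dpooled = self.fc1.backward(self.relu1.backward(dh))
        dfmap = np.zeros(cache["fmap_shape"], dtype=np.float32)
        for r, spp_cache in enumerate(cache["spp"]):
            _spp_backward(dpooled[r], spp_cache, cache["fmap_shape"], dfmap)
        self._cache = None
        return dfmap


class ToothMarkNet:
    """Backbone + region scoring head, with checkpoint (de)serialisation."""

    def __init__(
        self,
        arch: str = "tiny_test",
        feature_channels_override: int | None = None,
        embed_dim: int = 4096,
        n_classes: int = 2,
        spp_levels: tuple[int, ...] = (1, 2),
        input_size: int = 224,
        seed: int = 0,
        dropout: float = 0.5,
        backbone_weights: dict[str, np.ndarray] | None = None,
    ) -> None:
        rng = np.random.default_rng(seed)
        self.arch = arch
        self.input_size = input_size
        cf = feature_channels(arch, feature_channels_override)
        self.grid_mapping = GridMapping(input_size, BACKBONE_STRIDE, cf)
        self.backbone = build_backbone(arch, backbone_weights, rng=rng, channels=cf)
        d_spp = sum(n * n for n in spp_levels) * cf
        self.head = RegionScoringHead(d_spp, embed_dim, n_classes, spp_levels, dropout=dropout, rng=rng)
        self.n_classes = n_classes
        self.embed_dim = embed_dim
        self.spp_levels = tuple(spp_levels)

    # -- parameter plumbing ------------------------------------------
    def parameters(self) -> list[nn.Param]:
        return self.backbone.parameters() + self.head.parameters()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def named_state(self) -> dict[str, np.ndarray]:
        state = self.backbone.named_state("backbone.")
        state.update(self.head.named_state("head."))
        return state

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.backbone.load_state(state, "backbone.")
        self.head.load_state(state, "head.")

    # -- forward / training ------------------------------------------
    @staticmethod
    def to_batch(images: list[np.ndarray] | np.ndarray) -> np.ndarray:
        """uint8 HWC images -> float32 (B, 3, H, W) in [0, 1]."""
        arr = np.stack([np.asarray(im) for im in images])
        return np.ascontiguousarray(arr.transpose(0, 3, 1, 2), dtype=np.float32) / 255.0

    def forward(
        self,
        images: np.ndarray,
        regions_list: list[RegionSet | list],
        training: bool = False,
    ) -> list[dict]:
        """Per-image score dictionaries for a batch of equal-size images."""
        fmaps = self.backbone.forward(images, training)
        outputs = []
        for b, regions in enumerate(regions_list):
            outputs.append(self.head.forward(fmaps[b], regions, self.grid_mapping, training))
        return outputs

    def train_batch(
        self,
        images: np.ndarray,
        regions_list: list,
        labels: np.ndarray,
    ) -> float:
        """Accumulate gradients of the mean image loss; returns the loss."""
        fmaps = self.backbone.forward(images, training=True)
        B = len(regions_list)
        dfmaps = np.zeros_like(fmaps)
        total = 0.0
        for b, regions in enumerate(regions_list):
            out = self.head.forward(fmaps[b], regions, self.grid_mapping, training=True)
            y = out["y"]
            total += bce_loss(y, int(labels[b]))
            yc = np.clip(np.asarray(y, dtype=np.float64), 1e-7, 1.0 - 1e-7)
            t = np.zeros_like(yc)
            t[int(labels[b])] = 1.0
            dy = ((-t / yc + (1.0 - t) / (1.0 - yc)) / B).astype(np.float32)
            dfmaps[b] = self.head.backward_from_y(dy)
        self.backbone.backward(dfmaps)
        return total / B

    # -- persistence --------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Single ``.npz`` weight file plus a JSON sidecar with the config."""
        path = Path(path)
        np.savez(path, **self.named_state())
        sidecar = {
            "arch": self.arch,
            "input_size": self.input_size,
            "grid": self.grid_mapping.grid,
            "stride": self.grid_mapping.stride,
            "feature_channels": self.grid_mapping.feature_channels,
            "spp_levels": list(self.spp_levels),
            "embed_dim": self.embed_dim,
            "n_classes": self.n_classes,
            "dropout": self.head.drop1.p,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ToothMarkNet":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        net = cls(
            arch=sidecar["arch"],
            feature_channels_override=sidecar["feature_channels"],
            embed_dim=sidecar["embed_dim"],
            n_classes=sidecar["n_classes"],
            spp_levels=tuple(sidecar["spp_levels"]),
            input_size=sidecar["input_size"],
            dropout=sidecar.get("dropout", 0.5),
        )
        with np.load(path) as data:
            net.load_state({k: data[k] for k in data.files})
        return net
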