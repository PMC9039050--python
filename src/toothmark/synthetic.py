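"""Synthetic tongue-image generator with planted, ground-truthed tooth marks.

No public clinical tooth-mark dataset exists, so every experiment in
this package runs on synthetic tongues: an elliptical pink foreground on
an exactly-zero background, with optional planted marks on the lateral
boundary.  A mark mimics the two clinical signs of a tooth imprint —
a serrated indentation of the contour (a semicircular notch carved out
of the mask) and/or a darker compressed patch just inside the boundary.
Every planted mark records a tight ground-truth bounding box, which the
clinical data never has; this is what makes localization quantitatively
scorable here.

Marks are placed only on the lateral arcs (polar angle within 60 degrees
of horizontal), matching where tooth marks occur anatomically and
keeping them clear of the tongue tip/base regions that the region
proposer trims away.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .preprocess import TongueSample

__all__ = [
    "SyntheticParams",
    "generate_tongue",
    "generate_samples",
    "generate_dataset",
    "generate_generic_shapes",
]


@dataclass
class SyntheticParams:
    """Ranges controlling the synthetic tongue generator.

    Axis ranges are fractions of ``image_size``; colors are inclusive
    8-bit ranges.  ``n_marks`` is the inclusive range drawn for positive
    samples (negatives always get zero marks).  ``color_shift`` is the
    RGB delta applied to the compressed patch; ``noise_sigma`` the
    additive Gaussian pixel noise (foreground only, so the background
    stays exactly zero).
    """

    image_size: int = 224
    tongue_axes: tuple[tuple[float, float], tuple[float, float]] = (
        (0.26, 0.34),
        (0.34, 0.42),
    )
    base_color: tuple[tuple[int, int], ...] = ((185, 215), (110, 140), (115, 145))
    n_marks: tuple[int, int] = (1, 6)
    mark_radius: tuple[int, int] = (8, 20)
    mark_type: str = "both"  # indentation | color_patch | both
    color_shift: tuple[int, int, int] = (-70, -45, -45)
    noise_sigma: float = 4.0
    max_lateral_angle_deg: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mark_type not in ("indentation", "color_patch", "both"):
            raise ValueError(f"unknown mark_type {self.mark_type!r}")
        if self.n_marks[0] < 0 or self.n_marks[1] < self.n_marks[0]:
            raise ValueError("n_marks range must be nonnegative and ordered")


def _ellipse_mask(size: int, cx: float, cy: float, ax: float, ay: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return (((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0).astype(np.uint8)


def _tight_box(changed: np.ndarray) -> tuple[int, int, int, int] | None:
    ys, xs = np.nonzero(changed)
    if ys.size == 0:
        return None
    return (int(xs.min()), int(ys.min()), int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1))


def generate_tongue(
    params: SyntheticParams,
    rng: np.random.Generator | int,
    n_marks: int | None = None,
) -> TongueSample:
    """Generate one synthetic tongue sample (in-memory image and mask).

    ``n_marks`` overrides the sampled mark count (0 for a negative).
    Deterministic given the generator state.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    size = params.image_size
    (ax_lo, ax_hi), (ay_lo, ay_hi) = params.tongue_axes
    ax = float(rng.uniform(ax_lo, ax_hi)) * size
    ay = float(rng.uniform(ay_lo, ay_hi)) * size
    cx = size / 2 + float(rng.uniform(-0.02, 0.02)) * size
    cy = size / 2 + float(rng.uniform(-0.02, 0.02)) * size
    if n_marks is None:
        n_marks = int(rng.integers(params.n_marks[0], params.n_marks[1] + 1))
    r_lo, r_hi = params.mark_radius
    if r_hi >= min(ax, ay):
        raise ValueError("mark_radius must be smaller than the tongue semi-axes")

    mask = _ellipse_mask(size, cx, cy, ax, ay)
    color = np.array(
        [rng.integers(lo, hi + 1) for lo, hi in params.base_color], dtype=np.float64
    )
    image = np.zeros((size, size, 3), dtype=np.float64)
    image[mask > 0] = color

    # lateral placement angles, alternating sides, spaced to avoid merging
    max_a = math.radians(params.max_lateral_angle_deg)
    truth_boxes: list[tuple[int, int, int, int]] = []
    used: dict[str, list[float]] = {"left": [], "right": []}
    for _ in range(n_marks):
        side = "left" if rng.random() < 0.5 else "right"
        for _attempt in range(40):
            theta = float(rng.uniform(-max_a, max_a))
            if all(abs(theta - t) > 0.38 for t in used[side]):
                break
        else:
            side = "right" if side == "left" else "left"
            theta = float(rng.uniform(-max_a, max_a))
            if not all(abs(theta - t) > 0.38 for t in used[side]):
                continue
        used[side].append(theta)
        phi = math.pi - theta if side == "left" else theta
        px = cx + ax * math.cos(phi)
        py = cy + ay * math.sin(phi)
        # outward normal of the ellipse at (px, py)
        nx, ny = math.cos(phi) / ax, math.sin(phi) / ay
        norm = math.hypot(nx, ny)
        nx, ny = nx / norm, ny / norm
        r = float(rng.uniform(r_lo, r_hi))
        yy, xx = np.mgrid[0:size, 0:size]
        changed = np.zeros((size, size), dtype=bool)
        if params.mark_type in ("indentation", "both"):
            qx, qy = px + 0.4 * r * nx, py + 0.4 * r * ny
            carve = (xx - qx) ** 2 + (yy - qy) ** 2 < r * r
            changed |= carve & (mask > 0)
            mask[carve] = 0
            image[carve] = 0.0
        if params.mark_type in ("color_patch", "both"):
            qx, qy = px - 0.7 * r * nx, py - 0.7 * r * ny
            patch = ((xx - qx) ** 2 + (yy - qy) ** 2 < (0.9 * r) ** 2) & (mask > 0)
            image[patch] += np.asarray(params.color_shift, dtype=np.float64)
            changed |= patch
        box = _tight_box(changed)
        if box is not None:
            truth_boxes.append(box)

    if params.noise_sigma > 0:
        noise = rng.normal(0.0, params.noise_sigma, size=image.shape)
        image[mask > 0] += noise[mask > 0]
    image = np.clip(image, 0, 255)
    # foreground must stay nonzero for the edge scan; lift any zero pixel
    fg = mask > 0
    image[fg] = np.maximum(image[fg], 1.0)
    image[~fg] = 0.0
    label = 1 if truth_boxes else 0
    if n_marks > 0 and not truth_boxes:
        # extremely unlikely fallback: re-draw with a fresh substream
        return generate_tongue(params, np.random.default_rng(rng.integers(2**31)), n_marks)
    return TongueSample(
        label=label,
        truth_boxes=truth_boxes or None,
        image=image.astype(np.uint8),
        mask=mask,
    )


def generate_samples(
    n_pos: int, n_neg: int, params: SyntheticParams | None = None, seed: int = 0
) -> list[TongueSample]:
    """In-memory dataset: ``n_pos`` tooth-marked then ``n_neg`` plain tongues."""
    params = params or SyntheticParams()
    rng = np.random.default_rng(seed)
    samples = [generate_tongue(params, rng) for _ in range(n_pos)]
    samples += [generate_tongue(params, rng, n_marks=0) for _ in range(n_neg)]
    return samples


def generate_dataset(
    n_pos: int,
    n_neg: int,
    params: SyntheticParams | None = None,
    seed: int = 0,
    outdir: str | Path = ".",
) -> Path:
    """Write a synthetic dataset to disk and return the manifest path.

    Layout: ``images/*.png``, ``masks/*.png``, ``truth/*.json`` (positives
    only) and ``manifest.csv`` with columns ``image,mask,label,boxes``.
    """
    outdir = Path(outdir)
    for sub in ("images", "masks", "truth"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    samples = generate_samples(n_pos, n_neg, params, seed)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "mask", "label", "boxes"])
        for i, s in enumerate(samples):
            stem = f"sample_{i:04d}"
            Image.fromarray(s.image).save(outdir / "images" / f"{stem}.png")
            Image.fromarray(s.mask * 255).save(outdir / "masks" / f"{stem}.png")
            boxes_rel = ""
            if s.truth_boxes:
                boxes_rel = f"truth/{stem}.json"
                with open(outdir / boxes_rel, "w") as bf:
                    json.dump(
                        [{"x": x, "y": y, "w": w, "h": h} for x, y, w, h in s.truth_boxes],
                        bf,
                    )
            writer.writerow([f"images/{stem}.png", f"masks/{stem}.png", s.label, boxes_rel])
    return manifest


def generate_generic_shapes(
    n: int, seed: int = 0, image_size: int = 224
) -> list[TongueSample]:
    """Generic two-class shape images (disks vs squares) on black.

    Stands in for a large generic-image corpus when producing
    "generic-image" backbone initial weights, so no external download is
    ever needed.  Label 0 = disk, 1 = square.
    """
    rng = np.random.default_rng(seed)
    samples = []
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    for i in range(n):
        label = i % 2
        img = np.zeros((image_size, image_size, 3), dtype=np.float64)
        color = rng.integers(60, 256, size=3).astype(np.float64)
        cx, cy = rng.uniform(0.3, 0.7, size=2) * image_size
        half = rng.uniform(0.12, 0.3) * image_size
        if label == 0:
            region = (xx - cx) ** 2 + (yy - cy) ** 2 <= half * half
        else:
            region = (np.abs(xx - cx) <= half) & (np.abs(yy - cy) <= half)
        img[region] = color
        img[region] += rng.normal(0, 5, size=img.shape)[region]
        samples.append(
            TongueSample(
                label=label,
                image=np.clip(img, 0, 255).astype(np.uint8),
                mask=np.ones((image_size, image_size), dtype=np.uint8),
            )
        )
    return samples
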