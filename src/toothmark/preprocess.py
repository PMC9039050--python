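"""Image, mask and manifest I/O plus the masking/resizing/augmentation step.

Tongue photographs arrive as RGB images with a tongue-region delineation
(either a binary mask image or a Labelme-style polygon JSON).  The
preprocessing contract is: AND the image with the mask so everything
outside the tongue is exactly zero, resize to the fixed network input
size (224 by default, bilinear, aspect ratio not preserved), and at
training time apply random horizontal/vertical flips and a random
rotation of 0-15 degrees.

Conventions used throughout the package: coordinates are 0-based with
``x`` the column and ``y`` the row; boxes are half-open
``[x_min, x_min + w) x [y_min, y_min + h)``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

__all__ = [
    "PreprocessConfig",
    "TongueSample",
    "load_image",
    "load_mask",
    "rasterize_polygons",
    "apply_mask",
    "resize_to_input",
    "augment",
    "augment_pair",
    "load_manifest",
    "prepare_input",
]


@dataclass
class PreprocessConfig:
    """Geometry and augmentation settings for network inputs.

    ``input_size`` must stay divisible by the backbone stride (32).
    """

    input_size: int = 224
    rotation_max_deg: float = 15.0
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    augment_seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size <= 0 or self.input_size % 32:
            raise ValueError("input_size must be a positive multiple of the backbone stride (32)")
        if self.rotation_max_deg < 0:
            raise ValueError("rotation_max_deg must be >= 0")
        for p in (self.hflip_prob, self.vflip_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("flip probabilities must lie in [0, 1]")


@dataclass
class TongueSample:
    """One tongue photograph with its mask and image-level label.

    ``label`` is 0 for non-tooth-marked, 1 for tooth-marked.  Synthetic
    samples may carry ground-truth ``truth_boxes`` (list of
    ``(x_min, y_min, w, h)`` tuples) and in-memory ``image``/``mask``
    arrays that take precedence over the paths.
    """

    image_path: str | Path | None = None
    mask_path: str | Path | None = None
    label: int = 0
    truth_boxes: list[tuple[int, int, int, int]] | None = None
    image: np.ndarray | None = field(default=None, repr=False)
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")

    def load(self) -> "TongueSample":
        """Return a copy with image and mask materialised as arrays."""
        image = self.image if self.image is not None else load_image(self.image_path)
        mask = self.mask if self.mask is not None else load_mask(self.mask_path, shape=image.shape[:2])
        if mask.shape != image.shape[:2]:
            raise ValueError(
                f"mask shape {mask.shape} does not match image shape {image.shape[:2]}"
            )
        return replace(self, image=image, mask=mask)


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image as an (H, W, 3) uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def rasterize_polygons(
    polygons: list[list[tuple[float, float]]], shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize closed polygons ([x, y] vertices) to a binary (H, W) mask."""
    if not polygons:
        raise ValueError("polygon annotation contains no polygons")
    H, W = shape
    canvas = Image.new("L", (W, H), 0)
    draw = ImageDraw.Draw(canvas)
    for poly in polygons:
        if len(poly) < 3:
            raise ValueError(f"polygon needs >= 3 vertices, got {len(poly)}")
        draw.polygon([(float(x), float(y)) for x, y in poly], fill=1)
    return np.asarray(canvas, dtype=np.uint8)


def load_mask(path: str | Path, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Load a binary tongue mask from a PNG or a Labelme-style JSON file.

    Raster masks are thresholded at zero (any value > 0 is foreground) so
    both 1-bit and 8-bit mask files work.  JSON files must carry
    ``shapes[].points`` vertex lists; ``imageHeight``/``imageWidth`` fix
    the canvas unless ``shape`` is given.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            ann = json.load(fh)
        polygons = [s["points"] for s in ann.get("shapes", [])]
        if shape is None:
            try:
                shape = (int(ann["imageHeight"]), int(ann["imageWidth"]))
            except KeyError as exc:
                raise ValueError(
                    f"{path}: polygon annotation lacks imageHeight/imageWidth and no shape given"
                ) from exc
        return rasterize_polygons(polygons, shape)
    with Image.open(path) as im:
        raster = np.asarray(im.convert("L"))
    return (raster > 0).astype(np.uint8)


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """AND the image with the mask: background becomes exactly (0, 0, 0)."""
    if image.shape[:2] != mask.shape:
        raise ValueError(f"image {image.shape[:2]} and mask {mask.shape} shapes disagree")
    return image * (mask > 0).astype(image.dtype)[..., None]


def resize_to_input(
    image: np.ndarray, cfg: PreprocessConfig | int = 224, is_mask: bool = False
) -> np.ndarray:
    """Resize to ``input_size`` x ``input_size`` (bilinear; nearest for masks)."""
    size = cfg.input_size if isinstance(cfg, PreprocessConfig) else int(cfg)
    if image.size == 0 or image.shape[0] == 0 or image.shape[1] == 0:
        raise ValueError("cannot resize a zero-area image")
    if image.shape[0] == size and image.shape[1] == size:
        return image
    resample = Image.NEAREST if is_mask else Image.BILINEAR
    out = np.asarray(Image.fromarray(image).resize((size, size), resample))
    return out


def _draw_augment(cfg: PreprocessConfig, rng: np.random.Generator):
    hflip = rng.random() < cfg.hflip_prob
    vflip = rng.random() < cfg.vflip_prob
    angle = float(rng.uniform(0.0, cfg.rotation_max_deg)) if cfg.rotation_max_deg > 0 else 0.0
    return hflip, vflip, angle


def _apply_geometry(
    image: np.ndarray, hflip: bool, vflip: bool, angle: float, is_mask: bool
) -> np.ndarray:
    out = image
    if hflip:
        out = out[:, ::-1]
    if vflip:
        out = out[::-1, :]
    if angle != 0.0:
        resample = Image.NEAREST if is_mask else Image.BILINEAR
        out = np.asarray(Image.fromarray(np.ascontiguousarray(out)).rotate(angle, resample=resample, fillcolor=0))
    return np.ascontiguousarray(out)


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    cfg: PreprocessConfig,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, np.ndarray]:
    """Jointly augment an image and its mask; re-AND so background stays zero.

    Deterministic given the generator state: the same state yields
    bit-identical outputs.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    hflip, vflip, angle = _draw_augment(cfg, rng)
    img = _apply_geometry(image, hflip, vflip, angle, is_mask=False)
    msk = _apply_geometry(mask, hflip, vflip, angle, is_mask=True)
    return apply_mask(img, msk), msk


def augment(
    image: np.ndarray, cfg: PreprocessConfig, rng: np.random.Generator | int
) -> np.ndarray:
    """Random hflip/vflip plus a rotation by an angle in [0, rotation_max_deg].

    Exposed corners after rotation are filled with black, consistent with
    the zero background the region-proposal scan assumes.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    hflip, vflip, angle = _draw_augment(cfg, rng)
    return _apply_geometry(image, hflip, vflip, angle, is_mask=False)


def load_manifest(path: str | Path) -> list[TongueSample]:
    """Read a dataset manifest CSV with columns ``image,mask,label[,boxes]``.

    Paths are resolved relative to the manifest location.  A ``boxes``
    entry, if present, names a JSON file with a list of
    ``{"x":..,"y":..,"w":..,"h":..}`` ground-truth boxes.
    """
    path = Path(path)
    root = path.parent
    samples: list[TongueSample] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"image", "mask", "label"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = required - set(reader.fieldnames or [])
            raise ValueError(f"{path}: manifest missing column(s) {sorted(missing)}")
        for i, row in enumerate(reader, start=2):  # header is line 1
            raw = (row["label"] or "").strip()
            if raw not in ("0", "1"):
                raise ValueError(f"{path} row {i}: label must be 0 or 1, got {raw!r}")
            boxes = None
            if row.get("boxes"):
                with open(root / row["boxes"]) as bf:
                    boxes = [
                        (int(b["x"]), int(b["y"]), int(b["w"]), int(b["h"]))
                        for b in json.load(bf)
                    ]
            samples.append(
                TongueSample(
                    image_path=root / row["image"],
                    mask_path=root / row["mask"],
                    label=int(raw),
                    truth_boxes=boxes,
                )
            )
    return samples


def prepare_input(
    sample: TongueSample, cfg: PreprocessConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Masked, resized network input and its resized mask for one sample."""
    cfg = cfg or PreprocessConfig()
    loaded = sample.load()
    masked = apply_mask(loaded.image, loaded.mask)
    image = resize_to_input(masked, cfg)
    mask = resize_to_input(loaded.mask, cfg, is_mask=True)
    return apply_mask(image, mask), mask
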