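"""Spatial region proposal: equidistant candidate boxes on the tongue edges.

Tooth marks sit on the lateral contours of the tongue, so candidate
regions are anchored there directly instead of running a generic
object-proposal method.  On the masked grayscale image (background is
exactly zero), rows are visited at a fixed vertical interval starting
from the first foreground row; within each visited row the first
nonzero pixel scanning inward from the left (resp. right) edge is taken
as the midpoint of a square candidate box.  The first and last box on
each side are dropped, as they fall on the tongue tip/base which carry
no tooth-mark information.

Only position information is used — proposals depend on the nonzero
support of the image, not on color.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SRPParams",
    "CandidateRegion",
    "RegionSet",
    "DegenerateMaskError",
    "to_grayscale",
    "scan_side",
    "midpoint_to_box",
    "propose_regions",
]


class DegenerateMaskError(ValueError):
    """Raised when a mask yields no candidate regions after trimming."""


@dataclass
class SRPParams:
    """Geometry of the edge scan.

    ``box_size`` is the nominal square box side in pixels; the vertical
    step between scanned rows is ``floor(step_fraction * box_size)``
    (21 px for the 32-px default).  ``trim_count`` boxes are removed
    from each end of each side.  ``scan_limit`` bounds the inward
    horizontal scan and defaults to half the image width.
    """

    box_size: int = 32
    step_fraction: float = 2.0 / 3.0
    trim_count: int = 1
    scan_limit: int | None = None

    def __post_init__(self) -> None:
        if self.box_size < 1:
            raise ValueError("box_size must be >= 1")
        if not 0.0 < self.step_fraction <= 1.0:
            raise ValueError("step_fraction must lie in (0, 1]")
        if self.trim_count < 0:
            raise ValueError("trim_count must be >= 0")
        if self.step < 1:
            raise ValueError("effective step floor(step_fraction * box_size) must be >= 1")

    @property
    def step(self) -> int:
        return int(math.floor(self.step_fraction * self.box_size))

    def limit(self, width: int) -> int:
        return width // 2 if self.scan_limit is None else int(self.scan_limit)


@dataclass(frozen=True)
class CandidateRegion:
    """Axis-aligned candidate box, half-open pixel coordinates."""

    x_min: int
    y_min: int
    w: int
    h: int
    side: str | None = None
    index: int | None = None

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ValueError("candidate box must have w, h >= 1")
        if self.x_min < 0 or self.y_min < 0:
            raise ValueError("candidate box must have nonnegative origin")

    @property
    def bounds(self) -> tuple[int, int, int, int]:
        """(x_min, y_min, x_max, y_max) with half-open maxima."""
        return (self.x_min, self.y_min, self.x_min + self.w, self.y_min + self.h)


@dataclass
class RegionSet:
    """Ordered candidate regions (left side in scan order, then right)."""

    regions: list[CandidateRegion] = field(default_factory=list)

    @property
    def R(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luma grayscale (Rec. 601 weights); zero pixels stay exactly zero."""
    if image.ndim == 2:
        return image
    w = np.array([0.299, 0.587, 0.114], dtype=np.float64)
    gray = image.astype(np.float64) @ w
    if image.dtype == np.uint8:
        return np.rint(gray).astype(np.uint8)
    return gray.astype(np.float32)


def scan_side(gray: np.ndarray, side: str, params: SRPParams) -> list[tuple[int, int]]:
    """Midpoints of candidate boxes along one lateral contour.

    Starting at the first row containing any foreground, every
    ``params.step``-th row is visited; the first nonzero pixel scanning
    inward (left edge -> middle for ``side="left"``, right edge ->
    middle for ``side="right"``) gives a midpoint.  Rows with no
    foreground within the scan range are skipped.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    H, W = gray.shape[:2]
    nonzero_rows = np.flatnonzero((gray != 0).any(axis=1))
    if nonzero_rows.size == 0:
        return []
    limit = params.limit(W)
    midpoints: list[tuple[int, int]] = []
    for y in range(int(nonzero_rows[0]), H, params.step):
        if side == "left":
            strip = gray[y, :limit]
            hits = np.flatnonzero(strip)
            if hits.size:
                midpoints.append((int(hits[0]), y))
        else:
            strip = gray[y, W - limit :]
            hits = np.flatnonzero(strip)
            if hits.size:
                midpoints.append((int(W - limit + hits[-1]), y))
    return midpoints


def midpoint_to_box(
    midpoint: tuple[int, int], params: SRPParams, bounds: tuple[int, int], side: str = "left"
) -> CandidateRegion:
    """Square box of side ``box_size`` centered on the midpoint, clipped.

    The nominal box is ``[x - off, x - off + s)`` with ``off = floor(s/2)``
    on the left side and the mirror-complement ``s - 1 - floor(s/2)`` on
    the right side, so that horizontally flipping the mask mirrors the
    region set exactly (for odd ``s`` the two offsets coincide).
    Clipping shrinks the box at the image border rather than shifting
    it, so the anchoring contour pixel always stays inside the box.
    """
    W, H = bounds
    x, y = midpoint
    s = params.box_size
    half = s // 2 if side == "left" else s - 1 - s // 2
    x0, y0 = x - half, y - s // 2
    x1, y1 = x0 + s, y0 + s
    cx0, cy0 = max(0, x0), max(0, y0)
    cx1, cy1 = min(W, x1), min(H, y1)
    return CandidateRegion(cx0, cy0, cx1 - cx0, cy1 - cy0)


def propose_regions(
    masked_image: np.ndarray, params: SRPParams | None = None
) -> RegionSet:
    """Generate the candidate region set for one masked tongue image.

    Accepts the masked RGB image, a grayscale image or a binary mask —
    only the nonzero support matters.  Left-side boxes come first (top
    to bottom), then right-side boxes; ``trim_count`` boxes are dropped
    from each end of each side.  Raises :class:`DegenerateMaskError`
    when nothing survives trimming.
    """
    params = params or SRPParams()
    gray = to_grayscale(masked_image)
    H, W = gray.shape[:2]
    regions: list[CandidateRegion] = []
    for side in ("left", "right"):
        mids = scan_side(gray, side, params)
        if params.trim_count:
            mids = mids[params.trim_count : len(mids) - params.trim_count]
        for i, mid in enumerate(mids):
            box = midpoint_to_box(mid, params, (W, H), side=side)
            regions.append(
                CandidateRegion(box.x_min, box.y_min, box.w, box.h, side=side, index=i)
            )
    if not regions:
        raise DegenerateMaskError(
            "no candidate regions survive trimming: the foreground is too small "
            "for the configured box size / step / trim_count"
        )
    return RegionSet(regions)
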