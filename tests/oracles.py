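"""Independent brute-force oracles shared by the test modules.

These deliberately re-derive results with plain loops and closed forms,
independent of the library code paths they are used to check.
"""

import math

import numpy as np


def oracle_image_score(x_class: np.ndarray, x_det: np.ndarray) -> np.ndarray:
    """Double-loop exp-normalisation oracle for the two-stream image score."""
    C, R = x_class.shape
    y = np.zeros(C)
    for c in range(C):
        for r in range(R):
            sc = math.exp(x_class[c, r]) / sum(math.exp(x_class[k, r]) for k in range(C))
            sd = math.exp(x_det[c, r]) / sum(math.exp(x_det[c, k]) for k in range(R))
            y[c] += sc * sd
    return y


def brute_force_proposals(gray: np.ndarray, params):
    """Dense-scan reimplementation of the edge-anchored region proposer.

    Scans every row with plain Python loops, subsamples rows at the
    step, builds boxes midpoint-by-midpoint, trims each side, and
    returns (x_min, y_min, w, h, side) tuples in left-then-right order.
    """
    H, W = gray.shape[:2]
    limit = W // 2 if params.scan_limit is None else params.scan_limit
    first_row = None
    for y in range(H):
        if any(gray[y, x] != 0 for x in range(W)):
            first_row = y
            break
    if first_row is None:
        return []
    out = []
    for side in ("left", "right"):
        mids = []
        y = first_row
        while y < H:
            xs = range(0, limit) if side == "left" else range(W - 1, W - limit - 1, -1)
            for x in xs:
                if gray[y, x] != 0:
                    mids.append((x, y))
                    break
            y += params.step
        mids = mids[params.trim_count : len(mids) - params.trim_count or None]
        off = (
            params.box_size // 2
            if side == "left"
            else params.box_size - 1 - params.box_size // 2
        )
        for x, y in mids:
            x0, y0 = x - off, y - params.box_size // 2
            x1, y1 = x0 + params.box_size, y0 + params.box_size
            cx0, cy0, cx1, cy1 = max(0, x0), max(0, y0), min(W, x1), min(H, y1)
            out.append((cx0, cy0, cx1 - cx0, cy1 - cy0, side))
    return out
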