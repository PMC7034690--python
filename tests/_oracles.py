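"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the ranklet oracle
counts pixel pairs directly instead of summing ranks; the GLCM oracle
enumerates every pixel and offset; the run oracle scans lines extracted with
plain numpy slicing.
"""

from __future__ import annotations

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def ranklet_pair_count(block: np.ndarray, y_mask: np.ndarray) -> float:
    """R via direct O(C^2/4) pair counting: pairs (y > x), ties as 1/2."""
    ys = block[y_mask].astype(float)
    xs = block[~y_mask].astype(float)
    u = 0.0
    for y in ys:
        for x in xs:
            if y > x:
                u += 1.0
            elif y == x:
                u += 0.5
    c = block.size
    return u / (c * c / 8.0) - 1.0


def glcm_enumerate(
    img: np.ndarray,
    mask: np.ndarray,
    d: int,
    theta: int,
    levels: int,
    symmetric: bool,
) -> np.ndarray:
    """Normalized co-occurrence probabilities by per-pixel enumeration."""
    dr, dc = OFFSETS[theta][0] * d, OFFSETS[theta][1] * d
    h, w = img.shape
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[img[r, c], img[r2, c2]] += 1
                if symmetric:
                    counts[img[r2, c2], img[r, c]] += 1
    total = counts.sum()
    return counts / total if total else counts


def _lines(img: np.ndarray, mask: np.ndarray, theta: int):
    """Scan lines of (values, mask) per direction, via numpy slicing only."""
    h, w = img.shape
    if theta == 0:
        for r in range(h):
            yield img[r], mask[r]
    elif theta == 90:
        for c in range(w):
            yield img[:, c], mask[:, c]
    elif theta == 45:
        flipped_img, flipped_mask = img[::-1], mask[::-1]
        for k in range(-(h - 1), w):
            yield np.diagonal(flipped_img, k), np.diagonal(flipped_mask, k)
    elif theta == 135:
        a, m = img[::-1, ::-1], mask[::-1, ::-1]
        for k in range(-(h - 1), w):
            yield np.diagonal(a, k), np.diagonal(m, k)


def run_length_enumerate(
    img: np.ndarray, mask: np.ndarray, theta: int, levels: int
) -> np.ndarray:
    """Run-length counts r(g, l) by scanning each line pixel-by-pixel."""
    l_max = max(img.shape)
    counts = np.zeros((levels, l_max))
    for vals, msk in _lines(img, mask, theta):
        prev = None
        length = 0
        for v, m in zip(vals, msk):
            if not m:
                if length:
                    counts[prev, length - 1] += 1
                prev, length = None, 0
            elif v == prev:
                length += 1
            else:
                if length:
                    counts[prev, length - 1] += 1
                prev, length = v, 1
        if length:
            counts[prev, length - 1] += 1
    return counts
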