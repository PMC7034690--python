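"""Ranklet transform: orientation-selective, rank-based texture coefficients.

The image is tiled into square blocks (side ``resolution``, C = resolution**2
pixels).  Each block is split into two equal pixel subsets X and Y along a
Haar-style pattern — vertical (left | right), horizontal (top | bottom) or
diagonal (quadrant checker) — and scored by the normalized Wilcoxon rank-sum
statistic

    R = U / (C**2 / 8) - 1,      U = sum of Y ranks - (C/2)(C/2 + 1)/2,

where ranks are mid-ranks over all C pixels.  U counts the pixel pairs
(y in Y, x in X) with y > x, ties counting 1/2, so R lies in [-1, 1]: +1 when
every Y pixel exceeds every X pixel, -1 in the opposite case, 0 for a flat
(all-tie) block.  Because only ranks enter, the coefficients are exactly
invariant under any strictly increasing intensity map that introduces no new
ties — the property that makes the downstream texture features robust to
cross-scanner brightness/contrast/gamma differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.stats import rankdata

from .core import GrayImage, RoiMask, check_congruent
from .errors import GeometryError, ParameterError, TooSmallRoiError

ORIENTATIONS = ("vertical", "horizontal", "diagonal")


@dataclass
class RankletImage:
    """Per-orientation coefficient grid with its valid-block mask.

    ``mask`` is true for blocks whose source pixels all lie inside the ROI;
    only those cells feed downstream feature extraction.
    """

    coefficients: np.ndarray
    orientation: str
    resolution: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ParameterError(f"unknown orientation {self.orientation!r}")
        if self.coefficients.shape != self.mask.shape:
            raise GeometryError("coefficient grid and mask shapes differ")


def split_block(side: int, orientation: str) -> np.ndarray:
    """Boolean side x side grid marking the Y subset of the split.

    vertical: Y = right half-columns; horizontal: Y = bottom half-rows;
    diagonal: Y = top-left and bottom-right quadrants.  The complement is X.
    The convention is frozen: flipping it only negates every coefficient.
    """
    if side < 2 or side % 2:
        raise GeometryError(f"block side must be even and >= 2, got {side}")
    if orientation not in ORIENTATIONS:
        raise ParameterError(f"unknown orientation {orientation!r}")
    half = side // 2
    y = np.zeros((side, side), dtype=bool)
    if orientation == "vertical":
        y[:, half:] = True
    elif orientation == "horizontal":
        y[half:, :] = True
    else:  # diagonal
        y[:half, :half] = True
        y[half:, half:] = True
    return y


def ranklet_coefficient(block: np.ndarray, orientation: str) -> float:
    """Ranklet coefficient of a single square block, in [-1, 1]."""
    block = np.asarray(block)
    if block.ndim != 2 or block.shape[0] != block.shape[1]:
        raise GeometryError(f"block must be square, got shape {block.shape}")
    side = block.shape[0]
    y_mask = split_block(side, orientation)
    c = side * side
    ranks = rankdata(block.ravel(), method="average")
    u = ranks[y_mask.ravel()].sum() - (c // 2) * (c // 2 + 1) / 2.0
    return float(u / (c * c / 8.0) - 1.0)


def _iter_block_origins(
    r0: int, c0: int, height: int, width: int, resolution: int, stride: int
) -> Iterator[tuple[int, int, int, int]]:
    """(grid_row, grid_col, row, col) of each full block in the tiling."""
    gi = 0
    for r in range(r0, height - resolution + 1, stride):
        gj = 0
        for c in range(c0, width - resolution + 1, stride):
            yield gi, gj, r, c
            gj += 1
        gi += 1


def ranklet_transform(
    img: GrayImage,
    mask: RoiMask,
    resolution: int = 4,
    stride: int | None = None,
) -> dict[str, RankletImage]:
    """Transform an image into three orientation coefficient grids.

    Non-overlapping blocks (stride = resolution, the default) are anchored at
    the top-left of the ROI bounding box; trailing partial blocks are
    discarded.  A coefficient cell is marked valid only if every source pixel
    of its block lies inside the ROI.
    """
    check_congruent(img, mask)
    if resolution < 2 or resolution % 2:
        raise GeometryError(f"resolution must be even and >= 2, got {resolution}")
    if stride is None:
        stride = resolution
    if stride < 1:
        raise ParameterError(f"stride must be >= 1, got {stride}")
    r0, c0, r1, c1 = mask.bounding_box()
    if (r1 - r0) < resolution or (c1 - c0) < resolution:
        raise TooSmallRoiError(
            f"ROI bounding box {(r1 - r0)}x{(c1 - c0)} smaller than one "
            f"{resolution}x{resolution} block"
        )
    h, w = img.shape
    n_rows = (h - r0 - resolution) // stride + 1
    n_cols = (w - c0 - resolution) // stride + 1

    pix = img.pixels
    roi = mask.pixels
    c = resolution * resolution
    half_sum = (c // 2) * (c // 2 + 1) / 2.0
    norm = c * c / 8.0

    # Gather all blocks as (n_blocks, C) and rank each row at once.
    blocks = np.empty((n_rows * n_cols, c), dtype=float)
    valid = np.empty(n_rows * n_cols, dtype=bool)
    for gi, gj, r, col in _iter_block_origins(r0, c0, h, w, resolution, stride):
        k = gi * n_cols + gj
        blocks[k] = pix[r : r + resolution, col : col + resolution].ravel()
        valid[k] = roi[r : r + resolution, col : col + resolution].all()
    ranks = rankdata(blocks, method="average", axis=1)

    out: dict[str, RankletImage] = {}
    for orientation in ORIENTATIONS:
        y_flat = split_block(resolution, orientation).ravel()
        u = ranks[:, y_flat].sum(axis=1) - half_sum
        coeff = (u / norm - 1.0).reshape(n_rows, n_cols)
        out[orientation] = RankletImage(
            coefficients=coeff,
            orientation=orientation,
            resolution=resolution,
            mask=valid.reshape(n_rows, n_cols).copy(),
        )
    return out


def export_coefficients(
    transformed: dict[str, RankletImage], path_prefix: str
) -> list[str]:
    """Write each orientation's coefficient grid to ``<prefix>_<orient>.csv``.

    Cells of blocks not fully inside the ROI are written as empty fields.
    Returns the written paths.
    """
    import csv

    paths = []
    for orientation, rimg in transformed.items():
        path = f"{path_prefix}_{orientation}.csv"
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            for row, ok_row in zip(rimg.coefficients, rimg.mask):
                writer.writerow(
                    [repr(float(v)) if ok else "" for v, ok in zip(row, ok_row)]
                )
        paths.append(path)
    return paths


def quantize_coefficients(
    rimg: RankletImage, levels: int = 8
) -> tuple[GrayImage, np.ndarray]:
    """Bin coefficients in [-1, 1] into ``levels`` equal-width gray levels.

    Bins are half-open [lo, hi) except the last, which is closed so that a
    coefficient of exactly +1 lands in bin levels-1.  Returns the quantized
    grid (as a GrayImage with bit_depth = levels-1) and the valid-block mask.
    """
    if levels < 2:
        raise ParameterError(f"levels must be >= 2, got {levels}")
    coeff = rimg.coefficients
    bins = np.floor((coeff + 1.0) / 2.0 * levels).astype(int)
    np.clip(bins, 0, levels - 1, out=bins)
    return GrayImage(bins, bit_depth=levels - 1), rimg.mask.copy()
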