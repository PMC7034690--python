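"""Masked gray-level co-occurrence (GLCM) and run-length (GLRLM) features.

The GLCM p(i,j | d, theta) counts how often quantized levels i and j co-occur
at pixel offset d in direction theta (0, 45, 90, 135 degrees), restricted to
pairs whose *both* endpoints lie inside the ROI mask; symmetric accumulation
(the default) also counts the reversed pair, the standard Haralick practice.
Fourteen scalar features are computed per matrix and averaged over the four
directions.  The GLRLM counts maximal runs of equal level along each
direction, truncated at mask boundaries, and yields the eleven classical
run-length statistics.  All entropies use the natural logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np

from .core import CaseRecord, CaseFeatureRow, FeatureVector, GrayImage
from .errors import (
    DegenerateMatrixError,
    EmptyRoiError,
    ParameterError,
    SchemaError,
)
from . import ranklet as _ranklet
from .io import normalize_intensity

logger = logging.getLogger(__name__)

GLCM_FEATURE_NAMES: tuple[str, ...] = (
    "autocorrelation",
    "contrast",
    "correlation",
    "cluster_prominence",
    "cluster_shade",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "difference_variance",
    "difference_entropy",
    "information_measure_of_correlation",
    "inverse_difference_normalized",
    "inverse_difference_moment",
)

GLRLM_FEATURE_NAMES: tuple[str, ...] = (
    "sre",     # short-run emphasis
    "lre",     # long-run emphasis
    "gln",     # gray-level non-uniformity
    "rln",     # run-length non-uniformity
    "rp",      # run percentage
    "lgre",    # low gray-level run emphasis
    "hgre",    # high gray-level run emphasis
    "srlge",   # short-run low gray-level emphasis
    "srhge",   # short-run high gray-level emphasis
    "lrlge",   # long-run low gray-level emphasis
    "lrhge",   # long-run high gray-level emphasis
)

ANGLES = (0, 45, 90, 135)

# Row/col steps per direction; rows grow downward, so 45 deg points up-right.
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class GLCMatrix:
    """Normalized co-occurrence probability table with its settings."""

    p: np.ndarray
    levels: int
    distance: int
    angle: int
    symmetric: bool

    def __post_init__(self) -> None:
        if self.p.shape != (self.levels, self.levels):
            raise ParameterError(
                f"matrix shape {self.p.shape} != ({self.levels}, {self.levels})"
            )


@dataclass
class GLCMStats:
    """Marginal and difference/sum distributions derived from a GLCM."""

    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    px: np.ndarray
    py: np.ndarray
    p_sum: np.ndarray   # p_{x+y}(k), k = 0 .. 2(G-1)
    p_diff: np.ndarray  # p_{x-y}(k), k = |i-j| = 0 .. G-1
    hx: float
    hy: float
    hxy: float
    hxy1: float


@dataclass
class RunLengthMatrix:
    """Run counts r(g, l): gray level g (0-based bin) by run length l (1-based)."""

    r: np.ndarray
    levels: int
    angle: int
    n_pixels: int  # in-mask pixels, for run percentage


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * ln p with the 0 * ln 0 := 0 convention."""
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def compute_glcm(
    img: GrayImage,
    mask: np.ndarray,
    d: int = 1,
    theta: int = 0,
    levels: int | None = None,
    symmetric: bool = True,
) -> GLCMatrix:
    """Accumulate the masked co-occurrence matrix for one direction.

    A pair is counted iff both endpoints lie inside the mask; no padding or
    reflection at boundaries.
    """
    if theta not in _OFFSETS:
        raise ParameterError(f"theta must be one of {ANGLES}, got {theta}")
    if d < 1:
        raise ParameterError(f"distance must be >= 1, got {d}")
    if levels is None:
        levels = int(img.bit_depth) + 1
    pix = np.asarray(img.pixels)
    if pix.min() < 0 or pix.max() > levels - 1:
        raise ParameterError(
            f"image values [{pix.min()}, {pix.max()}] exceed [0, {levels - 1}]"
        )
    mask = np.asarray(mask) != 0
    if mask.shape != pix.shape:
        raise ParameterError("mask shape differs from image shape")

    dr, dc = (_OFFSETS[theta][0] * d, _OFFSETS[theta][1] * d)
    h, w = pix.shape
    # Valid source window such that (r+dr, c+dc) stays in bounds.
    r_lo, r_hi = max(0, -dr), min(h, h - dr)
    c_lo, c_hi = max(0, -dc), min(w, w - dc)
    counts = np.zeros((levels, levels), dtype=float)
    if r_hi > r_lo and c_hi > c_lo:
        src = pix[r_lo:r_hi, c_lo:c_hi]
        dst = pix[r_lo + dr : r_hi + dr, c_lo + dc : c_hi + dc]
        ok = mask[r_lo:r_hi, c_lo:c_hi] & mask[r_lo + dr : r_hi + dr, c_lo + dc : c_hi + dc]
        np.add.at(counts, (src[ok].astype(int), dst[ok].astype(int)), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise DegenerateMatrixError(
            f"no valid pixel pair inside mask for d={d}, theta={theta}"
        )
    return GLCMatrix(counts / total, levels, d, theta, symmetric)


def glcm_stats(P: GLCMatrix) -> GLCMStats:
    """Marginals, sum/difference distributions and entropy terms of a GLCM."""
    p = P.p
    g = P.levels
    idx = np.arange(g, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(idx @ px)
    mu_y = float(idx @ py)
    sigma_x = float(np.sqrt(((idx - mu_x) ** 2) @ px))
    sigma_y = float(np.sqrt(((idx - mu_y) ** 2) @ py))
    i = idx[:, None]
    j = idx[None, :]
    p_sum = np.zeros(2 * g - 1)
    np.add.at(p_sum, (i + j).astype(int).ravel(), p.ravel())
    p_diff = np.zeros(g)
    np.add.at(p_diff, np.abs(i - j).astype(int).ravel(), p.ravel())
    hx = float(-_xlogx(px).sum())
    hy = float(-_xlogx(py).sum())
    hxy = float(-_xlogx(p).sum())
    # HXY1 = -sum p(i,j) log(px(i) py(j)); cells with p == 0 contribute 0.
    outer = px[:, None] * py[None, :]
    nz = p > 0
    hxy1 = float(-(p[nz] * np.log(outer[nz])).sum())
    return GLCMStats(mu_x, mu_y, sigma_x, sigma_y, px, py, p_sum, p_diff, hx, hy, hxy, hxy1)


def glcm_features(P: GLCMatrix, source: str = "raw") -> FeatureVector:
    """The 14 Haralick-style scalar features of one co-occurrence matrix."""
    p = P.p
    g = P.levels
    s = glcm_stats(P)
    idx = np.arange(g, dtype=float)
    i = idx[:, None]
    j = idx[None, :]
    diff = i - j
    absdiff = np.abs(diff)

    autocorrelation = float((i * j * p).sum())
    contrast = float((diff**2 * p).sum())
    if s.sigma_x * s.sigma_y == 0:
        logger.warning("glcm_features: constant texture, correlation set to 0")
        correlation = 0.0
    else:
        correlation = float(
            ((i * j * p).sum() - s.mu_x * s.mu_y) / (s.sigma_x * s.sigma_y)
        )
    cluster_arg = i + j - s.mu_x - s.mu_y
    cluster_prominence = float((cluster_arg**4 * p).sum())
    cluster_shade = float((cluster_arg**3 * p).sum())
    dissimilarity = float((absdiff * p).sum())
    energy = float((p**2).sum())
    entropy = float(-_xlogx(p).sum())
    homogeneity = float((p / (1.0 + absdiff)).sum())
    k = np.arange(g, dtype=float)
    mu_d = float(k @ s.p_diff)
    difference_variance = float(((k - mu_d) ** 2) @ s.p_diff)
    difference_entropy = float(-_xlogx(s.p_diff).sum())
    h_max = max(s.hx, s.hy)
    imc = 0.0 if h_max == 0 else float((s.hxy - s.hxy1) / h_max)
    idn = float((p / (1.0 + absdiff / g)).sum())
    idm = float((p / (1.0 + diff**2 / g**2)).sum())

    values = (
        autocorrelation, contrast, correlation, cluster_prominence,
        cluster_shade, dissimilarity, energy, entropy, homogeneity,
        difference_variance, difference_entropy, imc, idn, idm,
    )
    return FeatureVector(GLCM_FEATURE_NAMES, np.array(values), source, "glcm14")


def average_over_angles(vectors: list[FeatureVector]) -> FeatureVector:
    """Element-wise mean of per-direction feature vectors (same name set)."""
    if not vectors:
        raise SchemaError("no feature vectors to average")
    names = vectors[0].names
    for v in vectors[1:]:
        if v.names != names:
            raise SchemaError(f"feature name mismatch: {v.names} vs {names}")
    values = np.mean([v.values for v in vectors], axis=0)
    return FeatureVector(names, values, vectors[0].source, vectors[0].family)


def _runs_along(line_vals: np.ndarray, line_mask: np.ndarray):
    """Yield (value, length) maximal runs, broken at mask-false positions."""
    run_val = None
    run_len = 0
    for v, m in zip(line_vals, line_mask):
        if not m:
            if run_len:
                yield run_val, run_len
            run_val, run_len = None, 0
        elif v == run_val:
            run_len += 1
        else:
            if run_len:
                yield run_val, run_len
            run_val, run_len = v, 1
    if run_len:
        yield run_val, run_len


def _direction_lines(shape: tuple[int, int], theta: int):
    """Index arrays for every scan line of the grid in direction theta."""
    h, w = shape
    if theta == 0:
        for r in range(h):
            yield np.full(w, r), np.arange(w)
    elif theta == 90:
        for c in range(w):
            yield np.arange(h), np.full(h, c)
    elif theta == 45:  # walk up-right: start on left column and bottom row
        for start_r in range(h):
            n = min(start_r + 1, w)
            yield start_r - np.arange(n), np.arange(n)
        for start_c in range(1, w):
            n = min(w - start_c, h)
            yield h - 1 - np.arange(n), start_c + np.arange(n)
    elif theta == 135:  # walk up-left
        for start_r in range(h):
            n = min(start_r + 1, w)
            yield start_r - np.arange(n), w - 1 - np.arange(n)
        for start_c in range(w - 2, -1, -1):
            n = min(start_c + 1, h)
            yield h - 1 - np.arange(n), start_c - np.arange(n)
    else:
        raise ParameterError(f"theta must be one of {ANGLES}, got {theta}")


def compute_glrlm(
    img: GrayImage,
    mask: np.ndarray,
    theta: int = 0,
    levels: int | None = None,
) -> RunLengthMatrix:
    """Count maximal equal-value runs along one direction, inside the mask."""
    if levels is None:
        levels = int(img.bit_depth) + 1
    pix = np.asarray(img.pixels).astype(int)
    mask = np.asarray(mask) != 0
    if mask.shape != pix.shape:
        raise ParameterError("mask shape differs from image shape")
    if not mask.any():
        raise EmptyRoiError("empty mask in run-length accumulation")
    l_max = max(pix.shape)
    counts = np.zeros((levels, l_max), dtype=float)
    for rows, cols in _direction_lines(pix.shape, theta):
        for val, length in _runs_along(pix[rows, cols], mask[rows, cols]):
            counts[val, length - 1] += 1
    if counts.sum() == 0:
        raise DegenerateMatrixError(f"no run inside mask for theta={theta}")
    return RunLengthMatrix(counts, levels, theta, int(mask.sum()))


def glrlm_features(R: RunLengthMatrix, source: str = "raw") -> FeatureVector:
    """The 11 classical run-length statistics of one run-length matrix.

    Gray levels are weighted 1-based (bin index + 1) so the low/high
    gray-level emphases are defined at bin 0.
    """
    r = R.r
    n_runs = r.sum()
    gl = (np.arange(R.levels, dtype=float) + 1.0)[:, None]  # 1-based level
    rl = (np.arange(r.shape[1], dtype=float) + 1.0)[None, :]
    sre = float((r / rl**2).sum() / n_runs)
    lre = float((r * rl**2).sum() / n_runs)
    gln = float((r.sum(axis=1) ** 2).sum() / n_runs)
    rln = float((r.sum(axis=0) ** 2).sum() / n_runs)
    rp = float(n_runs / R.n_pixels)
    lgre = float((r / gl**2).sum() / n_runs)
    hgre = float((r * gl**2).sum() / n_runs)
    srlge = float((r / (gl**2 * rl**2)).sum() / n_runs)
    srhge = float((r * gl**2 / rl**2).sum() / n_runs)
    lrlge = float((r * rl**2 / gl**2).sum() / n_runs)
    lrhge = float((r * gl**2 * rl**2).sum() / n_runs)
    values = (sre, lre, gln, rln, rp, lgre, hgre, srlge, srhge, lrlge, lrhge)
    return FeatureVector(GLRLM_FEATURE_NAMES, np.array(values), source, "glrlm11")


def quantize_gray(img: GrayImage, levels: int) -> GrayImage:
    """Equal-width reduction of a 0..bit_depth image to ``levels`` bins."""
    if levels < 2:
        raise ParameterError(f"levels must be >= 2, got {levels}")
    pix = np.asarray(img.pixels, dtype=float)
    bins = np.floor(pix * levels / (img.bit_depth + 1)).astype(int)
    np.clip(bins, 0, levels - 1, out=bins)
    return GrayImage(bins, bit_depth=levels - 1)


def _panel_glcm(img: GrayImage, mask: np.ndarray, source: str, d: int, symmetric: bool) -> FeatureVector:
    per_angle = [
        glcm_features(compute_glcm(img, mask, d=d, theta=t, symmetric=symmetric), source)
        for t in ANGLES
    ]
    return average_over_angles(per_angle)


def _panel_glrlm(img: GrayImage, mask: np.ndarray, source: str) -> FeatureVector:
    per_angle = [
        glrlm_features(compute_glrlm(img, mask, theta=t), source) for t in ANGLES
    ]
    return average_over_angles(per_angle)


def extract_case_features(
    case: CaseRecord,
    resolution: int = 4,
    stride: int | None = None,
    levels_raw: int = 32,
    levels_ranklet: int = 8,
    d: int = 1,
    symmetric: bool = True,
    normalize: bool = True,
) -> CaseFeatureRow:
    """All feature panels for one case.

    Emits 4 GLCM panels (raw + three ranklet orientations, 14 features each)
    and 4 GLRLM panels (same sources, 11 each), flattened to
    ``<source>_<feature>`` columns.  ``normalize=False`` skips the 8-bit
    stretch — used by the invariance report, where perturbed versions must
    not be re-stretched back onto each other.
    """
    img = normalize_intensity(case.image) if normalize else case.image
    case.mask.require_nonempty()
    features: dict[str, float] = {}

    raw_q = quantize_gray(img, levels_raw)
    roi = case.mask.pixels
    panels: list[FeatureVector] = [
        _panel_glcm(raw_q, roi, "raw", d, symmetric),
        _panel_glrlm(raw_q, roi, "raw"),
    ]

    transformed = _ranklet.ranklet_transform(img, case.mask, resolution, stride)
    for orientation in _ranklet.ORIENTATIONS:
        q_img, q_mask = _ranklet.quantize_coefficients(
            transformed[orientation], levels_ranklet
        )
        source = f"ranklet_{orientation}"
        panels.append(_panel_glcm(q_img, q_mask, source, d, symmetric))
        panels.append(_panel_glrlm(q_img, q_mask, source))

    for panel in panels:
        for name, value in panel.as_dict().items():
            features[f"{panel.source}_{name}"] = value
    return CaseFeatureRow(case.case_id, case.label, features)


def panel_columns(source: str, family: str = "glcm14") -> list[str]:
    """Column names of one extracted panel, e.g. panel_columns('ranklet_vertical')."""
    names = GLCM_FEATURE_NAMES if family == "glcm14" else GLRLM_FEATURE_NAMES
    return [f"{source}_{n}" for n in names]
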