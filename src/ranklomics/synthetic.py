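"""Synthetic tumor-like images, intensity perturbations and labeled cohorts.

Textures are Gaussian random fields: white noise smoothed at a controllable
correlation length, optionally mixed with an unsmoothed component whose
weight (``heterogeneity``) roughens the texture.  One scalar per axis thus
controls exactly the property the two genotype classes differ in — mutant
cases are modeled as *less* homogeneous (shorter correlation length, higher
heterogeneity).  ROIs are irregular rotated ellipses covering roughly 15% of
the frame.  Intensity perturbations (brightness offset, contrast scaling,
gamma) emulate cross-scanner drift and are restricted to strictly increasing,
non-saturating maps so the ranklet invariance guarantee is exact.

This module is the test-data backbone: everything is a pure function of its
seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import CaseRecord, GrayImage, RoiMask
from .errors import ParameterError, SaturationError
from .io import round_half_up
from . import texture as _texture

DEFAULT_SHAPE = (64, 64)

#: Default texture parameters per class; wild-type (label 0) is the smoother,
#: more homogeneous class, mutant (label 1) the more heterogeneous one.
WT_PARAMS_KW = dict(correlation_length=6.0, base_mean=128.0, base_sd=45.0, heterogeneity=0.1)
MUT_PARAMS_KW = dict(correlation_length=2.0, base_mean=128.0, base_sd=45.0, heterogeneity=0.6)


@dataclass(frozen=True)
class TextureParams:
    """Parameters of the Gaussian-random-field texture model.

    correlation_length: smoothing sigma in pixels (0 = white noise);
    base_mean / base_sd: target intensity location and spread (8-bit scale);
    heterogeneity: mixing weight in [0, 1] of an unsmoothed noise component.
    """

    correlation_length: float = 6.0
    base_mean: float = 128.0
    base_sd: float = 45.0
    heterogeneity: float = 0.1

    def __post_init__(self) -> None:
        if self.correlation_length < 0:
            raise ParameterError("correlation_length must be >= 0")
        if not 0.0 <= self.heterogeneity <= 1.0:
            raise ParameterError("heterogeneity must be in [0, 1]")


def default_params(label: int) -> TextureParams:
    return TextureParams(**(MUT_PARAMS_KW if label else WT_PARAMS_KW))


@dataclass(frozen=True)
class PerturbationSpec:
    """One strictly increasing intensity map: brightness, contrast or gamma."""

    kind: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in ("brightness", "contrast", "gamma"):
            raise ParameterError(f"unknown perturbation kind {self.kind!r}")
        if self.kind in ("contrast", "gamma") and self.magnitude <= 0:
            raise ParameterError(f"{self.kind} magnitude must be > 0")


#: Always-safe members of the standard battery: contrast shrinkage about the
#: mean and gamma never leave [0, 255] on an in-range image.
_SAFE_PERTURBATIONS = (
    PerturbationSpec("contrast", 0.85),
    PerturbationSpec("gamma", 0.8),
    PerturbationSpec("gamma", 1.25),
)


def standard_perturbations(
    img: GrayImage, brightness: float = 12.0
) -> tuple[PerturbationSpec, ...]:
    """The standard battery: brightness shifts (fit to the image's headroom),
    contrast scaling and two gamma maps.

    Brightness magnitudes are capped at the image's distance to 0/255 so the
    maps stay strictly increasing without clipping; a shift below 1 gray
    level is dropped.
    """
    pix = np.asarray(img.pixels, dtype=float)
    up = min(brightness, img.bit_depth - pix.max())
    down = min(brightness, pix.min())
    battery: list[PerturbationSpec] = []
    if up >= 1.0:
        battery.append(PerturbationSpec("brightness", float(up)))
    if down >= 1.0:
        battery.append(PerturbationSpec("brightness", -float(down)))
    battery.extend(_SAFE_PERTURBATIONS)
    return tuple(battery)


def _standardize(field: np.ndarray) -> np.ndarray:
    sd = field.std()
    if sd == 0:
        raise ParameterError("degenerate random field (zero variance)")
    return (field - field.mean()) / sd


def _case_rng(seed: int, case_index: int = 0) -> np.random.Generator:
    """Deterministic per-case generator: SeedSequence keyed on (seed, index)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(case_index)]))


def _elliptical_mask(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Rotated ellipse with jittered semi-axes ~(0.20 H, 0.25 W), centered."""
    h, w = shape
    a = h * rng.uniform(0.18, 0.22)
    b = w * rng.uniform(0.23, 0.27)
    phi = rng.uniform(0.0, np.pi)
    rr, cc = np.mgrid[0:h, 0:w]
    dr = rr - (h - 1) / 2.0
    dc = cc - (w - 1) / 2.0
    u = dr * np.cos(phi) + dc * np.sin(phi)
    v = -dr * np.sin(phi) + dc * np.cos(phi)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_texture_image(
    params: TextureParams,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    seed: int = 0,
) -> CaseRecord:
    """One unlabeled synthetic case: textured image + elliptical ROI.

    The field is mapped to base_mean + base_sd * z, then affinely compressed
    into [0, 255] only if it overflows (order-preserving, no clipping), and
    rounded half-up to 8-bit integers.
    """
    if shape[0] < 32 or shape[1] < 32:
        raise ParameterError(f"shape must be >= 32x32, got {shape}")
    rng = _case_rng(seed)
    noise = rng.standard_normal(shape)
    if params.correlation_length > 0:
        smooth = _standardize(gaussian_filter(noise, sigma=params.correlation_length))
    else:
        smooth = _standardize(noise)
    rough = _standardize(rng.standard_normal(shape))
    z = _standardize(
        (1.0 - params.heterogeneity) * smooth + params.heterogeneity * rough
    )
    vals = params.base_mean + params.base_sd * z
    lo, hi = vals.min(), vals.max()
    if lo < 0 or hi > 255:
        vals = (vals - lo) * (255.0 / (hi - lo))
    pixels = round_half_up(vals).astype(np.uint8)
    if pixels.max() == pixels.min():
        raise ParameterError("generated image has no dynamic range")
    mask = _elliptical_mask(shape, rng)
    return CaseRecord(
        case_id=f"synthetic-{seed}",
        image=GrayImage(pixels, bit_depth=255),
        mask=RoiMask(mask),
    )


def perturb_intensity(
    img: GrayImage, spec: PerturbationSpec, rounding: bool = True
) -> GrayImage:
    """Apply one strictly increasing intensity map.

    brightness: v + b; contrast: mean + c (v - mean); gamma: 255 (v/255)^g.
    A magnitude that would push the observed range outside [0, 255] is
    rejected (no silent clipping).  ``rounding=False`` returns float pixels —
    the exact path on which rank invariance holds with no rounding ties.
    """
    pix = np.asarray(img.pixels, dtype=float)
    lo, hi = float(pix.min()), float(pix.max())
    if spec.kind == "brightness":
        out = pix + spec.magnitude
    elif spec.kind == "contrast":
        mean = float(pix.mean())
        out = mean + spec.magnitude * (pix - mean)
    else:  # gamma
        out = img.bit_depth * (pix / img.bit_depth) ** spec.magnitude
    if out.min() < 0 or out.max() > img.bit_depth:
        raise SaturationError(
            f"{spec.kind} {spec.magnitude} maps observed range [{lo}, {hi}] "
            f"outside [0, {img.bit_depth}]"
        )
    if rounding:
        out = round_half_up(out)
    return GrayImage(out, bit_depth=img.bit_depth)


def generate_cohort(
    n_neg: int,
    n_pos: int,
    params_neg: TextureParams | None = None,
    params_pos: TextureParams | None = None,
    seed: int = 1234,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    scanner_jitter: bool = True,
) -> list[CaseRecord]:
    """Labeled cohort: n_neg wild-type then n_pos mutant cases.

    Each case draws its own generator from SeedSequence([seed, index]) so any
    case is reproducible independent of generation order.  Per-case random
    contrast (U(0.88, 0.97)) then brightness jitter (within the remaining
    headroom, capped at +/-10) mimic cross-scanner intensity variation.
    """
    if n_neg < 2 or n_pos < 2:
        raise ParameterError("need >= 2 cases per class")
    params_neg = params_neg or default_params(0)
    params_pos = params_pos or default_params(1)
    cases: list[CaseRecord] = []
    for idx in range(n_neg + n_pos):
        label = 0 if idx < n_neg else 1
        params = params_neg if label == 0 else params_pos
        case_seed = int(
            np.random.SeedSequence([int(seed), idx]).generate_state(1)[0] % (2**31)
        )
        case = generate_texture_image(params, shape, seed=case_seed)
        img = case.image
        if scanner_jitter:
            jrng = _case_rng(seed, idx + 1_000_000)
            img = perturb_intensity(
                img, PerturbationSpec("contrast", jrng.uniform(0.88, 0.97))
            )
            pix = img.pixels
            b_lo = max(-10.0, -float(pix.min()))
            b_hi = min(10.0, 255.0 - float(pix.max()))
            b = jrng.uniform(b_lo, b_hi)
            if b != 0.0:
                img = perturb_intensity(img, PerturbationSpec("brightness", b))
        prefix = "wt" if label == 0 else "mut"
        cases.append(
            CaseRecord(
                case_id=f"{prefix}{idx:03d}",
                image=img,
                mask=case.mask,
                label=label,
            )
        )
    return cases


@dataclass
class InvarianceReport:
    """Per-feature SD across perturbed versions, per source panel.

    ``values``: version-by-feature table per source; ``sd``: feature-by-source
    SD table (population SD, ddof=0).  Raw-panel rows respond to intensity
    perturbations; ranklet-panel rows are exactly zero on the pre-rounding
    path.
    """

    sources: list[str]
    feature_names: list[str]
    values: dict[str, np.ndarray]
    sd: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.sd


def invariance_report(
    case: CaseRecord,
    perturbations: Sequence[PerturbationSpec] | None = None,
    exact: bool = True,
    resolution: int = 4,
    levels_raw: int = 32,
    levels_ranklet: int = 8,
    d: int = 1,
) -> InvarianceReport:
    """Feature stability of raw vs ranklet GLCM panels under perturbation.

    Features are extracted from the original plus each perturbed version
    *without* re-normalization (re-stretching would undo affine perturbations
    by construction).  ``exact=True`` keeps perturbed pixels as floats so no
    rounding ties are introduced and ranklet-panel SDs are exactly zero for
    strictly monotone maps.
    """
    if perturbations is None:
        perturbations = standard_perturbations(case.image)
    if len(perturbations) < 2:
        raise ParameterError("need at least 2 perturbed versions plus the original")
    versions = [case.image] + [
        perturb_intensity(case.image, p, rounding=not exact) for p in perturbations
    ]
    sources = ["raw", "ranklet_vertical", "ranklet_horizontal", "ranklet_diagonal"]
    feature_names = list(_texture.GLCM_FEATURE_NAMES)
    per_source: dict[str, list[list[float]]] = {s: [] for s in sources}
    for img in versions:
        row = _texture.extract_case_features(
            CaseRecord(case.case_id, img, case.mask, case.label),
            resolution=resolution,
            levels_raw=levels_raw,
            levels_ranklet=levels_ranklet,
            d=d,
            normalize=False,
        )
        for s in sources:
            per_source[s].append([row.features[f"{s}_{f}"] for f in feature_names])
    values = {s: np.asarray(v) for s, v in per_source.items()}
    # Shift by the first version before taking the SD: numerically stabler
    # and exactly zero when all versions coincide bit-for-bit.
    sd = pd.DataFrame(
        {s: (values[s] - values[s][0]).std(axis=0, ddof=0) for s in sources},
        index=feature_names,
    )
    return InvarianceReport(sources, feature_names, values, sd)
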