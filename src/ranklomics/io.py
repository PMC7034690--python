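"""Reading cases (image + ROI mask), intensity normalization, feature tables.

Images arrive as single-frame grayscale DICOM, PNG or TIFF; masks as binary
PNG/TIFF of identical shape.  Intensities are stretched to the full 8-bit
range over the *whole* slice before any texture work, mirroring clinical
practice where normalization precedes contour delineation.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CaseFeatureRow, CaseRecord, Dataset, GrayImage, RoiMask
from .errors import SchemaError, ShapeMismatchError, UnsupportedFormatError

logger = logging.getLogger(__name__)

_DICOM_SUFFIXES = {".dcm", ".dicom", ".ima"}


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with ties going up (0.5 -> 1)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def _read_array(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in _DICOM_SUFFIXES:
        import pydicom

        ds = pydicom.dcmread(path)
        n_frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
        if n_frames != 1:
            raise UnsupportedFormatError(
                f"{path.name}: multi-frame DICOM ({n_frames} frames) not supported"
            )
        arr = ds.pixel_array
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        elif arr.shape[2] in (3, 4) and np.all(arr[..., :3].max(axis=2) == arr[..., :3].min(axis=2)):
            arr = arr[:, :, 0]  # gray stored as identical RGB channels
        else:
            raise UnsupportedFormatError(
                f"{path.name}: color or multi-frame input not supported "
                f"(shape {arr.shape})"
            )
    if arr.ndim != 2:
        raise UnsupportedFormatError(
            f"{path.name}: expected a 2D grayscale frame, got shape {arr.shape}"
        )
    return arr


def load_case(
    image_path: str | Path,
    mask_path: str | Path,
    case_id: str | None = None,
    label: int | None = None,
) -> CaseRecord:
    """Read an image + ROI mask pair into a :class:`CaseRecord`.

    Pixels are returned raw (un-normalized); the mask is coerced to binary
    (any nonzero value is foreground) and must be non-empty and congruent
    with the image.
    """
    img_arr = _read_array(image_path)
    mask_arr = _read_array(mask_path)
    if img_arr.shape != mask_arr.shape:
        raise ShapeMismatchError(
            f"image {img_arr.shape} vs mask {mask_arr.shape}"
        )
    image = GrayImage(img_arr, bit_depth=int(max(255, img_arr.max())))
    mask = RoiMask(mask_arr)
    mask.require_nonempty()
    if case_id is None:
        case_id = Path(image_path).stem
    return CaseRecord(case_id=case_id, image=image, mask=mask, label=label)


def normalize_intensity(img: GrayImage) -> GrayImage:
    """Stretch the gray-level distribution to the full 8-bit range (0-255).

    v' = round(255 * (v - min) / (max - min)), round-half-up.  A constant
    image has no dynamic range; it maps to all zeros with a logged warning
    rather than aborting a batch run.
    """
    pix = np.asarray(img.pixels, dtype=float)
    lo, hi = float(pix.min()), float(pix.max())
    if hi == lo:
        logger.warning(
            "normalize_intensity: constant image (value %s) mapped to all zeros", lo
        )
        return GrayImage(np.zeros(img.shape, dtype=np.uint8), bit_depth=255)
    out = round_half_up(255.0 * (pix - lo) / (hi - lo)).astype(np.uint8)
    return GrayImage(out, bit_depth=255)


def write_feature_table(rows: Sequence[CaseFeatureRow], path: str | Path) -> None:
    """Write one CSV row per case: case_id, label, then features in fixed order.

    Floats are serialized with 17 significant digits so that a round-trip
    through :func:`read_feature_table` is exact.
    """
    if not rows:
        raise SchemaError("no rows to write")
    names = list(rows[0].features)
    for r in rows[1:]:
        if list(r.features) != names:
            raise SchemaError(
                f"row {r.case_id!r} feature set differs from row {rows[0].case_id!r}"
            )
    frame = pd.DataFrame(
        [[r.case_id, r.label] + [r.features[n] for n in names] for r in rows],
        columns=["case_id", "label"] + names,
    )
    frame.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> Dataset:
    """Read a feature CSV written by :func:`write_feature_table`."""
    frame = pd.read_csv(path)
    for col in ("case_id", "label"):
        if col not in frame.columns:
            raise SchemaError(f"feature table missing required column {col!r}")
    frame = frame.set_index("case_id")
    labels = frame.pop("label").to_numpy()
    if np.any(pd.isna(labels)):
        raise SchemaError("feature table has missing labels")
    return Dataset(frame, labels.astype(int))
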