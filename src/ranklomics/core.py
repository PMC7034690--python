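"""Core in-memory containers shared across the pipeline.

A :class:`GrayImage` is the unit every transform operates on: a 2D grid of
non-negative intensities with a nominal maximum (``bit_depth``, 255 after
normalization).  A :class:`RoiMask` is a congruent boolean grid marking the
tumor region.  A :class:`CaseRecord` bundles the two with an identifier and an
optional binary genotype label (0 = wild-type, 1 = mutant).  Feature
extraction emits :class:`CaseFeatureRow` objects, and classification consumes
a :class:`Dataset` (a named feature matrix plus labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyRoiError, SchemaError, ShapeMismatchError


@dataclass
class GrayImage:
    """2D intensity grid.

    ``pixels`` is kept as the array handed in (integer after normalization;
    float pixels are permitted for the exact, pre-rounding perturbation path
    since every rank-based operation downstream is dtype-agnostic).
    """

    pixels: np.ndarray
    bit_depth: int = 255

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ShapeMismatchError(
                f"expected a non-empty 2D pixel grid, got shape {self.pixels.shape}"
            )
        if np.any(self.pixels < 0) or np.any(self.pixels > self.bit_depth):
            raise ValueError(
                f"pixel values must lie in [0, {self.bit_depth}]; "
                f"got range [{self.pixels.min()}, {self.pixels.max()}]"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class RoiMask:
    """Boolean ROI grid; any nonzero input value counts as foreground."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels) != 0
        if self.pixels.ndim != 2:
            raise ShapeMismatchError(
                f"expected a 2D mask grid, got shape {self.pixels.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.pixels.sum())

    def require_nonempty(self) -> None:
        if not self.pixels.any():
            raise EmptyRoiError("ROI mask contains no foreground pixel")

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(row_min, col_min, row_max_exclusive, col_max_exclusive)."""
        self.require_nonempty()
        rows = np.any(self.pixels, axis=1)
        cols = np.any(self.pixels, axis=0)
        r = np.flatnonzero(rows)
        c = np.flatnonzero(cols)
        return int(r[0]), int(c[0]), int(r[-1]) + 1, int(c[-1]) + 1


def check_congruent(image: GrayImage, mask: RoiMask) -> None:
    if image.shape != mask.shape:
        raise ShapeMismatchError(
            f"image shape {image.shape} != mask shape {mask.shape}"
        )


@dataclass
class CaseRecord:
    """One case: image + ROI + optional binary label (1 = mutant)."""

    case_id: str
    image: GrayImage
    mask: RoiMask
    label: int | None = None

    def __post_init__(self) -> None:
        check_congruent(self.image, self.mask)
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")


@dataclass
class FeatureVector:
    """Named feature values with a fixed order and a provenance tag.

    ``source`` records which image kind produced the values (``raw`` or one of
    the three ranklet orientations); ``family`` is ``glcm14`` or ``glrlm11``.
    """

    names: tuple[str, ...]
    values: np.ndarray
    source: str = "raw"
    family: str = "glcm14"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise SchemaError(
                f"{len(self.names)} names vs {self.values.size} values"
            )
        if np.any(~np.isfinite(self.values)):
            bad = [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]
            raise SchemaError(f"non-finite feature values: {bad}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))

    def __getitem__(self, name: str) -> float:
        try:
            return float(self.values[self.names.index(name)])
        except ValueError:
            raise KeyError(name) from None


@dataclass
class CaseFeatureRow:
    """All extracted feature panels for one case, flattened to named columns."""

    case_id: str
    label: int | None
    features: dict[str, float]


@dataclass
class Dataset:
    """Feature matrix (cases x named features) plus binary labels."""

    features: pd.DataFrame  # index = case_id
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.features) != self.labels.size:
            raise SchemaError(
                f"{len(self.features)} feature rows vs {self.labels.size} labels"
            )
        if self.features.isna().any().any():
            raise SchemaError("feature matrix contains missing values")

    @property
    def case_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def n_cases(self) -> int:
        return len(self.features)

    def subset(self, feature_names: Sequence[str]) -> "Dataset":
        missing = [f for f in feature_names if f not in self.features.columns]
        if missing:
            raise SchemaError(f"unknown features: {missing}")
        return Dataset(self.features[list(feature_names)], self.labels)


def rows_to_dataset(rows: Sequence[CaseFeatureRow]) -> Dataset:
    """Assemble CaseFeatureRows (with labels) into a Dataset."""
    if not rows:
        raise SchemaError("no rows to assemble")
    names = list(rows[0].features)
    for r in rows[1:]:
        if list(r.features) != names:
            raise SchemaError(
                f"case {r.case_id!r} has a different feature set than "
                f"case {rows[0].case_id!r}"
            )
    labels = []
    for r in rows:
        if r.label is None:
            raise SchemaError(f"case {r.case_id!r} has no label")
        labels.append(r.label)
    frame = pd.DataFrame(
        [[r.features[n] for n in names] for r in rows],
        index=[r.case_id for r in rows],
        columns=names,
    )
    frame.index.name = "case_id"
    return Dataset(frame, np.array(labels))
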