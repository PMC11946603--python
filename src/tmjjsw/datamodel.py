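"""Core in-memory containers for images, label masks and dataset splits.

Coordinate convention used throughout the package: arrays are row-major
with row 0 at the top of the displayed frame and column 0 at the left.
"Superior" (anatomically upward, toward the glenoid fossa) therefore
means a *smaller* row index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed label coding of the three TMJ structures.
BACKGROUND, MC, JS, GF = 0, 1, 2, 3

CLASS_NAMES: dict[int, str] = {MC: "MC", JS: "JS", GF: "GF"}
FOREGROUND_CLASSES: tuple[int, ...] = (MC, JS, GF)
ALL_CLASSES: tuple[int, ...] = (BACKGROUND, MC, JS, GF)


def _check_spacing(spacing_mm) -> tuple[float, float]:
    spacing = (float(spacing_mm[0]), float(spacing_mm[1]))
    if not all(s > 0 for s in spacing):
        raise ValueError(f"pixel spacing must be strictly positive, got {spacing}")
    return spacing


@dataclass
class UltrasoundImage:
    """A single 8-bit grayscale ultrasound frame with physical pixel spacing.

    Parameters
    ----------
    pixels : ndarray of shape (rows, cols)
        Intensities; must be integers in [0, 255].
    spacing_mm : (float, float)
        Physical size of one pixel as (row spacing, column spacing) in mm.
    id : str
        Case identifier.
    """

    pixels: np.ndarray
    spacing_mm: tuple[float, float] = (1.0, 1.0)
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"image must be 2D, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            if not np.array_equal(px, np.round(px)):
                raise ValueError("image intensities must be integers")
            px = px.astype(np.int64)
        if px.size and (px.min() < 0 or px.max() > 255):
            raise ValueError("image intensities must lie in [0, 255]")
        self.pixels = px.astype(np.uint8)
        self.spacing_mm = _check_spacing(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelMask:
    """A 2D multi-class label map over {0: background, 1: MC, 2: JS, 3: GF}."""

    labels: np.ndarray
    spacing_mm: tuple[float, float] = (1.0, 1.0)
    id: str = ""
    class_names: dict[int, str] = field(default_factory=lambda: dict(CLASS_NAMES))

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError(f"label mask must be 2D, got shape {lab.shape}")
        if lab.size and not np.isin(lab, ALL_CLASSES).all():
            bad = sorted(set(np.unique(lab)) - set(ALL_CLASSES))
            raise ValueError(f"label mask contains values outside {{0,1,2,3}}: {bad}")
        self.labels = lab.astype(np.uint8)
        self.spacing_mm = _check_spacing(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_mask(self, class_code: int) -> np.ndarray:
        """Boolean mask of one class."""
        return self.labels == class_code

    def with_labels(self, labels: np.ndarray) -> "LabelMask":
        """A copy of this mask carrying new label values but the same metadata."""
        return LabelMask(labels=labels, spacing_mm=self.spacing_mm, id=self.id,
                         class_names=dict(self.class_names))


@dataclass
class DatasetSplit:
    """A holdout partition of case ids into train / validation / test."""

    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    seed: int = 0

    def __post_init__(self) -> None:
        groups = (self.train_ids, self.val_ids, self.test_ids)
        sets = [set(g) for g in groups]
        total = sum(len(g) for g in groups)
        if len(set().union(*sets)) != total:
            raise ValueError("split groups must be pairwise disjoint")

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train_ids), len(self.val_ids), len(self.test_ids))

    @property
    def all_ids(self) -> set[str]:
        return set(self.train_ids) | set(self.val_ids) | set(self.test_ids)
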