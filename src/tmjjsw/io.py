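"""File I/O: images, label masks, manifests, measurement tables, splits.

Images are 8-bit grayscale PNG/TIFF. Masks are indexed PNG (or TIFF)
whose stored values map onto the class codes {0, 1, 2, 3}. Pixel spacing
is metadata the acquisition does not embed in the exported crops, so it
is supplied either through a JSON sidecar ``<stem>.json`` with key
``"spacing_mm": [row_mm, col_mm]`` or through a ``manifest.csv`` with
columns ``id,image,mask,row_spacing_mm,col_spacing_mm``.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .datamodel import ALL_CLASSES, DatasetSplit, LabelMask, UltrasoundImage
from .jsw import JSWMeasurement

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = [
    "id", "apex_row", "apex_col", "fossa_row", "fossa_col",
    "jsw_px", "jsw_mm", "status",
]


def _sidecar_spacing(path: Path) -> tuple[float, float] | None:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        return None
    meta = json.loads(sidecar.read_text())
    spacing = meta.get("spacing_mm")
    if spacing is None:
        return None
    return (float(spacing[0]), float(spacing[1]))


def _load_grayscale(path: Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        # RGB(A) exports of grayscale data are accepted iff channels agree.
        rgb = arr[..., :3]
        if not (rgb[..., 0] == rgb[..., 1]).all() or not (rgb[..., 0] == rgb[..., 2]).all():
            raise ValueError(f"{path}: multi-channel image with non-identical channels")
        arr = rgb[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: unsupported bit depth {arr.dtype}; expected 8-bit")
    return arr


def read_image(path, spacing_mm: tuple[float, float] | None = None,
               id: str | None = None) -> UltrasoundImage:
    """Read an 8-bit grayscale ultrasound frame.

    Spacing resolution order: explicit ``spacing_mm`` argument, then a
    ``<stem>.json`` sidecar, then (1.0, 1.0) with a logged warning.
    """
    path = Path(path)
    pixels = _load_grayscale(path)
    if spacing_mm is None:
        spacing_mm = _sidecar_spacing(path)
    if spacing_mm is None:
        logger.warning("%s: no pixel spacing supplied; defaulting to 1.0 mm/px", path)
        spacing_mm = (1.0, 1.0)
    return UltrasoundImage(pixels=pixels, spacing_mm=spacing_mm,
                           id=id if id is not None else path.stem)


def read_mask(path, class_map: Mapping[int, int] | None = None,
              spacing_mm: tuple[float, float] | None = None,
              id: str | None = None) -> LabelMask:
    """Read an indexed label mask and remap stored values to class codes.

    ``class_map`` maps stored pixel values to codes in {0,1,2,3}; by
    default the identity map over {0,1,2,3}. Any stored value absent
    from the map raises, naming the offending value.
    """
    path = Path(path)
    raw = _load_grayscale(path)
    if class_map is None:
        class_map = {c: c for c in ALL_CLASSES}
    present = np.unique(raw)
    unmapped = [int(v) for v in present if int(v) not in class_map]
    if unmapped:
        raise ValueError(f"{path}: stored mask value(s) {unmapped} not in class_map")
    lut = np.zeros(256, dtype=np.uint8)
    for stored, code in class_map.items():
        if code not in ALL_CLASSES:
            raise ValueError(f"class_map target {code} outside {{0,1,2,3}}")
        lut[stored] = code
    if spacing_mm is None:
        spacing_mm = _sidecar_spacing(path) or (1.0, 1.0)
    return LabelMask(labels=lut[raw], spacing_mm=spacing_mm,
                     id=id if id is not None else path.stem)


def write_mask(mask: LabelMask, path) -> None:
    """Write a label mask as an indexed 8-bit PNG/TIFF (values 0..3)."""
    iio.imwrite(Path(path), mask.labels.astype(np.uint8))


def read_manifest(path) -> pd.DataFrame:
    """Read a dataset manifest CSV (id,image,mask,row_spacing_mm,col_spacing_mm)."""
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id", "image", "mask", "row_spacing_mm", "col_spacing_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    return df


def make_split(ids: Sequence[str], fractions: tuple[float, float, float] = (0.60, 0.15, 0.25),
               seed: int = 0) -> DatasetSplit:
    """Random holdout partition into train / validation / test.

    The validation and test counts are ``floor(fraction * n)`` and every
    remaining case goes to the training set (the largest bucket), so for
    142 cases at (0.60, 0.15, 0.25) the sizes are 86/21/35. The shuffle
    is a seeded permutation, reproducible for a fixed seed.
    """
    ids = [str(i) for i in ids]
    if not ids:
        raise ValueError("ids must be non-empty")
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate ids: {dupes}")
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(ids)
    n_val = int(fractions[1] * n)
    n_test = int(fractions[2] * n)
    n_train = n - n_val - n_test
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [ids[i] for i in order]
    return DatasetSplit(
        train_ids=shuffled[:n_train],
        val_ids=shuffled[n_train:n_train + n_val],
        test_ids=shuffled[n_train + n_val:],
        seed=seed,
    )


def _measurement_row(m: JSWMeasurement) -> dict:
    return {
        "id": m.id,
        "apex_row": m.apex.row if m.apex is not None else "",
        "apex_col": m.apex.col if m.apex is not None else "",
        "fossa_row": m.fossa_point.row if m.fossa_point is not None else "",
        "fossa_col": m.fossa_point.col if m.fossa_point is not None else "",
        "jsw_px": m.jsw_px if m.jsw_px is not None else "",
        "jsw_mm": f"{m.jsw_mm:.4f}" if m.jsw_mm is not None else "",
        "status": m.status,
    }


def write_measurements_csv(rows: Iterable[JSWMeasurement | Mapping], path) -> None:
    """Write JSW measurements as CSV with one row per case.

    Accepts :class:`~tmjjsw.jsw.JSWMeasurement` objects or pre-built
    mappings with the same keys; mm values are written with 4 decimals.
    """
    records = [_measurement_row(r) if isinstance(r, JSWMeasurement) else dict(r)
               for r in rows]
    df = pd.DataFrame(records, columns=MEASUREMENT_COLUMNS)
    df.to_csv(path, index=False)


def read_measurements_csv(path) -> pd.DataFrame:
    """Read a measurement CSV written by :func:`write_measurements_csv`."""
    return pd.read_csv(path, dtype={"id": str, "status": str})
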