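"""Per-case, per-class segmentation metrics and test-set aggregation.

For each structure (MC, JS, GF) evaluated one-vs-rest:

* Dice = 2|P∩G| / (|P| + |G|)
* precision = TP / (TP + FP), recall = TP / (TP + FN)
* volume similarity VS = 1 − |V_P − V_G| / (V_P + V_G)
  (computed on pixel counts, the 2D analogue of volumes)
* Hausdorff distance = max of the two directed maximum
  nearest-neighbour distances between the boundary point sets, in mm.

Degenerate-class conventions: when a class is empty in both masks the
ratios are 1 and HD is 0 (vacuous agreement); when it is empty in
exactly one mask Dice/recall (or precision) are 0 and HD is undefined
(NaN) and excluded from summaries. Undefined values are NaN sentinels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial.distance import directed_hausdorff

from .datamodel import CLASS_NAMES, FOREGROUND_CLASSES, LabelMask

METRIC_NAMES = ("dice", "precision", "recall", "vs", "hd_mm")


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest pixel counts for a single class."""

    tp: int
    fp: int
    fn: int


def _labels_of(mask) -> np.ndarray:
    return mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)


def confusion_counts(pred, ref, class_code: int) -> ConfusionCounts:
    """Pixelwise TP/FP/FN for one class."""
    p = _labels_of(pred) == class_code
    g = _labels_of(ref) == class_code
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs ref {g.shape}")
    tp = int(np.count_nonzero(p & g))
    return ConfusionCounts(tp=tp, fp=int(np.count_nonzero(p)) - tp,
                           fn=int(np.count_nonzero(g)) - tp)


def dice(c: ConfusionCounts) -> float:
    """Dice overlap; 1.0 for an empty-vs-empty class, 0.0 when exactly one side is empty."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2 * c.tp / denom


def precision(c: ConfusionCounts) -> float:
    """TP/(TP+FP); NaN when nothing was predicted (undefined)."""
    if c.tp + c.fp == 0:
        return float("nan")
    return c.tp / (c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    """TP/(TP+FN); NaN when the reference class is empty (undefined)."""
    if c.tp + c.fn == 0:
        return float("nan")
    return c.tp / (c.tp + c.fn)


def volume_similarity(pred_count: int, ref_count: int) -> float:
    """VS = 1 − |V_P − V_G|/(V_P + V_G) on pixel counts; 1.0 when both are empty."""
    if pred_count < 0 or ref_count < 0:
        raise ValueError("counts must be non-negative")
    total = pred_count + ref_count
    if total == 0:
        return 1.0
    return 1.0 - abs(pred_count - ref_count) / total


def boundary_pixels(binary: np.ndarray) -> np.ndarray:
    """Foreground pixels 4-adjacent to background (image border counts as background)."""
    binary = np.asarray(binary, dtype=bool)
    interior = ndi.binary_erosion(binary, structure=ndi.generate_binary_structure(2, 1),
                                  border_value=0)
    return binary & ~interior


def hausdorff_mm(pred, ref, class_code: int) -> float:
    """Symmetric Hausdorff distance between class boundaries, in mm.

    Euclidean distance with per-axis physical scaling. Returns 0.0 when
    the class is empty on both sides, NaN when empty on exactly one.
    """
    p_lab, g_lab = _labels_of(pred), _labels_of(ref)
    if p_lab.shape != g_lab.shape:
        raise ValueError(f"shape mismatch: pred {p_lab.shape} vs ref {g_lab.shape}")
    spacing = (1.0, 1.0)
    if isinstance(pred, LabelMask) or isinstance(ref, LabelMask):
        sp = pred.spacing_mm if isinstance(pred, LabelMask) else ref.spacing_mm
        sg = ref.spacing_mm if isinstance(ref, LabelMask) else sp
        if isinstance(pred, LabelMask) and isinstance(ref, LabelMask) and sp != sg:
            raise ValueError(f"spacing mismatch: pred {sp} vs ref {sg}")
        spacing = sp
    p_set = np.argwhere(boundary_pixels(p_lab == class_code)) * np.asarray(spacing)
    g_set = np.argwhere(boundary_pixels(g_lab == class_code)) * np.asarray(spacing)
    if p_set.size == 0 and g_set.size == 0:
        return 0.0
    if p_set.size == 0 or g_set.size == 0:
        return float("nan")
    return max(directed_hausdorff(p_set, g_set)[0], directed_hausdorff(g_set, p_set)[0])


def evaluate_case(pred, ref, case_id: str | None = None) -> dict:
    """All five metrics for all three structures of one mask pair.

    Returns ``{"id": ..., "MC": {...}, "JS": {...}, "GF": {...}}``, each
    inner dict keyed by :data:`METRIC_NAMES`.
    """
    if case_id is None:
        case_id = getattr(ref, "id", "") or getattr(pred, "id", "")
    report: dict = {"id": case_id}
    for code in FOREGROUND_CLASSES:
        c = confusion_counts(pred, ref, code)
        if c.tp + c.fp + c.fn == 0:  # class absent everywhere: vacuous agreement
            vals = {"dice": 1.0, "precision": 1.0, "recall": 1.0, "vs": 1.0, "hd_mm": 0.0}
        else:
            vals = {
                "dice": dice(c),
                "precision": precision(c),
                "recall": recall(c),
                "vs": volume_similarity(c.tp + c.fp, c.tp + c.fn),
                "hd_mm": hausdorff_mm(pred, ref, code),
            }
        report[CLASS_NAMES[code]] = vals
    return report


def reports_to_frame(reports: Iterable[dict]) -> pd.DataFrame:
    """Long-format DataFrame (id, class, metric columns) from case reports."""
    rows = []
    for rep in reports:
        for cls in CLASS_NAMES.values():
            rows.append({"id": rep["id"], "class": cls, **rep[cls]})
    return pd.DataFrame(rows)


def summarize(reports: Sequence[dict]) -> pd.DataFrame:
    """Per-class mean ± SD of each metric across cases.

    SD uses the sample (n−1) denominator. NaN (undefined) per-case
    values are excluded; the number of exclusions is reported in
    ``<metric>_n_excluded`` columns.
    """
    if not reports:
        raise ValueError("no case reports to summarize")
    df = reports_to_frame(reports)
    out = []
    for cls, grp in df.groupby("class", sort=False):
        row: dict = {"class": cls, "n_cases": len(grp)}
        for metric in METRIC_NAMES:
            vals = grp[metric].to_numpy(dtype=float)
            defined = vals[~np.isnan(vals)]
            row[f"{metric}_mean"] = defined.mean() if defined.size else float("nan")
            row[f"{metric}_sd"] = (defined.std(ddof=1) if defined.size > 1 else float("nan"))
            row[f"{metric}_n_excluded"] = int(np.isnan(vals).sum())
        out.append(row)
    return pd.DataFrame(out)
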