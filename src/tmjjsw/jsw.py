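"""Joint-space-width (JSW) measurement from a TMJ label mask.

The measurement rule: locate the superior-most pixel of the mandibular
condyle (smallest row index; ties broken by the median column, taking
the lower of the two middle columns for an even tie count), then find
the nearest glenoid-fossa pixel in the same column strictly above the
apex, and report the vertical (row-index) distance between the two
points. Millimetre values are pixel distance times the row spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .datamodel import GF, MC, LabelMask

#: measurement outcome codes
STATUS_OK = "ok"
STATUS_NO_CONDYLE = "no_condyle"
STATUS_NO_FOSSA = "no_fossa_in_column"
STATUS_FOSSA_NOT_SUPERIOR = "fossa_not_superior"


class PixelPoint(NamedTuple):
    row: int
    col: int


@dataclass
class JSWMeasurement:
    """One joint-space-width measurement.

    ``status == "ok"`` implies both landmark points are present, share a
    column, and ``jsw_mm == jsw_px * row_spacing_mm``. For any other
    status the distance fields are ``None``.
    """

    id: str
    status: str
    apex: Optional[PixelPoint] = None
    fossa_point: Optional[PixelPoint] = None
    jsw_px: Optional[int] = None
    jsw_mm: Optional[float] = None

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


def find_condyle_apex(mask: LabelMask) -> Optional[PixelPoint]:
    """Superior-most condyle pixel; median-column tie-break.

    Returns ``None`` when the mask contains no MC pixels. Among pixels
    sharing the minimal row index, the column is the median of the tied
    columns; for an even number of ties the lower middle column is taken
    (sorted index ``(k - 1) // 2``).
    """
    rows, cols = np.nonzero(mask.labels == MC)
    if rows.size == 0:
        return None
    top = rows.min()
    tied = np.sort(cols[rows == top])
    return PixelPoint(int(top), int(tied[(tied.size - 1) // 2]))


def find_fossa_match(mask: LabelMask, apex: PixelPoint,
                     allow_inferior_fossa: bool = False) -> tuple[Optional[PixelPoint], str]:
    """Nearest glenoid-fossa pixel in the apex column, above the apex.

    Returns ``(point, status)``. With ``allow_inferior_fossa`` the search
    falls back to the nearest GF pixel in the column by absolute row
    distance when none lies above the apex (useful on pathological
    predictions where the fossa is mis-segmented below the condyle).
    """
    col_rows = np.nonzero(mask.labels[:, apex.col] == GF)[0]
    if col_rows.size == 0:
        return None, STATUS_NO_FOSSA
    above = col_rows[col_rows < apex.row]
    if above.size:
        return PixelPoint(int(above.max()), apex.col), STATUS_OK
    if allow_inferior_fossa:
        nearest = col_rows[np.argmin(np.abs(col_rows - apex.row))]
        return PixelPoint(int(nearest), apex.col), STATUS_OK
    return None, STATUS_FOSSA_NOT_SUPERIOR


def measure_jsw(mask: LabelMask, allow_inferior_fossa: bool = False) -> JSWMeasurement:
    """Measure the joint-space width of one mask.

    Anatomical absence (no condyle, no fossa above it) is reported in
    ``status`` rather than raised.
    """
    apex = find_condyle_apex(mask)
    if apex is None:
        return JSWMeasurement(id=mask.id, status=STATUS_NO_CONDYLE)
    fossa, status = find_fossa_match(mask, apex, allow_inferior_fossa=allow_inferior_fossa)
    if status != STATUS_OK:
        return JSWMeasurement(id=mask.id, status=status, apex=apex)
    jsw_px = abs(apex.row - fossa.row)
    return JSWMeasurement(
        id=mask.id,
        status=STATUS_OK,
        apex=apex,
        fossa_point=fossa,
        jsw_px=int(jsw_px),
        jsw_mm=float(jsw_px * mask.spacing_mm[0]),
    )
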