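"""End-to-end evaluation: postprocess → metrics → JSW → agreement.

Reference JSW values are measured from the reference masks with the
same measurement rule used on predictions, so AI-vs-reference
differences isolate segmentation error rather than measurement-rule
differences.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .agreement import agreement_stats
from .io import read_manifest, read_mask, write_measurements_csv
from .jsw import measure_jsw
from .metrics import evaluate_case, reports_to_frame, summarize
from .postprocess import ComponentFilter

logger = logging.getLogger(__name__)


def _mask_path(directory: Path, case_id: str) -> Path:
    for ext in (".png", ".tif", ".tiff"):
        p = directory / f"{case_id}{ext}"
        if p.exists():
            return p
    raise FileNotFoundError(f"no mask for case '{case_id}' in {directory}")


def full_eval(pred_dir, ref_dir, manifest, out_dir=None, cc_threshold: float = 0.60,
              connectivity: int = 8, allow_inferior_fossa: bool = False) -> dict:
    """Run the complete paired evaluation over a directory of cases.

    Parameters
    ----------
    pred_dir, ref_dir : directories holding ``<id>.png`` label masks
    manifest : manifest CSV path or DataFrame with id and spacing columns
    out_dir : if given, CSV/JSON outputs are written there

    Returns a dict with the per-case metric frame, the summary table,
    both measurement lists, the agreement report (or None when fewer
    than two valid pairs remain) and the excluded case ids.
    """
    pred_dir, ref_dir = Path(pred_dir), Path(ref_dir)
    mf = manifest if isinstance(manifest, pd.DataFrame) else read_manifest(manifest)
    filt = ComponentFilter(cc_threshold, connectivity)

    reports, pred_meas, ref_meas, excluded = [], [], [], []
    for row in mf.itertuples(index=False):
        spacing = (float(row.row_spacing_mm), float(row.col_spacing_mm))
        ref = read_mask(_mask_path(ref_dir, row.id), spacing_mm=spacing, id=row.id)
        pred = read_mask(_mask_path(pred_dir, row.id), spacing_mm=spacing, id=row.id)
        pred = filt.transform(pred)
        reports.append(evaluate_case(pred, ref, case_id=row.id))
        mp = measure_jsw(pred, allow_inferior_fossa=allow_inferior_fossa)
        mr = measure_jsw(ref, allow_inferior_fossa=allow_inferior_fossa)
        pred_meas.append(mp)
        ref_meas.append(mr)
        if not (mp.ok and mr.ok):
            excluded.append({"id": row.id, "pred_status": mp.status, "ref_status": mr.status})

    excluded_ids = {e["id"] for e in excluded}
    ai = [m.jsw_mm for m in pred_meas if m.ok and m.id not in excluded_ids]
    ref_mm = [m.jsw_mm for m in ref_meas if m.ok and m.id not in excluded_ids]
    agreement = agreement_stats(ai, ref_mm) if len(ai) >= 2 else None
    if excluded:
        logger.warning("excluded %d case(s) from agreement: %s", len(excluded),
                       [e["id"] for e in excluded])

    result = {
        "metrics": reports_to_frame(reports),
        "summary": summarize(reports),
        "pred_measurements": pred_meas,
        "ref_measurements": ref_meas,
        "agreement": agreement,
        "excluded": excluded,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result["metrics"].to_csv(out_dir / "metrics.csv", index=False)
        result["summary"].to_csv(out_dir / "summary.csv", index=False)
        write_measurements_csv(pred_meas, out_dir / "jsw_ai.csv")
        write_measurements_csv(ref_meas, out_dir / "jsw_reference.csv")
        payload = {
            "agreement": agreement.as_dict() if agreement else None,
            "n_excluded": len(excluded),
            "excluded": excluded,
        }
        (out_dir / "agreement.json").write_text(json.dumps(payload, indent=2))
    return result
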