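"""Paired AI-vs-reference agreement statistics for JSW measurements.

Sign convention: the per-case difference is ``reference − AI``, so a
positive bias means the AI under-measures relative to the reference.
Limits of agreement are the classic Bland–Altman ``bias ± 1.96·SD`` with
the sample (n−1) standard deviation of the differences. The mean
percentage error uses the absolute per-case error with the reference as
denominator, so it is *not* invariant to swapping the two methods.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

LOA_MULTIPLIER = 1.96


@dataclass
class AgreementReport:
    """Summary statistics for paired method-comparison measurements (mm)."""

    n: int
    ai_mean: float
    ai_median: float
    ref_mean: float
    ref_median: float
    bias: float          # mean(ref − ai)
    sd_diff: float       # SD of (ref − ai), n−1 denominator
    loa_low: float       # bias − 1.96·sd_diff
    loa_high: float      # bias + 1.96·sd_diff
    mae: float           # mean |ai − ref|
    mpe: float           # mean |ai − ref| / ref × 100, percent
    rmse: float          # sqrt(mean (ref − ai)²)

    def as_dict(self) -> dict:
        return asdict(self)


def _paired_arrays(ai_mm: Sequence[float], ref_mm: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    ai = np.asarray(ai_mm, dtype=float)
    ref = np.asarray(ref_mm, dtype=float)
    if ai.shape != ref.shape or ai.ndim != 1:
        raise ValueError(f"ai and ref must be equal-length 1D series, got {ai.shape} vs {ref.shape}")
    if np.isnan(ai).any() or np.isnan(ref).any():
        raise ValueError("missing values in paired measurements")
    return ai, ref


def agreement_stats(ai_mm: Sequence[float], ref_mm: Sequence[float]) -> AgreementReport:
    """Compute the full agreement report for paired measurements.

    Requires n ≥ 2 (the SD of differences is otherwise undefined) and a
    strictly positive reference series (percentage-error denominator).
    """
    ai, ref = _paired_arrays(ai_mm, ref_mm)
    n = ai.size
    if n < 2:
        raise ValueError(f"need at least 2 paired measurements, got {n}")
    if (ref <= 0).any():
        raise ValueError("reference measurements must be strictly positive")
    diff = ref - ai
    bias = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    return AgreementReport(
        n=int(n),
        ai_mean=float(ai.mean()),
        ai_median=float(np.median(ai)),
        ref_mean=float(ref.mean()),
        ref_median=float(np.median(ref)),
        bias=bias,
        sd_diff=sd_diff,
        loa_low=bias - LOA_MULTIPLIER * sd_diff,
        loa_high=bias + LOA_MULTIPLIER * sd_diff,
        mae=float(np.abs(diff).mean()),
        mpe=float((np.abs(diff) / ref).mean() * 100.0),
        rmse=float(np.sqrt((diff ** 2).mean())),
    )


def bland_altman_points(ai_mm: Sequence[float], ref_mm: Sequence[float]
                        ) -> tuple[np.ndarray, np.ndarray, AgreementReport]:
    """Per-case (mean, difference) coordinates plus the report carrying the lines.

    Points are ``((ai+ref)/2, ref−ai)``; the horizontal lines of the
    plot are the report's ``bias``, ``loa_low`` and ``loa_high``.
    """
    ai, ref = _paired_arrays(ai_mm, ref_mm)
    report = agreement_stats(ai, ref)
    return (ai + ref) / 2.0, ref - ai, report


def concordance_points(ai_mm: Sequence[float], ref_mm: Sequence[float]
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-case (reference, AI) scatter coordinates for the concordance plot."""
    if len(ai_mm) == 0 and len(ref_mm) == 0:
        return np.empty(0), np.empty(0)
    ai, ref = _paired_arrays(ai_mm, ref_mm)
    return ref, ai


def plot_agreement(ai_mm: Sequence[float], ref_mm: Sequence[float], out_prefix) -> list[str]:
    """Write Bland–Altman and concordance plots as PNG; returns the file paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means, diffs, report = bland_altman_points(ai_mm, ref_mm)
    ref, ai = concordance_points(ai_mm, ref_mm)
    paths = []

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=18, color="tab:blue")
    ax.axhline(report.bias, color="tab:red", ls="--", label=f"bias {report.bias:.3f} mm")
    for y in (report.loa_low, report.loa_high):
        ax.axhline(y, color="tab:green", ls="--")
    ax.set_xlabel("mean of AI and reference (mm)")
    ax.set_ylabel("reference − AI (mm)")
    ax.legend(loc="best", fontsize=8)
    path = f"{out_prefix}_bland_altman.png"
    fig.tight_layout(); fig.savefig(path, dpi=150); plt.close(fig)
    paths.append(path)

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(ref, ai, s=18, color="tab:blue")
    lims = [min(ref.min(), ai.min()), max(ref.max(), ai.max())]
    ax.plot(lims, lims, color="tab:red", ls="--")
    ax.set_xlabel("reference (mm)")
    ax.set_ylabel("AI (mm)")
    path = f"{out_prefix}_concordance.png"
    fig.tight_layout(); fig.savefig(path, dpi=150); plt.close(fig)
    paths.append(path)
    return paths
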