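"""Seeded synthetic TMJ ultrasound phantoms with known joint-space width.

A phantom emulates the appearance the measurement pipeline relies on:
two hyperechoic (bright) curved bone-surface bands — a downward-opening
parabolic condyle band below and a concave fossa band above — separated
by a darker joint-space strip whose vertical width at the condyle apex
is an exactly known number of pixels. The image channel adds
multiplicative speckle and 8-bit quantization; the mask channel is
noise-free, so the ground-truth JSW is recovered exactly by the
measurement rule on the clean mask.

The speckle law (Rayleigh-modulated multiplicative noise) is a
qualitative stand-in for ultrasound speckle, not a physical acoustic
simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi

from .datamodel import GF, JS, MC, LabelMask, UltrasoundImage
from .jsw import PixelPoint, find_condyle_apex

# base intensities of the noiseless template (8-bit scale)
_INTENSITY = {"background": 40, MC: 210, GF: 190, JS: 15}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, noise and seed of one synthetic phantom.

    Parameters
    ----------
    image_size : (rows, cols)
    spacing_mm : physical pixel size, default 0.05 mm/px isotropic
    jsw_px : true vertical gap at the condyle apex, >= 2 pixels
    condyle_curvature, fossa_curvature : parabola coefficients (px^-1);
        larger values bend the bands away from the gap faster
    band_thickness_px : thickness of each bone band
    speckle_scale : multiplicative speckle amplitude in [0, 1)
    dropout_prob : probability of erasing a lateral fossa segment,
        emulating an incompletely visualized fossa
    apex_row, apex_col : condyle apex position; None picks a feasible
        default (apex centred horizontally, gap centred vertically)
    seed : RNG seed; a fixed spec+seed reproduces the sample bit-for-bit
    """

    image_size: tuple[int, int] = (128, 128)
    spacing_mm: tuple[float, float] = (0.05, 0.05)
    jsw_px: int = 30
    condyle_curvature: float = 0.04
    fossa_curvature: float = 0.02
    band_thickness_px: int = 6
    speckle_scale: float = 0.3
    dropout_prob: float = 0.0
    apex_row: int | None = None
    apex_col: int | None = None
    seed: int = 0


@dataclass
class PhantomSample:
    """A generated phantom: image, clean mask, and its ground truth."""

    image: UltrasoundImage
    mask: LabelMask
    true_jsw_px: int
    true_apex: PixelPoint
    spec: PhantomSpec


def _flat_halfwidth(curvature: float) -> int:
    """Largest |d| whose rounded parabolic offset is still zero."""
    # offsets are floor(k*d^2 + 0.5); zero iff k*d^2 < 0.5
    return int(math.floor(math.sqrt(0.5 / curvature - 1e-12)))


def _resolve_geometry(spec: PhantomSpec) -> tuple[int, int]:
    rows, cols = spec.image_size
    if spec.jsw_px < 2:
        raise ValueError(f"jsw_px must be >= 2, got {spec.jsw_px}")
    if spec.band_thickness_px < 1:
        raise ValueError("band_thickness_px must be >= 1")
    if spec.condyle_curvature <= 0 or spec.fossa_curvature <= 0:
        raise ValueError("curvatures must be strictly positive")
    if spec.jsw_px + 2 * spec.band_thickness_px >= rows:
        raise ValueError(
            f"infeasible geometry: gap {spec.jsw_px} px + two {spec.band_thickness_px} px "
            f"bands do not fit in {rows} rows")
    apex_row = spec.apex_row
    if apex_row is None:
        # centre the gap+bands block vertically
        apex_row = (rows + spec.jsw_px) // 2
    apex_col = spec.apex_col if spec.apex_col is not None else cols // 2
    if not (spec.jsw_px + spec.band_thickness_px <= apex_row
            and apex_row + spec.band_thickness_px <= rows):
        raise ValueError(f"infeasible geometry: apex_row {apex_row} leaves no room for the bands")
    flat = _flat_halfwidth(spec.condyle_curvature)
    if not (flat <= apex_col <= cols - 1 - flat):
        raise ValueError(
            f"infeasible geometry: the condyle's flat crest (±{flat} px around column "
            f"{apex_col}) exceeds the image; increase condyle_curvature or move apex_col")
    return apex_row, apex_col


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate one phantom sample; fully determined by ``spec`` (incl. seed)."""
    apex_row, apex_col = _resolve_geometry(spec)
    rows, cols = spec.image_size
    rng = np.random.default_rng(spec.seed)

    labels = np.zeros((rows, cols), dtype=np.uint8)
    d2 = (np.arange(cols) - apex_col).astype(float) ** 2
    condyle_top = apex_row + np.floor(spec.condyle_curvature * d2 + 0.5).astype(int)
    fossa_bottom = apex_row - spec.jsw_px - np.floor(spec.fossa_curvature * d2 + 0.5).astype(int)

    rr = np.arange(rows)[:, None]
    mc_band = (rr >= condyle_top) & (rr < condyle_top + spec.band_thickness_px)
    gf_band = (rr <= fossa_bottom) & (rr > fossa_bottom - spec.band_thickness_px)
    # the joint space exists only where both bone surfaces are inside the frame
    js_band = ((rr > fossa_bottom) & (rr < condyle_top)
               & (fossa_bottom >= 0) & (condyle_top <= rows - 1))
    labels[js_band] = JS
    labels[mc_band] = MC
    labels[gf_band] = GF

    if spec.dropout_prob > 0 and rng.random() < spec.dropout_prob:
        flat = _flat_halfwidth(spec.condyle_curvature)
        side = rng.integers(2)
        if side == 0 and apex_col - flat - 4 > 0:
            lo, hi = 0, int(rng.integers(1, apex_col - flat - 3))
        elif cols - (apex_col + flat + 4) > 1:
            lo, hi = int(rng.integers(apex_col + flat + 4, cols - 1)), cols
        else:
            lo = hi = 0
        labels[:, lo:hi][labels[:, lo:hi] == GF] = 0

    base = np.full((rows, cols), _INTENSITY["background"], dtype=float)
    for code in (JS, MC, GF):
        base[labels == code] = _INTENSITY[code]
    if spec.speckle_scale > 0:
        speckle = rng.rayleigh(scale=1.0, size=base.shape)
        base = base * (1.0 + spec.speckle_scale * (speckle - 1.0))
    pixels = np.clip(np.round(base), 0, 255).astype(np.uint8)

    sample_id = f"phantom-{spec.seed}"
    return PhantomSample(
        image=UltrasoundImage(pixels=pixels, spacing_mm=spec.spacing_mm, id=sample_id),
        mask=LabelMask(labels=labels, spacing_mm=spec.spacing_mm, id=sample_id),
        true_jsw_px=spec.jsw_px,
        true_apex=PixelPoint(apex_row, apex_col),
        spec=spec,
    )


def generate_cohort(n: int, jsw_range_mm: tuple[float, float] = (0.8, 4.0),
                    base_spec: PhantomSpec | None = None, seed: int = 0,
                    ) -> list[PhantomSample]:
    """Generate ``n`` phantoms with true JSW uniform in ``jsw_range_mm``.

    Apex position and band curvatures are randomized per sample within
    feasible ranges; per-sample seeds derive from the master ``seed``.
    The default geometry (128 px at 0.05 mm/px) accommodates gaps up to
    ~4.5 mm.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_spec if base_spec is not None else PhantomSpec()
    rows, cols = base.image_size
    row_mm = base.spacing_mm[0]
    max_jsw_px = rows - 2 * base.band_thickness_px - 9
    lo_px = max(2, int(round(jsw_range_mm[0] / row_mm)))
    hi_px = int(round(jsw_range_mm[1] / row_mm))
    if lo_px > hi_px or hi_px > max_jsw_px:
        raise ValueError(
            f"infeasible jsw range {jsw_range_mm} mm: {lo_px}..{hi_px} px "
            f"exceeds the feasible {max_jsw_px} px for {rows} rows")
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n):
        jsw_mm = rng.uniform(*jsw_range_mm)
        jsw_px = int(np.clip(round(jsw_mm / row_mm), lo_px, hi_px))
        k_c = rng.uniform(0.03, 0.10)
        k_f = rng.uniform(0.015, 0.05)
        flat = _flat_halfwidth(k_c)
        band = base.band_thickness_px
        slack = rows - (jsw_px + 2 * band)
        apex_row = jsw_px + band + int(rng.integers(2, max(3, slack - 2)))
        apex_row = min(apex_row, rows - band)
        apex_col = int(rng.integers(flat + 6, cols - flat - 6))
        spec = replace(base, jsw_px=jsw_px, condyle_curvature=k_c, fossa_curvature=k_f,
                       apex_row=apex_row, apex_col=apex_col,
                       seed=int(rng.integers(2 ** 31)))
        samples.append(generate_phantom(spec))
    return samples


def degrade_mask(mask: LabelMask, n_spurious: int = 2, max_spurious_frac: float = 0.4,
                 seed: int = 0) -> LabelMask:
    """Add spurious small components to each structure of a clean mask.

    Per non-empty class, ``n_spurious`` random connected blobs are grown
    on background pixels, each strictly smaller than
    ``max_spurious_frac`` of the class's largest component, placed away
    from the condyle apex column and never touching (8-adjacency) any
    existing pixel of the same class — so size-relative filtering at the
    default 60% threshold removes exactly the added blobs.
    """
    if not (0.0 < max_spurious_frac < 0.6):
        raise ValueError(f"max_spurious_frac must be in (0, 0.6), got {max_spurious_frac}")
    rng = np.random.default_rng(seed)
    out = mask.labels.copy()
    rows, cols = out.shape
    struct8 = ndi.generate_binary_structure(2, 2)

    apex = find_condyle_apex(mask)
    protected_cols = np.zeros(cols, dtype=bool)
    if apex is not None:
        lo, hi = max(0, apex.col - 3), min(cols, apex.col + 4)
        protected_cols[lo:hi] = True

    if n_spurious == 0:
        return mask.with_labels(out)

    for class_code in (MC, JS, GF):
        class_pixels = out == class_code
        if not class_pixels.any():
            continue
        comp, _ = ndi.label(class_pixels, structure=struct8)
        largest = int(np.bincount(comp.ravel())[1:].max())
        if largest < 2:  # no strictly-smaller spurious component exists
            continue
        # cap keeps blob growth cheap; any size in [1, 0.6·largest) works
        blob_size = max(1, min(int(max_spurious_frac * largest), 150))
        for _ in range(n_spurious):
            blob = _grow_blob(out, class_code, blob_size, protected_cols, rng)
            if blob is None:
                raise RuntimeError(
                    f"could not place a spurious component of class {class_code} "
                    "without touching existing structures")
            out[tuple(np.array(blob).T)] = class_code
    return mask.with_labels(out)


def _grow_blob(labels: np.ndarray, class_code: int, size: int,
               protected_cols: np.ndarray, rng: np.random.Generator):
    """Random-walk a 4-connected blob of ``size`` background pixels.

    The blob avoids protected columns and keeps a 1-px moat to existing
    pixels of the same class. Returns a list of (row, col) or None.
    """
    rows, cols = labels.shape
    near_class = ndi.binary_dilation(labels == class_code,
                                     structure=ndi.generate_binary_structure(2, 2))
    allowed = (labels == 0) & ~near_class & ~protected_cols[None, :]
    candidates = np.argwhere(allowed)
    if candidates.size == 0:
        return None
    for _ in range(60):  # restart attempts
        start = tuple(candidates[rng.integers(len(candidates))])
        blob = {start}
        frontier = [start]
        while len(blob) < size and frontier:
            r, c = frontier[rng.integers(len(frontier))]
            nbrs = [(r + dr, c + dc) for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))]
            rng.shuffle(nbrs)
            grown = False
            for nr, nc in nbrs:
                if 0 <= nr < rows and 0 <= nc < cols and (nr, nc) not in blob \
                        and allowed[nr, nc]:
                    blob.add((nr, nc))
                    frontier.append((nr, nc))
                    grown = True
                    break
            if not grown:
                frontier.remove((r, c))
        if len(blob) == size:
            return sorted(blob)
    return None
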