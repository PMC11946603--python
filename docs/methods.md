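# Methods

This note documents the models, conventions and numerical choices behind
`tmjjsw`, in the order the pipeline applies them.

## Coordinate and unit conventions

All arrays are row-major with row 0 at the top of the displayed ultrasound
frame. *Superior* (anatomically upward, toward the glenoid fossa) means a
smaller row index; this matches how TMJ frames are rendered, with the
superficial fossa above the condyle. Physical pixel size is carried as
`(row_spacing_mm, col_spacing_mm)` metadata — exported crops do not embed
it, so it must come from a JSON sidecar or a manifest CSV. When absent it
defaults to 1 mm/px with a logged warning; every millimetre-valued output
then silently means "pixels", so supplying real spacing is essential for
clinical interpretation.

## Holdout split

`make_split` assigns `floor(f·n)` cases to validation and test and every
remainder case to the training set. For 142 exams at fractions
(0.60, 0.15, 0.25) this yields 86/21/35. Plain rounding would assign
round(35.5) = 36 test exams and break the 86+21+35 decomposition, which is
why the floor-plus-remainder rule is used. The shuffle is a seeded
permutation; a fixed seed reproduces the split exactly.

## Connected-component postprocessing

Predicted masks are cleaned per class (background excluded): components are
labelled under the configured adjacency (8-neighbour by default,
4-neighbour optional since diagonal bridges change component counts), and a
component is kept iff its pixel count is **at least** 60% of the largest
component of that class. The boundary is inclusive — a component at exactly
the threshold survives. "Size" is pixel count; with uniform spacing this is
proportional to physical area. The operation is idempotent, never removes
the largest component, and only ever relabels pixels to background.

## Joint-space-width measurement

1. **Condyle apex** — the MC pixel with the minimum row index. Ties along
   the top row are broken by the median column; for an even tie count the
   lower of the two middle columns is taken (sorted index `(k−1)//2`), a
   deterministic choice where any median convention would do.
2. **Fossa match** — the GF pixel in the apex column with the largest row
   index strictly smaller than the apex row, i.e. the nearest fossa pixel
   directly above the apex. No fossa pixel in the column at all reports
   `no_fossa_in_column`; fossa pixels only below the apex report
   `fossa_not_superior`. An opt-in `allow_inferior_fossa` fallback takes
   the nearest in-column pixel by absolute distance, for grossly
   mis-segmented predictions.
3. **Distance** — the raw row-index difference between the two points,
   converted to mm by the row spacing. It is *not* reduced by one and does
   not interpolate sub-pixel boundaries; users comparing against other
   conventions should account for this. Anatomical absence is reported in
   the `status` field, never raised.

The measurement depends only on pixels in the apex column (plus the apex
itself), is equivariant under whole-mask translation, and is exact on the
synthetic phantoms by construction.

## Segmentation metrics

Per case and per class (MC, JS, GF), one-vs-rest:

- Dice = 2·TP / (2·TP + FP + FN); precision = TP/(TP+FP);
  recall = TP/(TP+FN).
- Volume similarity VS = 1 − |V_P − V_G| / (V_P + V_G) on pixel counts
  (the 2D analogue of volumes). The absolute value is required for
  VS ≤ 1; VS ≥ Dice always, since TP ≤ min(V_P, V_G).
- Hausdorff distance: the maximum of the two directed maximum
  nearest-neighbour distances between **boundary** pixel sets (foreground
  pixels 4-adjacent to background, image border counting as background),
  Euclidean with per-axis mm scaling. Boundary sets are used because the
  directed maxima of region sets are attained on boundaries and the
  quantity is meant as a boundary-deviation measure.

Degenerate classes: empty-vs-empty scores 1 on all ratios and HD 0
(vacuous agreement); empty-vs-non-empty scores 0 on Dice (the convention
that a fully missed structure is a 0.00, not missing data) and leaves
precision-or-recall and HD undefined (NaN). Summaries report per-class
mean ± SD with the sample (n−1) denominator; NaNs are excluded and their
count reported. Where a single overall Dice is needed, it is the mean over
classes of the per-class case means.

## Agreement statistics

Differences are `reference − AI`, so positive bias means the AI
under-measures. Reported: means/medians of both series, bias, SD of
differences (n−1), Bland–Altman limits bias ± 1.96·SD (the classic normal
approximation, not a t-quantile), MAE, RMSE, and mean percentage error
defined as mean(|ref − ai| / ref) × 100 — absolute per-case errors against
the reference; note MPE is therefore not invariant to swapping the
methods. The identity RMSE² = bias² + ((n−1)/n)·SD² holds exactly and is
used as a self-check. At least two pairs are required.

## Synthetic phantoms

A phantom is the minimal geometry exhibiting the features the pipeline
relies on: a bright downward-opening parabolic condyle band, a bright
concave fossa band above it, a darker joint-space strip of exactly known
vertical width at the apex column, on a darker background. Default frame:
128×128 px at 0.05 mm/px (bone-surface scale typical of high-frequency
linear probes); gaps of 0.8–4.0 mm (16–80 px) fit this frame, bracketing
the ~1.8 mm means reported for patient measurements. Parabola curvatures,
apex position and per-sample seeds are randomized per cohort sample.
Integer rounding of the parabolic offsets produces a flat crest of tied
top-row pixels symmetric about the apex column, so the median-column rule
recovers the constructed apex exactly; the generator validates that this
crest fits inside the frame and raises `infeasible geometry` otherwise.

The image channel adds multiplicative Rayleigh-modulated speckle
(`img·(1 + s·(R−1))`, R with mode 1) and 8-bit quantization. This is a
qualitative stand-in for ultrasound speckle — no attenuation,
reverberation or refraction shadowing — so passing tests demonstrate
correctness of the mask-space algorithms and trainability on
band-structured images, not performance on clinical data. Masks are
generated noiselessly; noise lives only in the image channel.

`degrade_mask` adds, per class, random-walk blobs strictly smaller than
the filter threshold fraction of the class's largest component, grown on
background with a 1-px moat to same-class pixels and kept away from the
apex column. By construction, size-relative filtering at the default 60%
threshold restores the clean mask exactly — the basis of the end-to-end
recovery checks.

## Network and training harness

The segmenter is a 2D residual U-Net: encoder feature channels
[16, 32, 64, 128] with stride-2 downsampling, 16 convolutional subunits
per residual block (one residual skip per block, projection convolutions
where shape changes), affine-free instance normalization, single-slope
PReLU, dropout 0.3 in NDA (norm–dropout–activation) order; decoder levels
are transposed convolutions followed by one residual subunit, with
channel-concatenating skip connections. Input H×W must be divisible by
2^(levels−1); inference pads symmetrically with zeros and crops back.
Intensities are normalized by 255. The default network has 3,147,469
trainable parameters (reported by `n_parameters()`).

The layer library is written directly in numpy (float64, NCHW, im2col
convolutions) with hand-derived backpropagation; every backward pass is
validated against central-difference gradients in the test suite. The
loss is soft Dice on softmax probabilities, ε = 1e-5, background excluded
by default (configurable). Optimization: Adam at 1e-3, batch 2,
reduce-on-plateau on validation mean Dice (factor 0.5, patience 10 —
unspecified upstream, hence configurable), per-epoch best-checkpoint
selection by validation mean Dice, 150 epochs in the full recipe.
Ensembling averages softmax probabilities across runs before the argmax;
it degenerates exactly to single-run prediction and preserves per-pixel
normalization (majority voting would do neither).

Test- and script-scale runs use a toy recipe chosen for learnability
within seconds on one CPU: channels (16, 32), 2 subunits, dropout 0.1,
lr 3e-3, 10 epochs, batch 2, on 64×64 phantoms (16 train / 4 validation /
5 held-out). A single such run's held-out Dice varies with the seed; the
acceptance script therefore trains three independently seeded runs and
ensembles them, the same stabilization the full protocol prescribes.

## Known limitations

- The phantom is not an acoustic simulation; models trained on it do not
  transfer to clinical frames.
- The measurement rule is strictly vertical and single-column; oblique
  joint orientations bias it, and no sub-pixel boundary estimation is
  attempted.
- The Hausdorff implementation enumerates boundary pixels; for very large
  masks the KD-tree based directed distances dominate runtime but remain
  exact.
- Training the full-size network on real datasets is supported but slow on
  CPU (the numpy backend has no GPU path); the harness is intended for
  method-level validation, with the architecture and recipe faithfully
  reproduced at reduced scale.
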