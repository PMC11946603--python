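# tmjjsw

Tools for AI-assisted ultrasonographic assessment of the
temporomandibular joint (TMJ): postprocessing of multi-class
segmentation masks, automated joint-space-width (JSW) measurement,
segmentation-quality metrics, method-comparison (Bland–Altman)
statistics, a seeded synthetic phantom generator, and a residual U-Net
training/inference harness.

The package is aimed at researchers evaluating segmentation models on
TMJ ultrasound. Frames are 8-bit grayscale crops segmented into three
structures — the **mandibular condyle (MC)**, the **joint space (JS)**
and the **glenoid fossa (GF)** — and the clinically relevant quantity is
the vertical width of the joint space, whose narrowing accompanies
degenerative TMJ disease.

## What it computes

**Postprocessing.** Per non-background class, connected components are
labelled (8-neighbour by default) and a component is kept iff its pixel
count is at least 60% of the class's largest component; everything else
becomes background. This removes spurious islands a segmentation model
produces while preserving structures of comparable size.

**JSW measurement.** The condyle apex is the MC pixel with the smallest
row index (superior-most; ties broken by the median column). The
matching fossa point is the nearest GF pixel directly above the apex in
the same column. The JSW is the vertical distance between the two
points:

    JSW_px = apex_row − fossa_row,    JSW_mm = JSW_px × row_spacing_mm

Missing anatomy is reported as a status (`no_condyle`,
`no_fossa_in_column`, `fossa_not_superior`), never an exception.

**Metrics.** Per class, one-vs-rest: Dice `2|P∩G|/(|P|+|G|)`, precision
`TP/(TP+FP)`, recall `TP/(TP+FN)`, volume similarity
`1 − |V_P−V_G|/(V_P+V_G)`, and the symmetric Hausdorff distance
`max(sup_p inf_g d(p,g), sup_g inf_p d(g,p))` between boundary pixel
sets in mm. Summaries report mean ± SD (n−1) per class.

**Agreement.** For paired AI-vs-reference measurements: bias
(mean of `ref − ai`), SD of differences, 95% limits of agreement
`bias ± 1.96·SD`, MAE, RMSE and mean percentage error, plus
Bland–Altman and concordance plot data.

**Phantoms.** Seeded synthetic frames with two bright curved
bone-surface bands separated by a darker gap of exactly known width,
with multiplicative speckle in the image channel and clean ground-truth
masks — the substrate for all exact-recovery tests.

**Model harness.** A 2D residual U-Net (feature channels
[16, 32, 64, 128], stride-2 levels, 16 residual subunits per block,
instance norm, PReLU, dropout 0.3) with soft-Dice/softmax training,
Adam + reduce-on-plateau, validation-Dice checkpointing and mean-softmax
ensembling — implemented in pure numpy with hand-written
backpropagation, gradient-checked in the test suite.

## Worked example

```python
from tmjjsw import (generate_cohort, degrade_mask, filter_components,
                    measure_jsw, evaluate_case, summarize, agreement_stats)

cohort = generate_cohort(30, jsw_range_mm=(0.8, 4.0), seed=7)
m = measure_jsw(cohort[0].mask)
print(m.apex, m.fossa_point, m.jsw_px, m.jsw_mm)

raw = [degrade_mask(s.mask, n_spurious=2, max_spurious_frac=0.4, seed=i)
       for i, s in enumerate(cohort)]            # masks with spurious islands
preds = [filter_components(p) for p in raw]      # 60% component filter
summary = summarize([evaluate_case(p, s.mask) for p, s in zip(preds, cohort)])

ai = [measure_jsw(p).jsw_mm for p in preds]
ref = [measure_jsw(s.mask).jsw_mm for s in cohort]
rep = agreement_stats(ai, ref)
```

Output (abridged):

```
case 0: apex=(110,33), fossa=(54,33), JSW = 56 px = 2.80 mm (constructed: 56 px)

before postprocessing:
class  dice_mean  dice_sd  hd_mm_mean
   MC      0.718    0.008       3.904
   JS      0.934    0.033       2.426
   GF      0.735    0.029       3.811

after postprocessing (60% component filter):
class  dice_mean  dice_sd  hd_mm_mean
   MC        1.0      0.0         0.0
   JS        1.0      0.0         0.0
   GF        1.0      0.0         0.0

agreement (n=30): bias = 0.000 mm, SD = 0.000 mm, MAE = 0.000 mm,
MPE = 0.00%, RMSE = 0.000 mm
```

The spurious components depress Dice and inflate the Hausdorff distance;
the size-relative filter removes exactly the added islands, restoring
the reference masks, so the downstream JSW measurements agree perfectly.
On real model predictions the residual disagreement quantifies
segmentation error.

## Command line

```sh
tmjjsw simulate --n 100 --out cohort/ --seed 7        # phantom dataset
tmjjsw measure  --masks cohort/masks --manifest cohort/manifest.csv --out jsw.csv
tmjjsw evaluate --pred preds/ --ref cohort/masks --manifest cohort/manifest.csv \
                --out metrics.csv --summary summary.csv
tmjjsw agree    --ai jsw_ai.csv --ref jsw_ref.csv --out report.json --plots plots/
tmjjsw full-eval --pred preds/ --ref cohort/masks --manifest cohort/manifest.csv --out out/
tmjjsw train    --manifest cohort/manifest.csv --out run1/ --channels 16,32 \
                --res-units 2 --epochs 10 --seed 1
tmjjsw segment  --runs run1 run2 run3 --images cohort/images --out preds/
```

Pixel spacing comes from the manifest (`row_spacing_mm,col_spacing_mm`
columns) or a `<stem>.json` sidecar with `"spacing_mm": [row, col]`.

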