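# pectseg

Automatic pectoral-muscle segmentation for MLO-view mammograms.

In a mediolateral-oblique (MLO) mammogram the pectoral muscle (PM) shows as
a bright wedge in the top chest-wall corner. Because its intensity is close
to that of masses and microcalcifications, computer-aided detection (CAD)
pipelines must delineate and exclude it before lesion search — and on
scanned-film archives such as MIAS that has to survive blank scanner
margins, film labels, low contrast, blurred muscle boundaries and sharp
folded-skin creases that mimic them.

`pectseg` is a library + CLI for exactly that preprocessing step, aimed at
mammography CAD researchers. The boundary is modelled as a quadratic in the
row coordinate,

    x = a·y² + b·y + c        (y = row, x = column, origin top-left),

and estimated by a staged pipeline:

1. margin/artifact removal (column line profile + largest connected
   component), breast windowing, CLAHE, median denoising;
2. a distance-weighted oblique edge map — a diagonal compass kernel after
   light Gaussian smoothing (favouring the blurred PM edge over sharp skin
   folds), multiplied by linear wedge weights anchored at the muscle corner;
3. Otsu binarization, skin-line suppression, probabilistic Hough segments
   gated by laterality-specific angle ranges (100°–170° / 280°–350°),
   linked into chains; the longest chain is the PM outline;
4. RANSAC: K iterations of {sample 3 points, fit the quadratic, count
   points within the residual tolerance ε}; the largest consensus set wins
   and is polished by least squares, then rasterised into the PM mask.

A synthetic phantom generator reproduces the assumed scene structure with
pixel-exact ground truth, so the entire method is developed, tested and
benchmarked without downloading any image database, and an evaluation
module scores predicted against reference masks with FP%, FN% (relative to
the reference muscle area), Jaccard concordance, and the
good / acceptable / unacceptable bands (> 90% / > 50% / otherwise).

## Worked example

```python
from pectseg import phantom, segment, evaluate

spec = phantom.PhantomSpec()          # 256x256 left-sided phantom, default conditions
img, truth, breast = phantom.generate(spec)
res = segment(img)                    # full pipeline, default config
a, b, c = res.curve.coefficients
print(f"laterality : {res.laterality.name}")
print(f"curve      : x = {a:.2e}*y^2 + {b:.3f}*y + {c:.1f}  (cropped frame)")
print(f"consensus  : {res.curve.consensus} chain pixels within eps")
ev = evaluate.evaluate_pair(res.mask, truth)
print(f"FP {ev.fp_pct:.2f}%  FN {ev.fn_pct:.2f}%  concordance {ev.concordance_pct:.2f}%  -> {ev.category.value}")
```

prints

```
laterality : MUSCLE_UPPER_LEFT
curve      : x = 2.34e-04*y^2 + -0.429*y + 105.7  (cropped frame)
consensus  : 1645 chain pixels within eps
FP 0.13%  FN 0.27%  concordance 99.61%  -> good
```

The detected side is the left chest wall; the fitted quadratic deviates
from the phantom's true boundary (a = 3·10⁻⁴, c = 118 before the 12-px
margin crop) by about a pixel, and the resulting mask misses 0.27% of the
true muscle while adding 0.13% false muscle — "good" concordance.

The same flow from the shell:

```sh
pectseg phantom --n 10 --seed 7 --out scenes/
pectseg segment scenes/*.pgm --out masks/ --orientation auto
pectseg eval --pred masks/ --ref scenes/ --out report/
```

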