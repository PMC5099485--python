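# Methods

## Problem and model

In a mediolateral-oblique (MLO) mammogram the pectoral muscle appears as a
bright wedge in the top chest-wall corner. Its intensity overlaps that of
masses and microcalcifications, so computer-aided detection must exclude it
before lesion search. `pectseg` segments that wedge in MIAS-style scanned
film frames (8-bit, blank digitisation margins, film-label artifacts) by
modelling its lower boundary as a quadratic curve in frame coordinates,

    x = a·y² + b·y + c,     y = row (px, 0 at top), x = column (px),

which is single-valued in `y` because the boundary is near-vertical. The
method exploits three empirical regularities: the muscle is brighter than
surrounding tissue; its film boundary is *blurred* while the main
confounder — a folded-skin crease — is *sharp* but lies farther from the
muscle corner; and the muscle edge is the longest oblique edge in the upper
breast.

## Pipeline

1. **Margin removal.** The column-sum line profile is thresholded at
   `noise floor + 2% of profile range` (floor = median of the ten lowest
   column sums). A column is blank only if it also falls below half the
   median column mass; this guard makes frames without blank margins pass
   through unchanged. Rows are never cropped.
2. **Breast mask.** Global Otsu threshold on the cropped frame, one pass of
   3×3 morphological closing (erosion seeded with foreground at the frame
   border so the chest wall is not shaved), hole filling, then retention of
   the largest 8-connected component — film labels and scanner artifacts are
   smaller disconnected regions. Equal-area ties go to the component whose
   first pixel is earliest in raster order.
3. **Laterality.** The muscle side is the side with more breast-mask mass
   (centre column of odd-width frames excluded so the rule commutes with
   mirroring); an exact tie raises and the caller must pass the orientation.
4. **Enhancement.** Intensities inside the breast are windowed linearly to
   [0, 255]; contrast-limited adaptive histogram equalization (default 8×8
   tiles, clip 0.01 of the tile pixel count per bin, bilinear blending of
   tile mappings, one-bin tiles map identically) raises edge contrast; a
   3×3 median filter removes impulse noise. Background stays 0.
5. **Edge map.** Gaussian pre-smoothing (σ = 1, configurable) deliberately
   penalises sharp creases relative to the already-blurred muscle edge; the
   image is convolved with a diagonal compass kernel
   `[[2,1,0],[1,0,-1],[0,-1,-2]]` (column-mirrored and negated for
   upper-right muscles), the absolute response is multiplied by linear wedge
   weights `max(0, 1 − d/D)` anchored at the muscle corner (d = Euclidean
   distance to the corner, D = frame diagonal), and rescaled to [0, 255].
   The wedge suppresses folded-skin edges, which sit farther from the
   corner.
6. **Candidates.** Otsu binarization of the edge map; edge pixels within
   5 px of the breast-mask boundary are erased (skin-line suppression via
   8-connected erosion); 8-connected components whose centroid lies in the
   lower half of the breast's row extent are discarded.
7. **Line linking.** Progressive probabilistic Hough transform (θ over
   [0°, 180°) at 1°, vote threshold 30, minimum length 20 px, maximum gap
   5 px) returns directed segments oriented row-increasing. Angles are
   measured counterclockwise from the +column axis with +row down. The
   laterality gates are inclusive: [100°, 170°] for a muscle-upper-right
   frame and [280°, 350°] for muscle-upper-left. The two ranges are
   congruent mod 180°, so they only separate *directed* segments: the
   pipeline gates row-decreasing (reversed) segments for upper-left scenes
   and column-mirrored row-increasing segments for upper-right scenes, then
   keeps the corresponding originals. Gated segments whose directed angles
   differ by ≤ 10° and whose closest endpoints are ≤ 20 px apart are linked
   transitively into chains; chain length = member lengths + bridged gaps
   (minimum spanning tree of the connection graph). The longest chain is
   taken as the muscle outline — folds are shorter.
8. **RANSAC fit.** On the chain's rasterized pixels: repeat K = 1000 times
   {draw 3 points uniformly without replacement, fit the quadratic exactly,
   count points with column residual ≤ eps}; the largest consensus wins
   (ties to the earlier iteration), then a least-squares refit on the full
   inlier set polishes the model (disableable). The curve is rasterised
   (boundary pixels included, rounding half-up), intersected with the
   breast mask, and mapped back to original frame coordinates.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `margins.floor_fraction` | 0.02 | fraction of profile range | separates blank scanner margins from dim background columns |
| `clahe.blocks` / `clahe.clip_limit` | 8×8 / 0.01 | tiles / fraction of tile count per bin | enough local adaptation to lift a low-contrast muscle edge without amplifying flat-region noise past the median filter |
| `edge.presmooth_sigma` | 1.0 | px | biases the detector toward blurred boundaries (muscle) over sharp creases |
| `skin.band_px` | 5 | px | width of the skin-line suppression collar |
| `hough.*` | 30 / 20 / 5 | votes / px / px | fragments of a ≳200 px boundary at 256×256; speckle never reaches 20 collinear pixels |
| `chain.angle_tol` / `chain.gap_tol` | 10° / 20 px | — | bridges Hough fragmentation without merging the fold (which sits ≳30 px away) |
| `ransac.n`, `ransac.K` | 3, 1000 | points, iterations | exact minimal quadratic sample; K ≫ the ~10³ draws needed at 30% contamination |
| `ransac.eps` (module default) | 3 | px | inlier tolerance for generic point sets |
| `ransac.eps` (pipeline default) | 8 | px | see below |
| `seed` | 0 | — | drives Hough sampling and RANSAC draws; fixed seed ⇒ byte-identical output |

**Why the pipeline overrides eps to 8 px.** The Otsu-binarized edge band of
a boundary blurred at σ ≈ 3 px is ~8 px wide, and the chain pixels are
Hough-line rasters scattered across it. With eps = 3 the maximal-consensus
quadratic can settle anywhere inside the band (±1.5 px, depending on which
random segments the Hough transform emitted), which costs ~2% area error
and breaks mirror symmetry at the percent level. An inlier tolerance
spanning the band half-width makes the final refit average the band
symmetrically about its centre — which coincides with the true boundary,
because Gaussian blur is symmetric. Both area error and left/right
asymmetry drop below 1%. The module-level `RansacConfig` keeps eps = 3 for
generic point clouds.

## Synthetic phantoms

`phantom.generate` renders the structure the algorithm assumes: dark
background (mean 8), blank 12 px side margins, a semi-elliptical breast
(mean 100) anchored to the chest-wall edge, a muscle wedge (mean 170)
bounded by a known quadratic, the muscle boundary blurred at σ = 3 px,
optionally a sharp (σ = 0.5 px) skin-fold line shorter than the muscle edge
and a bright film-label rectangle outside the breast, plus additive
Gaussian noise (σ = 5, i.e. every intensity gap ≥ 3 SD). Ground truth is
the noiseless, pre-blur analytic muscle region — the blur models
acquisition, not anatomy. `default_suite(n, master_seed)` stratifies over
laterality, curvature a ∈ {0, ±5·10⁻⁴} (boundaries kept ≥ 10 px inside the
frame for every row), fold/label presence, and contrast jitter; test frames
are 256×256 so the full 50-case suite segments in a few seconds.

**What phantoms do not emulate:** parenchymal texture, vessels and ducts
crossing the boundary, nonlinear film response, positioning variation where
the muscle is absent or reaches past mid-height, and lesions. Passing the
phantom suite therefore demonstrates the pipeline's mechanics (geometry,
confounder rejection, determinism), not clinical-grade accuracy on real
film; measuring real-film error rates requires the MIAS archive itself,
which this package deliberately does not download.

## Numerical choices and degeneracies

- Otsu's threshold is computed in exact integer arithmetic (cross-multiplied
  between-class variance), so the smallest-argmax tie-break never depends on
  floating-point rounding; a single-intensity image raises, except in breast
  masking where a constant frame degrades to all-foreground so the failure
  surfaces later as a structured error.
- CLAHE tiles with one occupied histogram bin use the identity mapping;
  a constant image is a fixed point for every tiling and clip limit.
- Rounding is floor(x + 0.5) (half-up) throughout; boundary pixels belong
  to the muscle mask.
- The wedge of a 1×1 frame is defined as weight 1.
- Equal-length chains prefer larger pixel support, then input order; equal
  consensus prefers the earlier RANSAC iteration.
- All randomness (Hough shuffling, RANSAC draws) flows from one config seed;
  two runs on the same input are byte-identical.

## Known limitations

- The angle gates assume the muscle edge is oblique; a nearly
  vertical (90°) or nearly horizontal boundary is rejected by design.
- A muscle whose boundary is not a function of the row (strong S-shapes)
  violates the quadratic model.
- The laterality vote fails on pathological frames with exactly balanced
  mass; callers must then pass `--orientation`.
- Curve extrapolation below the last chain pixel follows the fitted
  quadratic; anatomically implausible extrapolations are clipped only by
  the breast mask.
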