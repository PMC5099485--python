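"""Synthetic MLO mammogram phantoms with pixel-exact ground truth.

A phantom emulates the structure the segmentation algorithm assumes in
MIAS-style scanned film: a dark background with blank side margins, a
semi-elliptical breast of intermediate intensity anchored to the chest-wall
side, a brighter pectoral wedge bounded by a gently curved quadratic edge
descending from the top corner, a *blurred* pectoral edge versus an
optional *sharp* (and shorter) folded-skin crease inside the breast, an
optional film-label rectangle outside the breast, and additive Gaussian
noise.  Ground truth is the noiseless, pre-blur muscle region: the blur
models acquisition, not anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as draw_line

from .errors import ParameterError
from .types import GrayImage, Laterality

__all__ = ["SkinFold", "LabelArtifact", "PhantomSpec", "generate", "default_suite"]


@dataclass(frozen=True)
class SkinFold:
    """A sharp, short linear crease inside the breast (segmentation confounder)."""

    p0: tuple[int, int]
    p1: tuple[int, int]
    contrast: float = 40.0
    blur_sigma: float = 0.5


@dataclass(frozen=True)
class LabelArtifact:
    """A bright film-label rectangle outside the breast."""

    top_left: tuple[int, int]
    size: tuple[int, int] = (28, 44)
    intensity: int = 210


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic frame.

    ``curve`` holds (a, b, c) of the true boundary ``x = a·y² + b·y + c`` in
    frame coordinates.  Intensities are (muscle, breast, background) means
    and must be strictly decreasing — the premise that makes the muscle the
    bright wedge.  When a skin fold is present its blur must be sharper than
    the pectoral edge blur.
    """

    height: int = 256
    width: int = 256
    laterality: Laterality = Laterality.MUSCLE_UPPER_LEFT
    curve: tuple[float, float, float] = (3e-4, -0.441, 118.0)
    intensities: tuple[float, float, float] = (170.0, 100.0, 8.0)
    pm_edge_blur_sigma: float = 3.0
    skin_fold: SkinFold | None = None
    margins: tuple[int, int] = (12, 12)
    label_artifact: LabelArtifact | None = None
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        mu, br, bg = self.intensities
        if not (mu > br > bg >= 0) or mu > 255:
            raise ParameterError("need muscle_mean > breast_mean > background_mean in [0,255]")
        if self.height < 32 or self.width < 32:
            raise ParameterError("phantom frames must be at least 32x32")
        if self.margins[0] < 0 or self.margins[1] < 0:
            raise ParameterError("margins must be >= 0")
        if self.margins[0] + self.margins[1] >= self.width:
            raise ParameterError("margins leave no interior")
        if self.skin_fold is not None and not (
            self.pm_edge_blur_sigma > self.skin_fold.blur_sigma
        ):
            raise ParameterError("pectoral edge blur must exceed skin-fold blur")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")


def _breast_ellipse(spec: PhantomSpec) -> np.ndarray:
    """Semi-elliptical breast anchored to the chest-wall interior edge."""
    h, w = spec.height, spec.width
    ml, mr = spec.margins
    interior_w = w - ml - mr
    cy = 0.35 * h
    ry = 0.55 * h
    rx = 0.72 * interior_w
    if spec.laterality is Laterality.MUSCLE_UPPER_LEFT:
        cx = float(ml)
    else:
        cx = float(w - 1 - mr)
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    inside = ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0
    interior = (cc >= ml) & (cc <= w - 1 - mr)
    return (inside & interior).astype(np.uint8)


def _muscle_truth(spec: PhantomSpec, breast: np.ndarray) -> np.ndarray:
    """Analytic muscle half-region (boundary pixels included) ∩ breast."""
    a, b, c = spec.curve
    y = np.arange(spec.height, dtype=np.float64)
    xb = np.floor(np.clip(a * y * y + b * y + c, -2.0, spec.width + 1.0) + 0.5)
    cols = np.arange(spec.width)[None, :]
    if spec.laterality is Laterality.MUSCLE_UPPER_LEFT:
        half = cols <= xb[:, None]
    else:
        half = cols >= xb[:, None]
    return (half & breast.astype(bool)).astype(np.uint8)


def generate(spec: PhantomSpec):
    """Render one phantom.

    Returns ``(GrayImage, muscle_truth, breast_truth)``; fully deterministic
    given ``spec.seed``.
    """
    mu, br, bg = spec.intensities
    breast = _breast_ellipse(spec)
    truth = _muscle_truth(spec, breast)

    muscle_soft = truth.astype(np.float64)
    if spec.pm_edge_blur_sigma > 0:
        muscle_soft = ndi.gaussian_filter(muscle_soft, spec.pm_edge_blur_sigma, mode="nearest")

    img = np.full((spec.height, spec.width), float(bg))
    img += breast * ((br - bg) + (mu - br) * muscle_soft)

    if spec.skin_fold is not None:
        sf = spec.skin_fold
        band = np.zeros(img.shape)
        rr, cc = draw_line(sf.p0[0], sf.p0[1], sf.p1[0], sf.p1[1])
        band[rr, cc] = 1.0
        band = ndi.binary_dilation(band > 0, structure=np.ones((3, 3))).astype(np.float64)
        if sf.blur_sigma > 0:
            band = ndi.gaussian_filter(band, sf.blur_sigma, mode="nearest")
        img += breast * sf.contrast * band

    if spec.label_artifact is not None:
        la = spec.label_artifact
        r0, c0 = la.top_left
        r1, c1 = r0 + la.size[0], c0 + la.size[1]
        rect = np.zeros(img.shape, dtype=bool)
        rect[r0:r1, c0:c1] = True
        img[rect & ~breast.astype(bool)] = float(la.intensity)

    ml, mr = spec.margins
    if ml:
        img[:, :ml] = 0.0
    if mr:
        img[:, -mr:] = 0.0

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)

    pixels = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    gi = GrayImage(pixels, source_id=f"phantom-{spec.laterality.value}-{spec.seed}")
    return gi, truth, breast


def _mirror_curve(curve, width: int):
    a, b, c = curve
    return (-a, -b, float(width - 1) - c)


def default_suite(n: int, master_seed: int = 7):
    """A deterministic, stratified list of ``n`` phantom specs.

    Alternates laterality, cycles boundary curvature a ∈ {0, +5e-4, −5e-4},
    toggles skin folds and film labels, and jitters contrast and boundary
    placement from ``master_seed``.  Every curve keeps its boundary at least
    10 px inside the frame for all rows.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(master_seed)
    specs = []
    for i in range(n):
        h = w = 256
        lat = Laterality.MUSCLE_UPPER_LEFT if i % 2 == 0 else Laterality.MUSCLE_UPPER_RIGHT
        a = (0.0, 5e-4, -5e-4)[i % 3]
        c = float(rng.uniform(0.42 * w, 0.50 * w))
        x_end = float(rng.uniform(0.08 * w, 0.16 * w))
        b = (x_end - c - a * (h - 1) ** 2) / (h - 1)
        curve = (a, b, c)
        # analytic safety margin: extremum inside the row range must stay in-frame
        ys = np.arange(h, dtype=np.float64)
        xb = a * ys * ys + b * ys + c
        if xb.min() < 10 or xb.max() > w - 10:
            raise ParameterError("suite curve leaves the 10 px safety band")
        muscle = float(rng.uniform(160, 185))
        breast = float(rng.uniform(95, 110))
        fold = None
        if i % 2 == 0 or i % 5 == 3:
            y0, y1 = 36, 96
            off = float(rng.uniform(34, 48))
            p0 = (y0, int(round(a * y0 * y0 + b * y0 + c + off)))
            p1 = (y1, int(round(a * y1 * y1 + b * y1 + c + off)))
            fold = SkinFold(p0=p0, p1=p1, contrast=float(rng.uniform(30, 50)))
        label = None
        if i % 4 < 2:
            label = LabelArtifact(top_left=(12, w - 70))
        if lat is Laterality.MUSCLE_UPPER_RIGHT:
            curve = _mirror_curve(curve, w)
            if fold is not None:
                fold = SkinFold(
                    p0=(fold.p0[0], w - 1 - fold.p0[1]),
                    p1=(fold.p1[0], w - 1 - fold.p1[1]),
                    contrast=fold.contrast,
                    blur_sigma=fold.blur_sigma,
                )
            if label is not None:
                label = LabelArtifact(top_left=(12, 26))
        specs.append(
            PhantomSpec(
                height=h,
                width=w,
                laterality=lat,
                curve=curve,
                intensities=(muscle, breast, 8.0),
                skin_fold=fold,
                label_artifact=label,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs
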