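"""End-to-end pectoral muscle segmentation.

Stage order (each stage's contract lives in its own module):

1. preprocess — crop blank margins, breast mask via histogram threshold,
   largest-component artifact removal, laterality, intensity windowing,
   CLAHE, median denoise;
2. edges — distance-weighted oblique edge map, Otsu binarization, skin-line
   suppression, upper-breast candidate selection;
3. lines — probabilistic Hough segments, laterality angle gate, chain
   linking, longest chain;
4. ransac — quadratic boundary fit on the chain pixels, curve rasterised to
   a mask, intersected with the breast mask and mapped back to the original
   frame through the crop offset.

Every intermediate is collected into a diagnostics dict for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import edges as E
from . import lines as L
from . import preprocess as P
from . import ransac as R
from .config import PipelineConfig
from .errors import PectsegError, SegmentationFailure
from .io import read_image
from .ransac import QuadraticCurve
from .types import GrayImage, Laterality, as_pixels

__all__ = ["SegmentationResult", "segment"]


@dataclass
class SegmentationResult:
    """Final mask in original-frame coordinates plus the fitted curve.

    The curve coefficients live in cropped-frame coordinates; add
    ``crop_offset[1]`` to a boundary column to reach the original frame.
    """

    mask: np.ndarray
    curve: QuadraticCurve
    laterality: Laterality
    crop_offset: tuple[int, int]
    diagnostics: dict = field(repr=False, default_factory=dict)


def _stage(name):
    """Decorator-free helper: re-raise stage errors with stage context."""
    class _Ctx:
        def __init__(self, diag):
            self.diag = diag

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, PectsegError) and not isinstance(
                exc, SegmentationFailure
            ):
                raise SegmentationFailure(name, exc) from exc
            return False

    return _Ctx


def segment(image, config: PipelineConfig | None = None,
            orientation: Laterality | None = None) -> SegmentationResult:
    """Segment the pectoral muscle in one MLO frame.

    ``image`` is a file path, :class:`GrayImage`, or uint8 array.  Stage
    failures raise :class:`SegmentationFailure` carrying the stage name and
    the underlying domain error.
    """
    cfg = config or PipelineConfig()
    if isinstance(image, (str, bytes)) or hasattr(image, "__fspath__"):
        image = read_image(image)
    arr = as_pixels(image)
    full_h, full_w = arr.shape
    diag: dict = {"input_shape": (full_h, full_w)}

    with _stage("preprocess")(diag):
        cropped, crop_offset = P.remove_blank_margins(arr, cfg.margins_floor_fraction)
        diag["crop_offset"] = crop_offset
        raw_mask = P.segment_breast(cropped)
        breast = P.remove_artifacts(raw_mask)
        diag["breast_area"] = int(breast.sum())
        lat = orientation or P.detect_laterality(cropped, breast)
        diag["laterality"] = lat.name
        windowed = P.window_breast(cropped, breast)
        enhanced = P.clahe(windowed, cfg.clahe_clip_limit, cfg.clahe_blocks)
        denoised = P.median_denoise(enhanced, cfg.median_window)
        diag["enhanced"] = denoised

    with _stage("edges")(diag):
        kernel = E.make_oblique_kernel(lat, override=cfg.edge_kernel)
        wedge = E.wedge_weights(*denoised.shape, lat)
        emap = E.edge_map(denoised, kernel, wedge, presmooth_sigma=cfg.edge_presmooth_sigma)
        ethr = E.otsu_threshold(emap)
        diag["edge_threshold"] = ethr
        ebin = (emap > ethr).astype(np.uint8)
        ebin = E.suppress_skin_line(ebin, breast, band=cfg.skin_band_px)
        rows = np.flatnonzero(breast.any(axis=1))
        breast_top, breast_bottom = int(rows[0]), int(rows[-1])
        candidates = E.select_candidates(
            ebin, breast_top, breast_bottom, cfg.candidates_height_fraction
        )
        diag["n_candidates"] = len(candidates)
        cand_mask = np.zeros_like(ebin)
        for cand in candidates:
            cand_mask[cand.pixels[:, 0], cand.pixels[:, 1]] = 1
        diag["edge_mask"] = cand_mask

    with _stage("lines")(diag):
        segs = L.hough_segments(
            cand_mask,
            vote_threshold=cfg.hough_vote_threshold,
            min_length=cfg.hough_min_length,
            max_gap=cfg.hough_max_gap,
            seed=cfg.seed,
        )
        diag["n_segments"] = len(segs)
        gated = L.gate_for_scene(segs, lat, cand_mask.shape[1])
        diag["n_gated"] = len(gated)
        chains = L.connect_chains(gated, cfg.chain_angle_tol, cfg.chain_gap_tol)
        diag["n_chains"] = len(chains)
        chain = L.longest_chain(chains)
        diag["chain_length"] = chain.total_length
        diag["chain"] = chain

    with _stage("ransac")(diag):
        rcfg = R.RansacConfig(
            n=cfg.ransac_n, eps=cfg.ransac_eps, K=cfg.ransac_K,
            seed=cfg.seed, refit=cfg.ransac_refit,
        )
        curve = R.fit_quadratic_ransac(chain.pixels, rcfg)
        diag["consensus"] = curve.consensus
        local = R.curve_to_mask(curve, *cand_mask.shape, lat)
        local &= breast
        full = np.zeros((full_h, full_w), dtype=np.uint8)
        r0, c0 = crop_offset
        full[r0 : r0 + local.shape[0], c0 : c0 + local.shape[1]] = local

    return SegmentationResult(
        mask=full, curve=curve, laterality=lat, crop_offset=crop_offset, diagnostics=diag
    )
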