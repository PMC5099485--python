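"""Margin cropping, breast masking, windowing, CLAHE, median filtering."""

import numpy as np
import pytest

from pectseg import phantom, preprocess as P
from pectseg.errors import (
    ConstantRegionError,
    EmptyContentError,
    ParameterError,
    UnresolvedLateralityError,
)
from pectseg.types import Laterality


# ---------------------------------------------------------------- margins

def test_blank_margins_are_cropped_exactly():
    img = np.zeros((100, 200), dtype=np.uint8)
    img[:, 50:170] = 200
    out, off = P.remove_blank_margins(img)
    assert off == (0, 50)
    assert out.shape == (100, 120)


def test_frame_without_margins_is_unchanged(rng):
    img = rng.integers(100, 200, (40, 60), dtype=np.uint8)
    out, off = P.remove_blank_margins(img)
    assert off == (0, 0)
    assert np.array_equal(out, img)


def test_blank_frame_raises():
    with pytest.raises(EmptyContentError):
        P.remove_blank_margins(np.zeros((32, 32), dtype=np.uint8))


def test_margin_crop_commutes_with_mirroring(default_phantom):
    img, _, _ = default_phantom
    a, _ = P.remove_blank_margins(img.pixels)
    b, _ = P.remove_blank_margins(img.pixels[:, ::-1])
    assert np.array_equal(a, b[:, ::-1])


def test_phantom_crop_leaves_no_blank_boundary_columns(default_phantom):
    img, _, _ = default_phantom
    out, _ = P.remove_blank_margins(img.pixels)
    assert out[:, 0].max() > 0 and out[:, -1].max() > 0
    assert out.shape[1] == img.width - sum((12, 12))


# ---------------------------------------------------------- breast masking

def test_two_level_image_is_separated_exactly():
    img = np.full((20, 20), 10, dtype=np.uint8)
    img[5:15, 5:15] = 200
    mask = P.segment_breast(img)
    assert np.array_equal(mask.astype(bool), img == 200)


def test_phantom_breast_mask_overlaps_truth(default_phantom):
    img, _, breast = default_phantom
    mask = P.remove_artifacts(P.segment_breast(img.pixels))
    inter = np.logical_and(mask, breast).sum()
    union = np.logical_or(mask, breast).sum()
    assert inter / union >= 0.95


def test_constant_image_degrades_to_all_foreground():
    mask = P.segment_breast(np.full((8, 8), 77, dtype=np.uint8))
    assert mask.all()


def test_largest_component_survives_artifact_removal():
    mask = np.zeros((60, 60), dtype=np.uint8)
    mask[5:45, 5:30] = 1  # area 1000
    mask[50:55, 50:58] = 1  # area 40
    out = P.remove_artifacts(mask)
    assert out.sum() == 1000
    assert out[50:55, 50:58].sum() == 0


def test_single_component_mask_is_identity(rng):
    mask = np.zeros((30, 30), dtype=np.uint8)
    mask[4:20, 6:25] = 1
    assert np.array_equal(P.remove_artifacts(mask), mask)


def test_equal_area_tie_goes_to_first_in_raster_order():
    mask = np.zeros((20, 20), dtype=np.uint8)
    mask[2:4, 2:4] = 1  # first 2x2 block in row-major order
    mask[10:12, 10:12] = 1
    out = P.remove_artifacts(mask)
    assert out[2:4, 2:4].all() and out[10:12, 10:12].sum() == 0


def test_artifact_removal_never_grows_foreground(rng):
    mask = (rng.random((40, 40)) > 0.7).astype(np.uint8)
    out = P.remove_artifacts(mask)
    assert out.sum() <= mask.sum()
    assert not np.any(out & ~mask)


def test_empty_mask_raises():
    with pytest.raises(EmptyContentError):
        P.remove_artifacts(np.zeros((5, 5), dtype=np.uint8))


# ------------------------------------------------------------- laterality

@pytest.mark.parametrize(
    "cols,expected",
    [(slice(0, 10), Laterality.MUSCLE_UPPER_LEFT), (slice(30, 40), Laterality.MUSCLE_UPPER_RIGHT)],
)
def test_one_sided_mass_sets_laterality(cols, expected):
    mask = np.zeros((20, 40), dtype=np.uint8)
    mask[:, cols] = 1
    assert P.detect_laterality(mask * 100, mask) is expected


def test_mirrored_scene_flips_laterality(default_phantom):
    img, _, breast = default_phantom
    lat = P.detect_laterality(img.pixels, breast)
    mlat = P.detect_laterality(img.pixels[:, ::-1], breast[:, ::-1])
    assert lat is Laterality.MUSCLE_UPPER_LEFT and mlat is lat.mirrored


def test_exactly_balanced_mass_is_unresolved():
    mask = np.ones((10, 10), dtype=np.uint8)
    with pytest.raises(UnresolvedLateralityError):
        P.detect_laterality(mask, mask)


# -------------------------------------------------------------- windowing

def test_window_maps_range_linearly():
    img = np.array([[100, 150, 200]], dtype=np.uint8)
    mask = np.ones_like(img)
    out = P.window_breast(img, mask)
    assert out.tolist() == [[0, 128, 255]]


def test_full_range_breast_is_unchanged_inside_mask(rng):
    img = rng.integers(0, 256, (20, 20), dtype=np.uint8)
    img.flat[0], img.flat[1] = 0, 255
    mask = np.ones_like(img)
    assert np.array_equal(P.window_breast(img, mask), img)


def test_window_output_spans_full_range(rng):
    img = rng.integers(40, 200, (30, 30), dtype=np.uint8)
    mask = (rng.random((30, 30)) > 0.4).astype(np.uint8)
    out = P.window_breast(img, mask)
    inside = out[mask.astype(bool)]
    assert inside.min() == 0 and inside.max() == 255
    assert (out[~mask.astype(bool)] == 0).all()


def test_constant_breast_region_raises():
    img = np.full((8, 8), 120, dtype=np.uint8)
    with pytest.raises(ConstantRegionError):
        P.window_breast(img, np.ones_like(img))


# ------------------------------------------------------------------ CLAHE

@pytest.mark.parametrize("clip,blocks", [(0.01, (8, 8)), (1.0, (1, 1)), (0.5, (2, 4))])
def test_constant_image_is_clahe_fixed_point(clip, blocks):
    img = np.full((32, 32), 99, dtype=np.uint8)
    assert np.array_equal(P.clahe(img, clip, blocks), img)


def test_single_tile_unclipped_equals_global_equalization(rng):
    """1×1 tiling with clip >= 1 must reproduce textbook global histogram
    equalization, computed here independently from sorted pixel ranks."""
    img = rng.integers(0, 256, (32, 32), dtype=np.uint8)
    out = P.clahe(img, clip_limit=1.0, blocks=(1, 1))
    flat = np.sort(img.ravel())
    cdf = np.searchsorted(flat, img, side="right")  # pixels <= v
    oracle = np.floor(255.0 * cdf / img.size + 0.5).astype(np.uint8)
    assert np.array_equal(out, oracle)


def test_clahe_keeps_intensities_in_range(rng):
    img = rng.integers(0, 256, (64, 48), dtype=np.uint8)
    out = P.clahe(img, 0.02, (4, 4))
    assert out.dtype == np.uint8 and out.min() >= 0 and out.max() <= 255


def test_clahe_increases_pectoral_edge_contrast(default_phantom):
    """Mean 5-px band difference across the known muscle boundary must grow."""
    img, _, _ = default_phantom
    crop, off = P.remove_blank_margins(img.pixels)
    breast = P.remove_artifacts(P.segment_breast(crop))
    win = P.window_breast(crop, breast)
    enh = P.clahe(win)
    a, b, c = 3e-4, -0.441, 118.0

    def band_contrast(im):
        diffs = []
        for r in range(5, 200):
            xb = int(a * r * r + b * r + c) - off[1]
            left = im[r, max(xb - 5, 0) : xb - 1].astype(float).mean()
            right = im[r, xb + 2 : xb + 6].astype(float).mean()
            diffs.append(abs(left - right))
        return np.mean(diffs)

    assert band_contrast(enh) > band_contrast(win)


def test_clahe_agrees_qualitatively_with_skimage(default_phantom):
    """Independent CLAHE (scikit-image) should rank pixels almost identically."""
    from scipy.stats import spearmanr
    from skimage import exposure

    img, _, _ = default_phantom
    crop, _ = P.remove_blank_margins(img.pixels)
    breast = P.remove_artifacts(P.segment_breast(crop))
    win = P.window_breast(crop, breast)
    mine = P.clahe(win, 0.01, (8, 8)).astype(float)
    theirs = exposure.equalize_adapthist(
        win, kernel_size=(win.shape[0] // 8, win.shape[1] // 8), clip_limit=0.01
    )
    rho = spearmanr(mine.ravel()[::11], theirs.ravel()[::11]).statistic
    assert rho > 0.9


@pytest.mark.parametrize("bad", [{"clip_limit": 0.0}, {"blocks": (0, 4)}, {"blocks": (64, 64)}])
def test_clahe_rejects_invalid_parameters(bad):
    img = np.zeros((32, 32), dtype=np.uint8)
    kwargs = {"clip_limit": 0.01, "blocks": (4, 4)}
    kwargs.update(bad)
    with pytest.raises(ParameterError):
        P.clahe(img, **kwargs)


# ----------------------------------------------------------------- median

def test_median_constant_fixed_point():
    img = np.full((10, 10), 42, dtype=np.uint8)
    assert np.array_equal(P.median_denoise(img, 3), img)


def test_median_removes_isolated_salt_pixel():
    img = np.zeros((9, 9), dtype=np.uint8)
    img[4, 4] = 255
    assert P.median_denoise(img, 3)[4, 4] == 0


def test_median_matches_brute_force_neighbourhood_sort(rng):
    img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
    out = P.median_denoise(img, 3)
    padded = np.pad(img, 1, mode="symmetric")
    for r in range(16):
        for c in range(16):
            block = np.sort(padded[r : r + 3, c : c + 3].ravel())
            assert out[r, c] == block[4]


def test_even_median_window_rejected():
    with pytest.raises(ParameterError):
        P.median_denoise(np.zeros((8, 8), dtype=np.uint8), 4)


# ------------------------------------------------------- mirror invariance

def test_enhancement_chain_commutes_with_mirroring(default_phantom):
    img, _, _ = default_phantom

    def run(arr):
        crop, _ = P.remove_blank_margins(arr)
        breast = P.remove_artifacts(P.segment_breast(crop))
        win = P.window_breast(crop, breast)
        return P.median_denoise(P.clahe(win))

    assert np.array_equal(run(img.pixels), run(img.pixels[:, ::-1])[:, ::-1])
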