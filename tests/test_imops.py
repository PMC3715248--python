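"""Colour conversion and binary area filters against brute-force oracles."""

import numpy as np
import pytest

from vineseg.errors import DimensionMismatchError
from vineseg.imops import (
    RegionFilterConfig,
    apply_mask,
    fill_small_holes,
    lab_to_rgb,
    remove_small_regions,
    rgb_to_lab,
)


def _flood_components(binary: np.ndarray, connectivity: int):
    """Naive BFS labelling oracle; returns list of pixel-index sets."""
    h, w = binary.shape
    if connectivity == 8:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for r in range(h):
        for c in range(w):
            if binary[r, c] and not seen[r, c]:
                stack = [(r, c)]
                seen[r, c] = True
                comp = []
                while stack:
                    rr, cc = stack.pop()
                    comp.append((rr, cc))
                    for dr, dc in steps:
                        r2, c2 = rr + dr, cc + dc
                        if 0 <= r2 < h and 0 <= c2 < w and binary[r2, c2] and not seen[r2, c2]:
                            seen[r2, c2] = True
                            stack.append((r2, c2))
                comps.append(comp)
    return comps


def _oracle_remove(binary, cfg):
    out = binary.copy()
    thr = cfg.threshold(binary.shape)
    for comp in _flood_components(binary, cfg.connectivity):
        if len(comp) < thr:
            for r, c in comp:
                out[r, c] = False
    return out


def _oracle_fill(binary, cfg):
    out = binary.copy()
    thr = cfg.threshold(binary.shape)
    h, w = binary.shape
    for comp in _flood_components(~binary, cfg.connectivity):
        touches = any(r in (0, h - 1) or c in (0, w - 1) for r, c in comp)
        if len(comp) < thr and not touches:
            for r, c in comp:
                out[r, c] = True
    return out


# ---------------------------------------------------------------------- lab


def test_lab_anchors():
    white = rgb_to_lab(np.ones((1, 1, 3)))[0, 0]
    assert white[0] == pytest.approx(100.0, abs=0.01)
    assert abs(white[1]) < 0.5 and abs(white[2]) < 0.5
    black = rgb_to_lab(np.zeros((1, 1, 3)))[0, 0]
    assert np.allclose(black, 0.0, atol=1e-6)
    # independent evaluation of the sRGB->XYZ->Lab formulas for mid-grey:
    # lin = ((0.5+0.055)/1.055)^2.4 = 0.21404; L* = 116*lin^(1/3) - 16
    grey = rgb_to_lab(np.full((1, 1, 3), 0.5))[0, 0]
    lin = ((0.5 + 0.055) / 1.055) ** 2.4
    expected_l = 116.0 * lin ** (1.0 / 3.0) - 16.0
    assert grey[0] == pytest.approx(expected_l, abs=0.05)
    assert abs(grey[1]) < 0.5 and abs(grey[2]) < 0.5


def test_lab_round_trip_on_gamut(rng):
    rgb = rng.uniform(0.05, 0.95, size=(16, 16, 3))
    lab = rgb_to_lab(rgb)
    lab2 = rgb_to_lab(lab_to_rgb(lab))
    assert np.max(np.abs(lab - lab2)) < 0.1


def test_lab_rejects_out_of_range():
    with pytest.raises(ValueError):
        rgb_to_lab(np.full((2, 2, 3), 1.5))
    with pytest.raises(ValueError):
        rgb_to_lab(np.full((2, 2, 3), np.nan))


# ------------------------------------------------------------- area filters


@pytest.mark.parametrize("connectivity", [4, 8])
def test_remove_small_regions_matches_flood_fill(rng, connectivity):
    cfg = RegionFilterConfig(min_area_fraction=0.005, connectivity=connectivity)
    for _ in range(25):
        raster = rng.random((64, 64)) < 0.35
        assert np.array_equal(remove_small_regions(raster, cfg), _oracle_remove(raster, cfg))


@pytest.mark.parametrize("connectivity", [4, 8])
def test_fill_small_holes_matches_flood_fill(rng, connectivity):
    cfg = RegionFilterConfig(min_area_fraction=0.005, connectivity=connectivity)
    for _ in range(25):
        raster = rng.random((64, 64)) < 0.65
        assert np.array_equal(fill_small_holes(raster, cfg), _oracle_fill(raster, cfg))


def test_remove_small_regions_contracts(rng):
    cfg = RegionFilterConfig(min_area_fraction=0.01, connectivity=8)
    raster = rng.random((48, 48)) < 0.4
    once = remove_small_regions(raster, cfg)
    assert np.array_equal(once, remove_small_regions(once, cfg))  # idempotent
    assert not np.any(once & ~raster)  # output TRUE set subset of input
    assert np.array_equal(
        remove_small_regions(np.zeros((8, 8), bool), cfg), np.zeros((8, 8), bool)
    )


def test_threshold_boundary_component_kept():
    cfg = RegionFilterConfig(min_area_fraction=4 / 64, connectivity=8)
    raster = np.zeros((8, 8), bool)
    raster[0:2, 0:2] = True  # exactly ceil(4/64*64)=4 pixels
    assert np.array_equal(remove_small_regions(raster, cfg), raster)
    raster3 = np.zeros((8, 8), bool)
    raster3[0, 0:3] = True  # 3 pixels: below threshold
    assert not remove_small_regions(raster3, cfg).any()


def test_fill_small_holes_contracts(rng):
    cfg = RegionFilterConfig(min_area_fraction=0.01, connectivity=8)
    raster = rng.random((48, 48)) < 0.6
    once = fill_small_holes(raster, cfg)
    assert np.array_equal(once, fill_small_holes(once, cfg))  # idempotent
    assert not np.any(raster & ~once)  # superset
    # a 2-pixel hole inside a solid disc is filled
    disc = np.zeros((16, 16), bool)
    disc[2:14, 2:14] = True
    disc[7, 7] = disc[7, 8] = False
    filled = fill_small_holes(disc, cfg)
    assert filled[7, 7] and filled[7, 8]
    assert filled[2:14, 2:14].all()
    assert np.array_equal(filled[0], disc[0])  # border untouched
    # a FALSE region touching the border is never filled
    edge = np.ones((16, 16), bool)
    edge[0, 5] = False
    assert not fill_small_holes(edge, cfg)[0, 5]


def test_fill_equals_dual_of_remove_on_interior(rng):
    """Filling holes = complement ∘ remove ∘ complement, restricted to
    components that do not touch the border."""
    cfg = RegionFilterConfig(min_area_fraction=0.004, connectivity=8)
    raster = rng.random((64, 64)) < 0.7
    dual = ~remove_small_regions(~raster, cfg)
    filled = fill_small_holes(raster, cfg)
    # on pixels whose FALSE component misses the border, both agree
    border_mask = np.zeros((64, 64), bool)
    for comp in _flood_components(~raster, 8):
        if any(r in (0, 63) or c in (0, 63) for r, c in comp):
            for r, c in comp:
                border_mask[r, c] = True
    assert np.array_equal(filled[~border_mask], dual[~border_mask])


# ---------------------------------------------------------------- apply_mask


def test_apply_mask_elementwise(rng):
    img = rng.random((10, 12))
    mask = rng.random((10, 12)) < 0.5
    out = apply_mask(img, mask, fill=0.0)
    assert np.all(out[mask] == 0.0)
    assert np.array_equal(out[~mask], img[~mask])
    # identity under the empty mask; constant under the full mask
    assert np.array_equal(apply_mask(img, np.zeros((10, 12), bool)), img)
    assert np.all(apply_mask(img, np.ones((10, 12), bool), fill=0.0) == 0.0)
    # multichannel
    rgb = rng.random((10, 12, 3))
    out3 = apply_mask(rgb, mask, fill=0.5)
    assert np.all(out3[mask] == 0.5)


def test_apply_mask_shape_mismatch(rng):
    with pytest.raises(DimensionMismatchError):
        apply_mask(rng.random((4, 4)), np.zeros((5, 5), bool))


def test_region_config_validation():
    with pytest.raises(ValueError):
        RegionFilterConfig(min_area_fraction=0.0)
    with pytest.raises(ValueError):
        RegionFilterConfig(connectivity=6)
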