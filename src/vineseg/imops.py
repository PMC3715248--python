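"""Image-level primitives: colour conversion, small-region filtering, masking.

Colour conversion follows CIE L*a*b* under sRGB primaries and the D65
reference white (the scikit-image default). The "morphological" clean-up
steps of the masking pipeline are implemented as connected-component area
filters: `remove_small_regions` is an area opening of the TRUE set,
`fill_small_holes` fills small interior FALSE components. Both are scale-free
through `min_area_fraction`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import color as _skcolor
from skimage import measure as _skmeasure

from .errors import DimensionMismatchError

__all__ = [
    "RegionFilterConfig",
    "rgb_to_lab",
    "lab_to_rgb",
    "remove_small_regions",
    "fill_small_holes",
    "apply_mask",
]


@dataclass(frozen=True)
class RegionFilterConfig:
    """Area filter settings.

    min_area_fraction: minimum connected-component size as a fraction of the
    image pixel count (strictly positive); components of at least
    ``ceil(min_area_fraction * H * W)`` pixels survive.
    connectivity: 4 (edge neighbours) or 8 (edge + diagonal).
    """

    min_area_fraction: float = 2e-4
    connectivity: int = 8

    def __post_init__(self):
        if not (0.0 < self.min_area_fraction < 1.0):
            raise ValueError("min_area_fraction must be in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    def threshold(self, shape) -> int:
        """Pixel-count threshold for a raster of the given shape."""
        h, w = shape[:2]
        return math.ceil(self.min_area_fraction * h * w)

    @property
    def _sk_connectivity(self) -> int:
        return 2 if self.connectivity == 8 else 1


def rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """Convert an H×W×3 sRGB raster in [0, 1] to CIE L*a*b* (D65).

    L* lies in [0, 100]; a* and b* are unbounded chromaticity axes.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise DimensionMismatchError(f"expected H×W×3 RGB, got shape {rgb.shape}")
    if not np.all(np.isfinite(rgb)):
        raise ValueError("non-finite RGB values")
    if rgb.min() < 0.0 or rgb.max() > 1.0:
        raise ValueError("RGB values must lie in [0, 1]")
    return _skcolor.rgb2lab(rgb)


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_lab`; out-of-gamut values are clipped."""
    return _skcolor.lab2rgb(np.asarray(lab, dtype=np.float64))


def _as_bool(binary) -> np.ndarray:
    binary = np.asarray(binary)
    if binary.dtype != bool:
        raise TypeError("expected a boolean raster")
    if binary.ndim != 2:
        raise DimensionMismatchError(f"expected 2-D raster, got shape {binary.shape}")
    return binary


def remove_small_regions(binary: np.ndarray, cfg: RegionFilterConfig) -> np.ndarray:
    """Drop TRUE components smaller than the area threshold.

    Components of exactly threshold size are preserved. Idempotent; the
    output TRUE set is a subset of the input TRUE set.
    """
    binary = _as_bool(binary)
    thr = cfg.threshold(binary.shape)
    if thr <= 1:
        return binary.copy()
    labels = _skmeasure.label(binary, connectivity=cfg._sk_connectivity)
    if labels.max() == 0:
        return binary.copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes >= thr
    keep[0] = False
    return keep[labels]


def fill_small_holes(binary: np.ndarray, cfg: RegionFilterConfig) -> np.ndarray:
    """Set small interior FALSE components to TRUE.

    A FALSE component is filled iff it is smaller than the area threshold
    and does not touch the image border. Idempotent; the output TRUE set is
    a superset of the input TRUE set.
    """
    binary = _as_bool(binary)
    thr = cfg.threshold(binary.shape)
    labels = _skmeasure.label(~binary, connectivity=cfg._sk_connectivity)
    if labels.max() == 0:
        return binary.copy()
    sizes = np.bincount(labels.ravel())
    border = np.zeros(labels.max() + 1, dtype=bool)
    for edge in (labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]):
        border[np.unique(edge)] = True
    fill = (sizes < thr) & ~border
    fill[0] = False
    return binary | fill[labels]


def apply_mask(image: np.ndarray, mask, fill: float = 0.0) -> np.ndarray:
    """Replace pixels claimed by ``mask`` with ``fill``; others untouched.

    Works on H×W or H×W×c rasters; ``mask`` may be a boolean array or any
    object with a boolean ``values`` attribute.
    """
    values = getattr(mask, "values", mask)
    values = np.asarray(values)
    if values.dtype != bool:
        raise TypeError("mask must be boolean")
    image = np.asarray(image, dtype=np.float64)
    if image.shape[:2] != values.shape:
        raise DimensionMismatchError(
            f"mask shape {values.shape} does not match image shape {image.shape[:2]}"
        )
    out = image.copy()
    out[values] = fill
    return out
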