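"""Synthetic vineyard scenes with ground truth.

A scene is rendered from a table of per-class spectral signatures — stylised
reflectance curves for leaves, stems, branches, soil, sky and grapes on a
400–1000 nm grid — plus per-class RGB colours. The geometry emulates a
trellised grapevine viewed side-on: sky above soil, one vertical stem,
thin branch segments, elliptical leaf blobs and berry-cluster fruit bunches,
painted with occlusion order grapes > leaves > branches > stem > background.

The signature constants are model choices, not measurements; what the
pipeline relies on is their ordering structure: photosynthetic tissue is
dark in the red (chlorophyll absorption at 600–700 nm) and bright in the
near infrared, soil and sky are bright in the red, woody tissue reflects
less NIR than leaves, and grapes are dark blue-purple in RGB (lowest b*).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from skimage import draw as _skdraw
from sklearn.decomposition import PCA

from .image_model import LabelMap, SceneBundle, VineClass

__all__ = [
    "SignatureTable",
    "SceneSpec",
    "default_signatures",
    "generate_scene",
    "generate_scene_set",
    "contrast_ratio",
    "rank_bands_pca",
    "sample_spectra",
]

log = logging.getLogger(__name__)

#: rendering classes; SOIL and SKY both map to BACKGROUND in the truth map
RENDER_CLASSES = ("leaf", "stem", "branch", "soil", "sky", "fruit")

_TRUTH_OF = {
    "leaf": VineClass.LEAF,
    "stem": VineClass.STEM,
    "branch": VineClass.BRANCH,
    "soil": VineClass.BACKGROUND,
    "sky": VineClass.BACKGROUND,
    "fruit": VineClass.FRUIT,
}


@dataclass
class SignatureTable:
    """Per-class reflectance mean/sd over a wavelength grid plus RGB colour."""

    wavelengths: np.ndarray  # (W,) nm, ascending; includes 635/660/880 exactly
    mean: dict  # class -> (W,) reflectance in [0, 1]
    sd: dict  # class -> (W,) positive
    rgb_mean: dict  # class -> (3,) in [0, 1]
    rgb_sd: dict  # class -> scalar positive

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        for cls in self.mean:
            m, s = np.asarray(self.mean[cls]), np.asarray(self.sd[cls])
            if m.shape != self.wavelengths.shape or s.shape != self.wavelengths.shape:
                raise ValueError(f"signature length mismatch for class '{cls}'")
            if m.min() < 0.0 or m.max() > 1.0:
                raise ValueError(f"reflectance means for '{cls}' outside [0, 1]")
            if s.min() <= 0.0:
                raise ValueError(f"sd for '{cls}' must be positive")
        for w in (635, 660, 880):
            if not np.any(self.wavelengths == w):
                raise ValueError(f"wavelength grid must cover {w} nm exactly")

    def index_of(self, wavelength_nm: float) -> int:
        idx = np.flatnonzero(self.wavelengths == wavelength_nm)
        if idx.size == 0:
            raise KeyError(f"{wavelength_nm} nm not on the signature grid")
        return int(idx[0])

    def reflectance(self, cls: str, wavelength_nm: float) -> float:
        return float(self.mean[cls][self.index_of(wavelength_nm)])


# anchor points (nm, reflectance) interpolated onto the grid; the red
# chlorophyll dip, the 700–760 nm red edge and the NIR plateau are the
# features the band choices exploit
_ANCHORS = {
    "leaf": [(400, 0.08), (500, 0.09), (550, 0.16), (600, 0.13), (635, 0.13),
             (660, 0.12), (676, 0.11), (690, 0.12), (710, 0.30), (740, 0.60),
             (760, 0.70), (800, 0.76), (850, 0.81), (880, 0.82), (1000, 0.80)],
    "branch": [(400, 0.12), (550, 0.18), (635, 0.26), (660, 0.40), (690, 0.41),
               (760, 0.48), (800, 0.52), (880, 0.55), (1000, 0.55)],
    "stem": [(400, 0.10), (550, 0.14), (635, 0.16), (660, 0.17), (690, 0.18),
             (760, 0.30), (880, 0.35), (1000, 0.36)],
    "soil": [(400, 0.30), (500, 0.38), (550, 0.42), (600, 0.48), (635, 0.52),
             (660, 0.54), (690, 0.55), (760, 0.57), (880, 0.58), (1000, 0.60)],
    "sky": [(400, 0.80), (500, 0.78), (550, 0.76), (635, 0.72), (660, 0.70),
            (760, 0.66), (880, 0.62), (1000, 0.60)],
    "fruit": [(400, 0.05), (550, 0.05), (635, 0.06), (660, 0.06), (760, 0.30),
              (880, 0.45), (1000, 0.45)],
}

_RGB = {
    "leaf": (0.15, 0.38, 0.14),
    "stem": (0.36, 0.30, 0.24),
    "branch": (0.55, 0.47, 0.20),
    "soil": (0.52, 0.42, 0.30),
    "sky": (0.82, 0.87, 0.93),
    "fruit": (0.22, 0.10, 0.34),
}


def default_signatures(sd: float = 0.015, rgb_sd: float = 0.025) -> SignatureTable:
    """The stylised default signature table.

    Grid: 3 nm spacing over 400–1000 nm with the three filter wavelengths
    (635, 660, 880 nm) inserted so band lookups are exact.
    """
    grid = np.union1d(np.arange(400, 1001, 3, dtype=float), [635.0, 660.0, 880.0])
    mean = {}
    sds = {}
    for cls, anchors in _ANCHORS.items():
        xs, ys = zip(*anchors)
        mean[cls] = np.interp(grid, xs, ys)
        sds[cls] = np.full_like(grid, sd)
    rgb_mean = {cls: np.asarray(c, dtype=float) for cls, c in _RGB.items()}
    rgb_sds = {cls: rgb_sd for cls in _RGB}
    return SignatureTable(grid, mean, sds, rgb_mean, rgb_sds)


@dataclass
class SceneSpec:
    """Geometry, noise and illumination settings for one synthetic scene."""

    height: int = 256
    width: int = 256
    n_grape_bunches: int = 3
    bunch_radius: tuple = (14, 24)
    berry_radius: tuple = (3, 5)
    berries_per_bunch: tuple = (12, 22)
    n_leaf_blobs: int = 32
    leaf_radius: tuple = (6, 14)
    n_branches: int = 12
    branch_width: tuple = (2, 4)
    branch_length: tuple = (40, 110)
    stem_width: tuple = (7, 11)
    soil_fraction: float = 0.5
    noise_sd: float = 0.03
    illumination: tuple = (0.8, 1.2)
    seed: int = 0

    def __post_init__(self):
        if self.height < 32 or self.width < 32:
            raise ValueError("scene dimensions must be at least 32 pixels")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name in ("n_grape_bunches", "n_leaf_blobs", "n_branches"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _paint_geometry(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Paint render-class indices (into RENDER_CLASSES) with occlusion order."""
    h, w = spec.height, spec.width
    cls = np.empty((h, w), dtype=np.int8)
    idx = {name: i for i, name in enumerate(RENDER_CLASSES)}

    horizon = int(round(h * (1.0 - spec.soil_fraction)))
    cls[:horizon, :] = idx["sky"]
    cls[horizon:, :] = idx["soil"]

    # stem: one near-vertical band through the canopy
    sw = int(rng.integers(spec.stem_width[0], spec.stem_width[1] + 1))
    x0 = int(rng.integers(w // 3, 2 * w // 3))
    for r in range(h):
        xx = x0 + int(round(2.0 * np.sin(r / h * np.pi)))
        cls[r, max(0, xx) : min(w, xx + sw)] = idx["stem"]

    # branches: thin segments leaving the stem at shallow angles
    for _ in range(spec.n_branches):
        r0 = int(rng.integers(int(0.05 * h), int(0.8 * h)))
        c0 = x0 + sw // 2
        angle = rng.uniform(-0.9, 0.9)
        direction = rng.choice([-1, 1])
        length = int(rng.integers(spec.branch_length[0], spec.branch_length[1] + 1))
        bw = int(rng.integers(spec.branch_width[0], spec.branch_width[1] + 1))
        r1 = int(np.clip(r0 + np.sin(angle) * length, 0, h - 1))
        c1 = int(np.clip(c0 + direction * np.cos(angle) * length, 0, w - 1))
        rr, cc = _skdraw.line(r0, c0, r1, c1)
        for off in range(bw):
            rr2 = np.clip(rr + off, 0, h - 1)
            cls[rr2, cc] = idx["branch"]

    # leaves: random ellipses concentrated in the canopy
    for _ in range(spec.n_leaf_blobs):
        rc = int(rng.integers(int(0.05 * h), int(0.85 * h)))
        cc_ = int(rng.integers(0, w))
        ra = int(rng.integers(spec.leaf_radius[0], spec.leaf_radius[1] + 1))
        rb = int(rng.integers(spec.leaf_radius[0], spec.leaf_radius[1] + 1))
        rot = rng.uniform(0, np.pi)
        rr, cc2 = _skdraw.ellipse(rc, cc_, ra, rb, shape=(h, w), rotation=rot)
        cls[rr, cc2] = idx["leaf"]

    # grape bunches: clusters of overlapping berries
    for _ in range(spec.n_grape_bunches):
        rc = int(rng.integers(int(0.25 * h), int(0.85 * h)))
        cc_ = int(rng.integers(int(0.1 * w), int(0.9 * w)))
        bunch_r = int(rng.integers(spec.bunch_radius[0], spec.bunch_radius[1] + 1))
        n_berries = int(rng.integers(spec.berries_per_bunch[0], spec.berries_per_bunch[1] + 1))
        for _ in range(n_berries):
            dr = rng.normal(0, bunch_r / 2.0)
            dc = rng.normal(0, bunch_r / 2.5)
            br = int(rng.integers(spec.berry_radius[0], spec.berry_radius[1] + 1))
            rr, cc2 = _skdraw.disk(
                (int(np.clip(rc + dr, 0, h - 1)), int(np.clip(cc_ + dc, 0, w - 1))),
                br,
                shape=(h, w),
            )
            cls[rr, cc2] = idx["fruit"]
    return cls


def _illumination_field(spec: SceneSpec) -> np.ndarray:
    lo, hi = spec.illumination
    ramp = np.linspace(lo, hi, spec.width)
    return np.broadcast_to(ramp, (spec.height, spec.width))


def _render_band(
    cls: np.ndarray,
    sig: SignatureTable,
    wavelength: float,
    spec: SceneSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    i = sig.index_of(wavelength)
    means = np.array([sig.mean[name][i] for name in RENDER_CLASSES])
    sds = np.array([sig.sd[name][i] for name in RENDER_CLASSES])
    base = rng.normal(means[cls], sds[cls])
    base *= _illumination_field(spec)
    if spec.noise_sd > 0:
        base = base + rng.normal(0.0, spec.noise_sd, size=base.shape)
    return np.clip(base, 0.0, 1.0)


def _render_rgb(
    cls: np.ndarray, sig: SignatureTable, spec: SceneSpec, rng: np.random.Generator
) -> np.ndarray:
    means = np.stack([sig.rgb_mean[name] for name in RENDER_CLASSES])
    sds = np.array([sig.rgb_sd[name] for name in RENDER_CLASSES])
    base = rng.normal(means[cls], sds[cls][..., None])
    base *= _illumination_field(spec)[..., None]
    if spec.noise_sd > 0:
        base = base + rng.normal(0.0, spec.noise_sd, size=base.shape)
    return np.clip(base, 0.0, 1.0)


def generate_scene(spec: SceneSpec, sig: SignatureTable | None = None) -> SceneBundle:
    """Render one synthetic scene bundle with its ground-truth label map.

    Fully reproducible from ``spec.seed``. Warns if the requested geometry
    is so crowded that one of the five evaluation classes vanished.
    """
    sig = sig or default_signatures()
    rng = np.random.default_rng(spec.seed)
    cls = _paint_geometry(spec, rng)

    truth_values = np.empty(cls.shape, dtype=np.uint8)
    for i, name in enumerate(RENDER_CLASSES):
        truth_values[cls == i] = int(_TRUTH_OF[name])
    truth = LabelMap(truth_values)

    counts = truth.class_counts()
    missing = [c.name for c in (VineClass.FRUIT, VineClass.STEM, VineClass.LEAF,
                                VineClass.BRANCH, VineClass.BACKGROUND) if counts[c] == 0]
    if missing:
        warnings.warn(
            f"scene too crowded: classes {missing} vanished; realised counts "
            f"{ {c.name: n for c, n in counts.items()} }",
            stacklevel=2,
        )

    bundle = SceneBundle(
        rgb=_render_rgb(cls, sig, spec, rng),
        band635=_render_band(cls, sig, 635, spec, rng),
        band660=_render_band(cls, sig, 660, spec, rng),
        band880=_render_band(cls, sig, 880, spec, rng),
        truth=truth,
        scene_id=f"synthetic-{spec.seed}",
    )
    return bundle


def generate_scene_set(
    n: int,
    spec: SceneSpec | None = None,
    sig: SignatureTable | None = None,
    base_seed: int = 0,
) -> list[SceneBundle]:
    """Generate ``n`` scenes with seeds ``base_seed .. base_seed+n-1``.

    Illumination ramps are varied scene to scene (direction and strength),
    emulating capture under different lighting conditions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or SceneSpec()
    meta_rng = np.random.default_rng(base_seed)
    scenes = []
    for i in range(n):
        # mild ramps within the 0.8-1.2 design range, random direction
        lo = float(meta_rng.uniform(0.8, 0.95))
        hi = float(meta_rng.uniform(1.05, 1.2))
        if meta_rng.random() < 0.5:
            lo, hi = hi, lo
        scene_spec = replace(spec, seed=base_seed + i, illumination=(lo, hi))
        scenes.append(generate_scene(scene_spec, sig))
    return scenes


def contrast_ratio(sig: SignatureTable, a: str, b: str) -> np.ndarray:
    """Elementwise ``mean_a / mean_b`` over the wavelength grid."""
    num, den = sig.mean[a], sig.mean[b]
    if np.any(den == 0.0):
        raise ZeroDivisionError(f"class '{b}' has zero reflectance on the grid")
    return num / den


def sample_spectra(
    sig: SignatureTable,
    classes=("leaf", "stem", "branch", "soil"),
    n_per_class: int = 25,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw noisy full-spectrum samples per class (rows) for band ranking.

    Returns ``(spectra, wavelengths)`` with ``spectra`` of shape
    ``(len(classes) * n_per_class, n_wavelengths)``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cls in classes:
        rows.append(rng.normal(sig.mean[cls], sig.sd[cls], size=(n_per_class, len(sig.wavelengths))))
    return np.clip(np.vstack(rows), 0.0, 1.0), sig.wavelengths.copy()


def rank_bands_pca(spectra: np.ndarray, n_bands: int, wavelengths=None) -> np.ndarray:
    """Pick the wavelengths that best represent the leading principal axes.

    Columns are mean-centred and the first ``n_bands`` principal components
    computed; for each component in order, the wavelength with the largest
    absolute loading is selected (ties break toward the lower wavelength).
    Duplicates are skipped and the list topped up by the next-largest
    overall loading scores, so exactly ``n_bands`` distinct wavelengths are
    returned.
    """
    spectra = np.asarray(spectra, dtype=np.float64)
    if spectra.ndim != 2 or spectra.shape[0] < 2:
        raise ValueError("need a samples×wavelengths matrix with >= 2 samples")
    if not (1 <= n_bands <= spectra.shape[1]):
        raise ValueError("n_bands must be between 1 and the number of wavelengths")
    if wavelengths is None:
        wavelengths = np.arange(spectra.shape[1], dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=np.float64)

    n_comp = min(n_bands, spectra.shape[0] - 1, spectra.shape[1])
    if n_comp < 1:
        raise ValueError("rank-deficient input: cannot extract any component")
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(spectra)
    loadings = np.abs(pca.components_)  # (n_comp, W)

    chosen: list[int] = []
    for comp in loadings:
        order = np.argsort(-comp, kind="stable")  # ties -> lower index/wavelength
        for j in order:
            if j not in chosen:
                chosen.append(int(j))
                break
        if len(chosen) >= n_bands:
            break
    if len(chosen) < n_bands:
        score = loadings.max(axis=0)
        for j in np.argsort(-score, kind="stable"):
            if int(j) not in chosen:
                chosen.append(int(j))
            if len(chosen) >= n_bands:
                break
    return wavelengths[chosen[:n_bands]]
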