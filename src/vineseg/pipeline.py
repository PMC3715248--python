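"""The sequential masking classifier and the RGB-only baseline.

The classifier labels every pixel of a registered RGB + {635, 660, 880} nm
scene as FRUIT, STEM, LEAF, BRANCH or BACKGROUND by four staged K-means
runs, each followed by a mask that excludes its pixels from later stages:

1. 635 nm, K=2 — background vs foreground. Chlorophyll absorbs red light,
   so canopy pixels are dark and soil/sky bright; the brighter centroid is
   background (mask 1, after small-region removal).
2. a*b* chromaticity of the masked RGB image, K=4 — the lowest-b* cluster
   is the dark blue-purple grapes (mask 2, after hole filling).
3. 880 nm on remaining pixels, K=3 — woody stems reflect less NIR than
   leaves; the lowest centroid is stems (mask 3).
4. 660 nm with all masked pixels filled to 0, K=3 — lowest centroid is the
   masked fill, middle is leaves, highest is branches.

Cluster-to-class assignment rests on these centroid-ordering rules; each is
explicit in :class:`PipelineConfig`. Stage precedence is the mask order:
background > fruit > stems > leaf/branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .clustering import ClusterModel, kmeans_fit
from .errors import DegenerateInputError, PipelineStageError, VinesegError
from .image_model import LabelMap, Mask, SceneBundle, VineClass
from .imops import (
    RegionFilterConfig,
    apply_mask,
    fill_small_holes,
    remove_small_regions,
    rgb_to_lab,
)

__all__ = [
    "PipelineConfig",
    "StageResult",
    "segment_background",
    "segment_fruit",
    "segment_stems",
    "segment_leaves_branches",
    "classify_scene",
    "classify_scene_rgb_only",
]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the sequential masking classifier.

    The cluster counts (2, 4, 3, 3) match the staged design; the ordering
    rules say which centroid each stage claims:

    * ``background_rule``: "brighter" (default) or "darker" centroid at
      635 nm is background;
    * ``fruit_rule``: "lowest_b" — lowest-b* chromaticity centroid is fruit;
    * ``stems_rule``: "lowest" unmasked centroid at 880 nm is stems;
    * ``leaves_rule``: "ascending" — at 660 nm the lowest centroid is the
      masked fill, the middle leaves, the highest branches.
    * ``step9_full_raster``: cluster the full 660 nm raster with masked
      pixels filled to 0 (the masked pixels then form their own dark
      cluster); if False, cluster only unmasked pixels.
    """

    k_background: int = 2
    k_colour: int = 4
    k_stems: int = 3
    k_leaves: int = 3
    background_rule: str = "brighter"
    fruit_rule: str = "lowest_b"
    stems_rule: str = "lowest"
    leaves_rule: str = "ascending"
    region_cfg_background: RegionFilterConfig = field(default_factory=RegionFilterConfig)
    region_cfg_fruit: RegionFilterConfig = field(default_factory=RegionFilterConfig)
    seed: int = 0
    n_restarts: int = 10
    max_iter: int = 300
    tol: float = 1e-6
    step9_full_raster: bool = True

    def _kmeans(self, X, K) -> ClusterModel:
        return kmeans_fit(
            X, K, seed=self.seed, n_restarts=self.n_restarts,
            max_iter=self.max_iter, tol=self.tol,
        )


@dataclass
class StageResult:
    """One stage's mask together with its fitted cluster model."""

    mask: Mask
    model: ClusterModel
    stage_name: str


def _require_variation(values: np.ndarray, stage: str, k: int) -> None:
    if np.unique(values).size < k:
        raise PipelineStageError(stage, "no separable clusters (degenerate input)")


def segment_background(band635: np.ndarray, cfg: PipelineConfig) -> StageResult:
    """Stage 1–2: split 635 nm intensities into background/foreground.

    Returns mask 1: TRUE = background, after small-region removal.
    """
    band635 = np.asarray(band635, dtype=np.float64)
    flat = band635.ravel()
    _require_variation(flat, "background", cfg.k_background)
    model = cfg._kmeans(flat, cfg.k_background)
    brightness = model.centroids[:, 0]
    if cfg.background_rule == "brighter":
        bg = int(np.argmax(brightness))
    elif cfg.background_rule == "darker":
        bg = int(np.argmin(brightness))
    else:
        raise ValueError(f"unknown background_rule {cfg.background_rule!r}")
    raw = (model.assignments == bg).reshape(band635.shape)
    cleaned = remove_small_regions(raw, cfg.region_cfg_background)
    return StageResult(Mask(cleaned, "background"), model, "background")


def segment_fruit(rgb: np.ndarray, mask1: Mask, cfg: PipelineConfig) -> StageResult:
    """Stages 4–6: cluster a*b* chromaticity of unmasked pixels, K=4.

    The lowest-b* centroid (dark blue-purple grapes) is claimed as fruit;
    tiny holes inside bunches are filled. Returns mask 2.
    """
    lab = rgb_to_lab(rgb)
    unmasked = ~mask1.values
    ab = lab[..., 1:3][unmasked]
    if ab.shape[0] < cfg.k_colour:
        raise PipelineStageError("fruit", f"fewer than K={cfg.k_colour} unmasked pixels")
    model = cfg._kmeans(ab, cfg.k_colour)
    if cfg.fruit_rule != "lowest_b":
        raise ValueError(f"unknown fruit_rule {cfg.fruit_rule!r}")
    fruit = int(np.argmin(model.centroids[:, 1]))
    raw = np.zeros(mask1.values.shape, dtype=bool)
    raw[unmasked] = model.assignments == fruit
    filled = fill_small_holes(raw, cfg.region_cfg_fruit)
    filled &= unmasked  # background precedence: filling never steals mask-1 pixels
    frac = filled.mean()
    if frac < cfg.region_cfg_fruit.min_area_fraction:
        log.warning(
            "fruit mask covers only %.5f of the image (< min_area_fraction %.5f); "
            "the scene may contain no grapes", frac, cfg.region_cfg_fruit.min_area_fraction,
        )
    return StageResult(Mask(filled, "fruit"), model, "fruit")


def segment_stems(band880: np.ndarray, mask12: Mask, cfg: PipelineConfig) -> StageResult:
    """Step 8: cluster unmasked 880 nm intensities, K=3.

    Woody stems reflect less NIR than leaves (branches fall in between), so
    the lowest centroid is claimed as stems. Returns mask 3.
    """
    band880 = np.asarray(band880, dtype=np.float64)
    unmasked = ~mask12.values
    vals = band880[unmasked]
    if vals.size < cfg.k_stems:
        raise PipelineStageError("stems", f"fewer than K={cfg.k_stems} unmasked pixels")
    _require_variation(vals, "stems", cfg.k_stems)
    model = cfg._kmeans(vals, cfg.k_stems)
    if cfg.stems_rule != "lowest":
        raise ValueError(f"unknown stems_rule {cfg.stems_rule!r}")
    stems = int(np.argmin(model.centroids[:, 0]))
    raw = np.zeros(mask12.values.shape, dtype=bool)
    raw[unmasked] = model.assignments == stems
    share = raw.sum() / max(unmasked.sum(), 1)
    if share < 0.005:
        log.warning(
            "stems cluster holds only %.4f of unmasked pixels; stems may be absent", share
        )
    return StageResult(Mask(raw, "stems"), model, "stems")


def segment_leaves_branches(
    band660: np.ndarray, mask123: Mask, cfg: PipelineConfig
) -> tuple[LabelMap, ClusterModel]:
    """Step 9: split the 660 nm image into masked / leaves / branches, K=3.

    With ``step9_full_raster`` the whole raster is clustered after filling
    masked pixels to 0; the lowest centroid is the masked fill, the middle
    leaves, the highest branches. Returns a partial label map (LEAF/BRANCH/
    UNLABELED; masked pixels are never labelled here) plus the model.
    """
    band660 = np.asarray(band660, dtype=np.float64)
    if cfg.leaves_rule != "ascending":
        raise ValueError(f"unknown leaves_rule {cfg.leaves_rule!r}")
    unmasked = ~mask123.values
    if cfg.step9_full_raster:
        filled = apply_mask(band660, mask123, fill=0.0)
        flat = filled.ravel()
        _require_variation(flat, "leaves", cfg.k_leaves)
        model = cfg._kmeans(flat, cfg.k_leaves)
        assign = model.assignments.reshape(band660.shape)
    else:
        vals = band660[unmasked]
        if vals.size < cfg.k_leaves:
            raise PipelineStageError("leaves", f"fewer than K={cfg.k_leaves} unmasked pixels")
        _require_variation(vals, "leaves", cfg.k_leaves)
        model = cfg._kmeans(vals, cfg.k_leaves)
        assign = np.full(band660.shape, -1, dtype=np.intp)
        assign[unmasked] = model.assignments

    order = np.argsort(model.centroids[:, 0], kind="stable")
    leaf_cluster = int(order[len(order) // 2]) if len(order) == 3 else int(order[0])
    branch_cluster = int(order[-1])

    values = np.full(band660.shape, int(VineClass.UNLABELED), dtype=np.uint8)
    values[(assign == leaf_cluster) & unmasked] = int(VineClass.LEAF)
    values[(assign == branch_cluster) & unmasked] = int(VineClass.BRANCH)
    return LabelMap(values), model


def classify_scene(
    bundle: SceneBundle, cfg: PipelineConfig | None = None
) -> tuple[LabelMap, list[StageResult]]:
    """Run the full sequential masking classifier on one scene.

    Composes the stages in order with precedence background > fruit >
    stems > leaf/branch. Residual pixels of the step-9 "masked" cluster
    that no mask claims are dark outliers and are assigned BACKGROUND
    (their count is logged). The returned label map has no UNLABELED
    pixels; the stage results form the audit trail.
    """
    cfg = cfg or PipelineConfig()
    stages: list[StageResult] = []

    def run(stage, fn, *args):
        try:
            return fn(*args)
        except VinesegError as exc:
            if isinstance(exc, PipelineStageError):
                raise
            raise PipelineStageError(stage, str(exc)) from exc

    s1 = run("background", segment_background, bundle.band635, cfg)
    stages.append(s1)
    s2 = run("fruit", segment_fruit, bundle.rgb, s1.mask, cfg)
    stages.append(s2)
    mask12 = s1.mask | s2.mask
    s3 = run("stems", segment_stems, bundle.band880, mask12, cfg)
    stages.append(s3)
    mask123 = mask12 | s3.mask
    partial, _model9 = run("leaves", segment_leaves_branches, bundle.band660, mask123, cfg)

    values = partial.values.copy()
    values[s3.mask.values] = int(VineClass.STEM)
    values[s2.mask.values] = int(VineClass.FRUIT)
    values[s1.mask.values] = int(VineClass.BACKGROUND)
    residual = values == int(VineClass.UNLABELED)
    n_residual = int(residual.sum())
    if n_residual:
        log.info("assigning %d residual dark pixels to BACKGROUND", n_residual)
        values[residual] = int(VineClass.BACKGROUND)
    return LabelMap(values), stages


def classify_scene_rgb_only(
    rgb: np.ndarray, cfg: PipelineConfig | None = None
) -> LabelMap:
    """RGB-only baseline: one K=5 K-means on a*b* chromaticity.

    The five clusters are mapped to classes by centroid ordering: lowest b*
    is fruit (dark purple), then highest b* is branches (yellow), then most
    negative a* is leaves (green), then the least chromatic remaining
    centroid is background, and the last is stems. This single-pass
    clustering is the comparison baseline for the sequential classifier.
    """
    cfg = cfg or PipelineConfig()
    lab = rgb_to_lab(rgb)
    ab = lab[..., 1:3].reshape(-1, 2)
    if ab.shape[0] < 5:
        raise DegenerateInputError("fewer than 5 pixels")
    spread = ab.max(axis=0) - ab.min(axis=0)
    if spread.max() < 1.0:
        raise DegenerateInputError(
            "degenerate clusters: image is achromatic (a*~b*~0 everywhere)"
        )
    model = cfg._kmeans(ab, 5)
    centroids = model.centroids
    remaining = list(range(5))

    fruit = min(remaining, key=lambda k: centroids[k, 1])
    remaining.remove(fruit)
    branch = max(remaining, key=lambda k: centroids[k, 1])
    remaining.remove(branch)
    leaf = min(remaining, key=lambda k: centroids[k, 0])
    remaining.remove(leaf)
    background = min(remaining, key=lambda k: float(np.hypot(*centroids[k])))
    remaining.remove(background)
    stem = remaining[0]

    cluster_to_class = {
        fruit: VineClass.FRUIT,
        branch: VineClass.BRANCH,
        leaf: VineClass.LEAF,
        background: VineClass.BACKGROUND,
        stem: VineClass.STEM,
    }
    remap = np.empty(5, dtype=np.uint8)
    for k, cls in cluster_to_class.items():
        remap[k] = int(cls)
    return LabelMap(remap[model.assignments].reshape(rgb.shape[:2]))
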