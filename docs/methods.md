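# Methods

## The model

`vineseg` treats a vineyard scene as a mixture of five pixel populations —
fruits, stems, leaves, branches and background (soil + sky) — that are
separable stage by stage in different measurement spaces:

* at 635 nm, photosynthetic tissue is dark (chlorophyll absorption in the
  600–700 nm window) while soil and sky are bright, so a 2-cluster K-means
  on that single band splits background from canopy;
* in (a\*, b\*) chromaticity, ripe grapes are dark blue-purple and sit at
  the lowest b\* of the canopy colours, so a 4-cluster K-means on the
  unmasked pixels isolates fruit;
* at 880 nm, leaf mesophyll scatters near-infrared light strongly while
  woody tissue does not (stems < branches < leaves), so a 3-cluster K-means
  on the remaining pixels isolates stems at the lowest centroid;
* at 660 nm, the remaining mix (leaves dark, dry branch bark brighter,
  masked pixels filled to 0) resolves into three intensity levels.

Each stage claims its pixels with a boolean mask and excludes them from all
later stages; precedence is therefore the mask order. The approach is fully
unsupervised — the only scene-specific decisions are which centroid each
stage claims, expressed as ordering rules on centroid locations.

Assumptions: the four channels are pixel-registered (sequential capture
through a filter wheel on a static rig); lighting is roughly uniform across
the scene; intensities are relative (no radiometric calibration), which the
clustering tolerates because it only relies on within-scene orderings.

## K-means

Lloyd iterations minimise `J_K = Σ_k Σ_{i∈C_k} ||x_i − m_k||²`. Design
choices, stated because they pin down bit-for-bit reproducibility:

* **Initialisation.** Restarts alternate between k-means++ (D²-weighted
  point sampling) and random-partition seeding (centroids are means of a
  random K-colouring). The mixture matters: point-seeded Lloyd provably
  cannot reach the global optimum on some small instances, whereas
  partition seeding places initial centres off-data and covers those
  basins. Default `n_restarts=10`, seed 0; the lowest-`J_K` restart wins,
  ties to the earlier restart.
* **Assignment ties** break toward the lower cluster index (`argmin`).
* **Empty clusters** are re-seeded to the point farthest from its current
  centroid; since an empty cluster contributes no cost, the objective stays
  monotonically non-increasing across iterations.
* **Convergence**: largest centroid shift < `tol` (1e-6) or 300 iterations.
* **Canonical labelling**: returned clusters are sorted lexicographically
  by centroid, so cluster indices do not depend on initialisation order and
  row permutations of the input permute the assignments identically.
* Features are used unscaled (raw band intensities, raw a\*b\*).

A brute-force enumerator (`brute_force_min_inertia`, O(K^n)) provides the
independent optimum for validation on instances up to n≈12.

## Morphology

The mask clean-up steps are connected-component area filters, scale-free
via `min_area_fraction` (default 2e-4 of the image, ≈1,000 px at
2,448×2,050 field resolution, ≈13 px at the 256×256 synthetic scale),
connectivity 8. `remove_small_regions` drops TRUE components strictly below
`ceil(min_area_fraction·H·W)` pixels (threshold-size components survive);
`fill_small_holes` fills FALSE components below threshold that do not touch
the image border. Both are idempotent and are validated against naive
flood-fill oracles.

## Colour

RGB→L\*a\*b\* uses sRGB primaries and the D65 reference white
(scikit-image). Only the chromaticity pair (a\*, b\*) is clustered — all
colour information lives there, and dropping L\* gives some robustness to
illumination level.

## Cluster-to-class rules

The original procedure fixed its cluster labels once, by thresholds on
centroid locations tuned on real imagery; those thresholds were never
published. This implementation replaces them with explicit ordering
predicates justified by the spectral physics above: background = brighter
635 nm centroid; fruit = lowest b\*; stems = lowest 880 nm centroid;
at 660 nm lowest = masked fill, middle = leaves, highest = branches. Each
rule is a config field, so a flipped-contrast deployment (e.g. a bright
screen behind the canopy) is a one-line change.

Two further composition choices were genuinely open:

* The 660 nm stage clusters the **full raster** with masked pixels filled
  to 0, so the masked pixels form their own dark cluster (an
  unmasked-pixels-only mode is available via `step9_full_raster=False`).
* Pixels of the 660 nm "masked" cluster that no mask actually claims are
  dark outliers; they are assigned BACKGROUND and counted in the log, so a
  completed label map never contains UNLABELED pixels.
* Hole filling in the fruit mask never steals pixels already claimed by the
  background mask (precedence is enforced, keeping the stage masks
  pairwise disjoint).

The RGB-only baseline (K=5 on a\*b\*) needs a 5-way rule: fruit = lowest
b\*, then branches = highest b\*, then leaves = most negative a\*, then
background = least chromatic remaining centroid, stems = the rest. It is
deliberately crude — it exists to show what a single colour clustering
cannot do.

## Evaluation

Matching matrix rows are truth, columns prediction, class order FRUIT,
STEM, LEAF, BRANCH, BACKGROUND. The FP rate is returned as a percentage
(its defining ratio is dimensionless; the percentage form matches how the
per-scene tables are printed). Metrics with empty denominators are flagged
`None`, never silently zeroed; the FP rate of a never-predicted class is a
genuine 0. Cross-scene summaries are arithmetic means reported to one
decimal, rounding halves away from zero, computed in decimal arithmetic so
printed one-decimal inputs aggregate exactly. The published six-scene
tables shipped in `field_study` contain two known printed inconsistencies
(the baseline mean leaf precision prints as 57.8 but computes to 57.6 from
its table; the scene-4 baseline accuracy/error pair sums to 99.9); the
package reports the table-derived values.

## Synthetic scenes

The generator's purpose is closed-loop validation: render a scene from
known per-class signatures, classify it, and score against the rendered
truth. Signature curves are **stylised model constants**, not measurements;
their contract is the ordering structure (vegetation dark in red / bright
in NIR, soil bright in red, sky brightest at 635 nm, stems < branches <
leaves at 880 nm, grapes lowest-b\* in colour), and they live on a 3 nm
400–1000 nm grid with the three filter wavelengths inserted so band
lookups are exact (no 3 nm arithmetic grid can contain 635, 660 and 880
simultaneously).

Numeric levels were chosen so that each stage's intended split is the
SSE-optimal one under the default noise and illumination: K-means is a
variance criterion, so a dominant class whose within-class spread
(reflectance × illumination ramp) rivals a small class's separation will be
split in preference to isolating the small class. Two consequences shaped
the defaults: dry-cane branches are rendered distinctly brighter than
leaves at 660 nm (0.40 vs 0.12), and the geometry keeps the leaf canopy at
a moderate fraction of the image (~20%) with non-negligible stem/branch
area, mirroring the row-trained vines the method targets.

Rendering: per pixel, reflectance ~ N(class mean, class sd 0.015), times a
horizontal multiplicative illumination ramp (default 0.8–1.2; scene sets
vary ramp strength and direction within that range), plus sensor noise
N(0, 0.03), clipped to [0, 1]. RGB channels render the same way from class
colours. Geometry: sky above soil (default 50/50), one near-vertical stem,
12 thin branch segments (2–4 px), 32 elliptical leaf blobs, 3 berry-cluster
bunches; occlusion order grapes > leaves > branches > stem > background.
All randomness flows from one seed; identical spec + seed reproduces the
bundle bit-for-bit.

What the generator does **not** emulate — and therefore what passing
closed-loop tests cannot show about real imagery: shadows and specular
highlights, within-class reflectance texture (disease, senescence,
fungicide deposits), occlusion-driven partial pixels, registration error
between bands, and non-Gaussian sensor noise. Closed-loop recovery shows
the pipeline logic and its rules are correct under the model's own
assumptions; field accuracy on real scenes is characterised by the
published six-scene tables instead, which the evaluation module aggregates.

## Band-contrast checks

`contrast_ratio` confirms the filter-choice rationale on the default
signatures: the leaf-to-soil ratio deviates most from 1 inside 630–690 nm.
`rank_bands_pca` mean-centres sampled spectra, takes the leading principal
components, and picks per component the wavelength with the largest
absolute loading (ties to the lower wavelength, duplicates skipped and
topped up by overall score). On default-signature draws the top three
include a 630–690 nm band and a ≥850 nm band, matching the red + NIR
filter logic.

## Problem sizes and determinism

Default test/validation sizes: 256×256 scenes (six per closed-loop set),
200 exhaustive K-means instances, 100 morphology rasters — together a few
CPU-minutes. Everything is seeded; the acceptance script derives all its
randomness from a single `--seed`.

## Known limitations

* The centroid-ordering rules are physically motivated defaults, not the
  original tuned thresholds; on real imagery they may need flipping or
  re-anchoring (they are config, not code).
* Branch recall is intrinsically fragile: branches are thin, few-pixel
  structures, and a variance-based clustering will sacrifice them first —
  shrinking branch area in the generator monotonically shrinks branch true
  positives.
* No illumination correction or shadow handling; strongly non-uniform
  lighting degrades the single-band stages first.
* K is fixed per stage (2, 4, 3, 3); scenes genuinely missing a class
  (e.g. no grapes) produce a warning and a near-empty mask rather than an
  adaptive K.
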