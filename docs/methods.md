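# Methods

`toothstage` implements a semi-automated pipeline for grading the
developmental stage (Demirjian C–H) of mandibular premolars from cropped
panoramic-radiograph regions: ROI preprocessing, globally optimal radial
active-contour segmentation by dynamic programming, tenfold label-preserving
augmentation, and a small convolutional stage classifier with the
accompanying model-selection studies. Because clinical radiographs of this
kind are not redistributable, a synthetic phantom generator supplies all
images used by the tests and examples; its fidelity and limits are
discussed below.

## Preprocessing

A square ROI (default 250×250 px) is cropped around a user-supplied seed
point — the method is deliberately semi-automated, and seed placement is
the one manual input. Intensities are then stretched linearly between the
1st and 99th percentiles (the stretch method and percentiles are our
choice; a percentile stretch is robust to the stray extreme pixels typical
of radiograph crops) and a 7×7 median filter removes impulse noise while
preserving edges. All border handling is edge replication, which keeps
medians well defined near the frame and introduces no artificial dark
border that a gradient-based contour would latch onto. CLAHE (8×8 tiles,
clip limit 0.01 — our defaults) is available as an optional enhancement in
the segmentation path.

Coordinates are (row, col), 0-based, with pixel centers at integer
positions; angle 0 points along +col and increases toward +row. Every
module uses this convention.

## Segmentation: dynamic-programming active contour

From the seed point, M radial lines at uniform angles each carry
N = radius_length / spacing discrete candidate positions (spacing 1 px, so
N equals the radius in pixels). A closed contour selects one candidate per
line; its cost is the sum over lines of

    E_i(v_i, v_{i+1}) = -g(v_i)   if D(v_i, v_{i+1}) ≤ δ,
                        sentinel  otherwise,

with the wrap pair (v_M, v_1) included. g is the image gradient
(central differences, bilinear sub-pixel sampling) projected on each line's
outward unit vector; minimizing the total finds the closed contour of
maximal directional gradient strength whose consecutive points stay within
δ. For a bright object on a darker surround the outward derivative at the
true boundary is negative, so the field is negated by default
(`bright_object=True`); the flag exists because the cost as written is
polarity-sensitive.

Numerical and algorithmic choices:

- **Cyclic closure.** The wrap term makes the chain a cycle. The default
  `exact` mode conditions on the first-line candidate: conceptually the
  open-chain DP is solved once per possible v_1; in practice all first
  points are solved simultaneously by giving the DP table a start-state
  dimension, which returns the true global optimum at O(M·N²·B) cost
  (B = feasible band width). A `two_pass` approximation (open-chain
  optimum, then an exact cycle through its first point) is provided for
  very large N.
- **Banded transitions.** Uniform angles and spacing make the pairwise
  feasibility matrix identical for every adjacent line pair (wrap
  included); it is decomposed once into its populated diagonals, so each DP
  step touches only candidate pairs within δ.
- **δ default 3×spacing** (user-settable). δ is a smoothness prior: at the
  recommended geometry (1200 lines, 100 px) it allows ~3 px radial movement
  between neighboring lines, enough to follow root prongs yet too stiff for
  pixel noise.
- **Finite sentinel** (> M·max|g|, default M·max|g|+1) stands in for the
  infinite cost of a δ violation so arithmetic stays finite; any fully
  feasible tuple therefore beats any violating one, and when no feasible
  tuple exists the least-bad selection is returned flagged
  `feasible=False`. The reported energy is always the recomputed sum of the
  selection's edge costs.
- **Ties** are broken toward the lexicographically smallest selection
  (forward reconstruction on backward cost-to-go tables), making results
  deterministic.
- **Rasterization** is boundary-inclusive point-in-polygon on pixel
  centers; the contours produced here are simple polygons, for which this
  coincides with the even-odd rule.

The recommended operating point (1200 lines × 100 px) follows the
parameter sweep the package can reproduce (`parameter_sweep`): shorter
radii truncate the object (under-segmentation), denser/longer grids cost
time and start tracking clutter (over-segmentation). Segmentation quality
is scored by Dice and Jaccard overlap plus a qualitative under/well/over
grade; the grade thresholds (spillover or missed area > 20 % of the true
area) are our quantitative stand-in for what is, in clinical practice, a
visual judgment.

## Phantoms

`phantom` generates star-convex tooth silhouettes directly as a radial
function r(θ) about the image center — star-convexity, the shape family a
radial contour can represent exactly, is therefore true by construction.
The silhouette is a crown ellipse plus a smooth downward root lobe, minus a
narrow apex notch that models the open apex. Stage is encoded
geometrically, following the qualitative Demirjian stage descriptions:

| stage | root length / crown height | apex gap (px) |
|-------|---------------------------|---------------|
| C     | 0.20                      | 18            |
| D     | 0.45                      | 15            |
| E     | 0.70                      | 12            |
| F     | 1.00                      | 9             |
| G     | 1.20                      | 6             |
| H     | 1.35                      | 0             |

The root lengthens monotonically C→H and the apex closes exactly at H. The
step sizes are chosen so the stage-defining features remain resolvable
after the classifier's 250→90 downsampling; "sex" in the source cohort
becomes two geometry-scale cohorts (×1.00 / ×1.12). Per-case jitter
(relative s.d. 0.08, truncated at 2 s.d.) scatters crown size, root length
and apex gap without breaking stage ordering or the frame bound. The
background carries smooth low-frequency clutter (amplitude 0.08) and
salt-and-pepper impulses (2 % of pixels) — the latter specifically so the
7×7 median stage is observable end-to-end. Tooth/background contrast is
0.45 ± 0.04.

What the phantoms do **not** model: beam physics, neighboring teeth,
periodontal structures, blur/exposure variation, or anatomical root-shape
variety. Passing tests therefore demonstrate that the algorithms are
correct and well-behaved on the geometry they target, not that the pipeline
reaches any particular accuracy on clinical radiographs.

## Augmentation

Each labeled crop yields `factor` variants (default 10, reproducing the
240→2,400 expansion; the original counts as variant 1) by composing zoom
(±10 %), crop-and-resize (90–100 %), rotation (±15°), horizontal flip
(p = 0.5), Gaussian blur (σ ∈ [0, 1]), intensity rescale (±10 %) and
brightness shift (±0.1). Magnitudes are small enough to be
label-preserving: the stage is a shape ratio, which these transforms
perturb by at most a few percent. Variants are drawn from a generator
seeded by (plan seed, item id), so augmentation is reproducible and
independent of dataset ordering. By default augmentation is applied after
the train/test split and only to the training portion, preventing leakage
of near-duplicates into the held-out set; applying it before the split is
possible by simply expanding first.

## Classifier

The reference network (90×90×1 input) is: 3×3 conv 64 same → ReLU →
3×3 conv 64 stride 3 → ReLU → 2×2 maxpool → 3×3 conv 64 same → ReLU →
3×3 conv 64 stride 3 → ReLU → 2×2 maxpool → flatten (256) → dense 30 →
ReLU → dense 6 → softmax. Feature-map sides run 90, 30, 15, 15, 5, 2 and
the parameter counts are 640 / 36,928 / 36,928 / 36,928 / 7,710 / 186
(total 119,320), each reproducible from (k²·c_in+1)·c_out and
(n_in+1)·n_out. Stride-3 convolutions at positions 2 and 4 are the only
parsimonious layout consistent with both the printed shapes and counts.

Training uses softmax cross-entropy (the standard choice for a softmax
multi-class head), batch 8, 10 epochs, Adam(β₁ = 0.9, β₂ = 0.999,
lr = 10⁻³) by default; SGD, RMSProp and AdaGrad are available for the
50-epoch optimizer comparison. The 80 % training portion internally gives
up a stratified 20 % validation split for the learning curves. Weights use
He-normal initialization from an explicit seed; shuffling and dropout draw
from seeded generators, so a fixed seed reproduces a run bit-for-bit on the
same platform. The engine itself is a compact float32 im2col
implementation (`toothstage.nn`) sized exactly to this model family; 250-px
ROIs are resized to 90×90 bilinearly on input.

Model-selection utilities mirror the reference study protocol: a 27-point grid
over dense layers {0,1,2} × layer sizes {16,32,64} × conv layers {1,2,3}
ranked by final validation loss; the four-optimizer comparison on identical
splits and initial weights; and a dropout study (rates none/0.1/0.5/0.7/
0.9) applied to the 30-unit dense layer.

## Evaluation

Confusion matrices are 6×6 count grids (rows = reference, columns =
predicted, order C…H). Reports give row-normalized proportions to two
decimals, overall accuracy (trace/total), per-stage recall, and unweighted
Cohen's κ = (p_o − p_e)/(1 − p_e); adjacent-stage disagreements are not
discounted, so the statistic is conservative. Learning-curve summaries
report the best epoch (argmin validation loss) and an overfitting onset
defined as the first epoch whose validation loss exceeds its running
minimum for ≥ 2 consecutive epochs.

## Problem sizes used in the test suite

The acceptance battery runs at the pipeline's reference sizes where they
are cheap (240→2,400 augmentation; 1200×100 segmentation grids; 10-epoch
training on the 1,920 augmented training items) and at reduced sizes where
exhaustive verification is the point (DP oracle instances with M ≤ 5,
N ≤ 4, where all N^M tuples are enumerated; 60 noise-free phantoms for
segmentation recovery; 360-line grids in smoke tests). The end-to-end test
follows the full reference path — preprocess, segment, superimpose, then
augment and train — because the classifier is designed to consume the
segmented ROIs; on phantoms this path reaches ~0.85 held-out accuracy with
residual confusions confined to adjacent stages, the error structure
expected when classes form an ordered developmental sequence.

## Known limitations

- Exact cyclic closure costs a factor ~N more memory than one open-chain
  pass (it stores all suffix tables); at the recommended geometry this is
  ~100 MB. `two_pass` trades global optimality for constant memory.
- The DP is globally optimal only over the radial lattice: boundaries
  outside `radius_length`, or objects that are not star-convex about the
  seed, cannot be represented regardless of optimization quality.
- Phantom "sex" cohorts differ only in scale, a much weaker confound than
  real sexual dimorphism.
- The stage classifier is a fixed-resolution, single-tooth model; it does
  not localize teeth and inherits the manual seed-point step.
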