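# Methods

This note documents the models, numerical choices and limitations of
`fcdsurf`: a pipeline that detects focal cortical dysplasia (FCD) type II
lesions from vertex-wise multimodal features on cortical surface meshes.

## Surface representation and geometry

Each hemisphere is a pair of triangle meshes — the white (gray/white
boundary) and pial (gray/CSF) surfaces — with identical face arrays and
1:1 vertex correspondence, in RAS millimetres with 0-based indices.
Loading enforces the 2-manifold contract (every edge on one or two faces),
that every vertex is referenced, and strictly positive vertex areas.

* **Vertex area** is one third of the incident triangle areas, so vertex
  areas sum exactly to the surface area; all "area-weighted" means in the
  pipeline use this measure.
* **Normals** are area-weighted face-normal averages; counter-clockwise
  winding viewed from outside gives outward normals.
* **Geodesic distance** is Dijkstra shortest-path length over the edge
  graph, not an exact polyhedral geodesic.  At the scales used (6 mm
  doughnut, 25 mm deformation disc) the overestimate of edge-path versus
  exact distance is a few percent and is accepted; every geodesic
  operation is tested against an independent brute-force Dijkstra.
* **Mean curvature** uses the cotangent Laplacian: `H_i = (L x)_i · n_i /
  (2 a_i)`.  The sign convention is *concavity-positive*: sulcal fundi are
  positive, a convex sphere reads −1/R.  The convention is pinned by a
  test (orientation reversal flips the sign).  Boundary vertices of open
  meshes are masked NaN.
* **Gaussian curvature** is the angle deficit `(2π − Σθ)/a_i`; summed
  against vertex areas it reproduces 2πχ on closed meshes to machine
  precision.  Degenerate (zero-area) faces are excluded with a warning.

## Volume sampling

Scalar volumes (T1, FLAIR, PET) are assumed co-registered to the
surfaces.  Sampling is trilinear (exact for affine intensity fields,
which is tested); nearest-neighbour is available for label volumes.
Sample locations are either a fraction of the cortical ribbon,
`white + f·(pial − white)` with f=0 at the gray/white boundary, or a fixed
offset *into* white matter along the white-surface outward normal
(`white − d·n`).  Samples falling outside the volume grid become masked
NaN rather than clamped — silent edge artifacts are worse than missing
vertices.

## Features

| feature | definition | units |
|---|---|---|
| thickness | `‖pial_i − white_i‖` | mm |
| gwc | T1 at 30 % ribbon depth / T1 1 mm below boundary | ratio |
| mean_curvature | cotangent estimator on the white surface | mm⁻¹ |
| sulcal_depth | geodesic distance to nearest gyral crown (pial) | mm |
| lcd | area-weighted mean ǀKǀ over a 25 mm geodesic disc (pial) | mm⁻² |
| flair_00…flair_m10 | FLAIR at boundary, 25/50/75 % depth, 0.5/1 mm below | intensity |
| pet_hypo | PET at 50 % depth / area-weighted whole-cortex mean | ratio |
| doughnut_{gwc, thickness, flair_50} | 6 mm disc mean − 6–12 mm annulus mean, distances on the inflated surface | feature units |
| asym_* | `2(L−R)/(L+R)` through the homotopic correspondence, for every base feature | unitless |

Thirty features per vertex in total (15 base + 15 asymmetry).  Open
choices were resolved as follows, configurable where noted:

* **Gyral crowns** (sulcal depth): pial coordinates are neighbourhood-
  averaged 200 times; the signed offset of each vertex from its smoothed
  position along the smoothed normal is computed, and vertices within
  0.5 mm of the outer envelope (95th percentile of offsets) are crowns.
  On a flat sheet every vertex is a crown and the depth is zero.
* **LCD** uses the filled geodesic disc (not an annulus); an annulus
  variant would only change the feature smoothly and is not exposed.
* **PET** is sampled mid-cortex (50 % depth) and normalized by division
  with the area-weighted mean uptake over all valid cortical vertices of
  both hemispheres, making the map invariant to global uptake scaling.
  PET asymmetry is the asymmetry index of this map.
* **Doughnut** surround is the annulus with outer radius 2r; distances
  are computed on the surface passed by the caller (the inflated surface
  in the pipeline).
* **Asymmetry** uses the standard index 2(L−R)/(L+R), masked where
  |L+R| < 1e-9.

## Smoothing and two-stage normalization

Order is pinned by tests: smooth → within-subject z → between-subject z.

Smoothing is iterative heat diffusion `x ← x + τ A⁻¹ L x` with the
uniform-weight graph Laplacian L and vertex-area mass matrix A.  Because
L is symmetric, the area-weighted mean is conserved exactly; τ is capped
at 0.9·min(aᵢ/degᵢ) so the discrete maximum principle holds.  The
iteration count comes from a second-order expansion: one step adds
per-axis variance τ·Σⱼ|eᵢⱼ|²/(2aᵢ), so n = σ²/v̄ with σ² = FWHM²/(8 ln 2).
On a flat 1 mm grid a point source reaches half height at 5.0 mm for a
10 mm FWHM request (test tolerance ±15 %); on folded meshes the achieved
FWHM is approximate.  Masked vertices are excluded from diffusion (the
operator is re-balanced on the valid submesh) and stay masked.

Both z-stages use the population standard deviation (ddof = 0).  The
within-subject stage standardizes each map across valid vertices and
fails loudly on zero variance; the between-subject stage standardizes
each vertex against the control cohort's per-vertex mean/sd, masking
vertices with control sd below 1e-6 rather than inflating them.
Control statistics are fitted from control subjects only and serialize
to a single `.npz` archive with a JSON manifest.

## Classifier

Training rows follow the homotopic-sampling construction: every lesion
vertex contributes a positive row and its contralateral homotopic vertex
a negative row, balancing classes exactly; rows with any masked feature
are dropped in pairs.  PCA (95 % retained variance; constant columns
dropped with a warning) precedes a feedforward network with one hidden
layer of 10 logistic units and a logistic output.

Training splits off 15 % of rows as a held-out test set and 15 % as a
validation set (70/15/15).  The network is optimized by adam on
cross-entropy, one epoch per `partial_fit` call, and early-stops when the
validation cross-entropy has not improved for 20 epochs; the
best-validation-loss weights are restored.  (Monitoring validation
*accuracy* instead — as off-the-shelf early stopping does — saturates on
the small validation sets typical here within a few epochs and freezes
nearly untrained, uninformative probability maps.)  Rows are first
sorted into a canonical lexicographic order, so training is reproducible
given the seed and invariant to input row permutations.  The stored
detector (PCA basis + layer weights) is evaluated by the package's own
forward pass, which is cross-checked against scikit-learn's
`predict_proba` to 1e-12 in a test.

Cross-validation operates at **subject** level (vertex-level folds would
leak within-subject correlation), stratified by group so every fold holds
patients and controls, with a fresh random partition and fresh network
initialization per iteration.  Each fold trains on the remaining
subjects, picks the probability threshold maximizing Youden J (detection
rate minus control false-positive rate, grid 0.50–0.95 in 0.05 steps,
ties to the higher threshold) on its *training* subjects, and evaluates
the held-out subjects.  Clusters are connected components of
suprathreshold vertices on the mesh adjacency graph, filtered at
25 mm² minimum area and ranked by peak probability; a patient is
detected when the major (highest-peak) cluster overlaps the lesion
label.

## Evaluation statistics

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/total, with zero denominators reported as NaN.  Cohen's kappa
`(Po − Pe)/(1 − Pe)` carries the qualitative bands slight (≤0.20), fair
(≤0.40), moderate (≤0.60), substantial (≤0.80), almost perfect (≤1.00),
with inclusive upper edges.  Pearson's chi-square applies **no**
continuity correction (required to reproduce the reference worked
examples) and warns toward Fisher's exact test when an expected count is
below 5; Mann-Whitney U uses the normal approximation with tie
correction, two-sided.  Concordance is decided by the major cluster
only — a lower-ranked overlapping cluster does not rescue a discordant
call; Dice overlap is reported as an auxiliary quantity.

## Synthetic cohorts

The generator builds each hemisphere as a radial graph over an icosphere:
pial radius `r(u) = R + A·g(Ru)` with a smooth product-of-sines fold
field g (wavelength 18 mm, amplitude 2 mm over R = 30 mm), and the white
surface a cortical thickness below along the same ray.  Because meshes
and phantom-volume compartments evaluate the same analytic radius field,
geometry and voxel data are exactly consistent, thickness is exact, and a
star-shaped surface cannot self-intersect.  The right hemisphere is the
mirror image, giving an exact homotopic correspondence (identity index
map) that stands in for symmetric-template registration.  The sphere of
radius R serves as the inflated surface.

Real hemispheres are not mirror images, so each hemisphere additionally
receives its own low-amplitude secondary fold field (0.3 mm, 25 mm
wavelength) and a ±5 % spatially varying cortical thickness with
per-hemisphere random phases; asymmetry maps therefore have realistic
non-zero background, and exact mirror symmetry (under which all asymmetry
maps vanish identically — a tested property) is recovered by zeroing
these two parameters.  Per-subject jitter (3 % thickness, 5 % fold
amplitude) creates between-subject geometric variance for the control
statistics.

Phantom volumes are 1 mm isotropic with WM/GM/CSF compartments
(T1 120/80/30, FLAIR 70/100/30, PET 40/100/10), an acquisition
point-spread (0.5 mm for T1/FLAIR, 2 mm for PET) and additive Gaussian
noise (sd 3 per modality).  A planted lesion is a geodesic disc
(default radius 10 mm, smooth rim taper outside the labelled disc)
carrying the FCD signatures: the pial surface pushed outward by
Δthickness = 1.5 mm; T1 and FLAIR blended with a Gaussian-blurred copy
(σ = 2 mm) weighted by a radial window centred on the white surface, so
the gray/white boundary blurs (GWC rises toward 1, the vertical FLAIR
gradient drops) while upper-cortical FLAIR keeps its +15 %
hyperintensity; and GM PET uptake reduced by 40 %, which also produces
the interhemispheric PET asymmetry (−0.5 at zero noise through the
asymmetry-index arithmetic).  The resection label is the lesion disc
dilated by 4 mm.  Controls are identical constructions without a lesion —
the package approximates a non-FCD epilepsy control arm as "no cortical
lesion", since mesial pathologies are invisible to these cortical
features.

All randomness flows from a single cohort seed through per-subject seeds
recorded in the manifest; identical seeds give byte-identical manifests,
meshes and volumes.

## Problem sizes and runtime

Default meshes use icosphere subdivision 4 (2 562 vertices per
hemisphere) on a scaled-down R = 30 mm hemisphere; the end-to-end
recovery experiment (10 patients, 10 controls, 5-fold cross-validation,
5 iterations) runs in well under two minutes on one CPU at these sizes,
and the effect-size sweep uses subdivision 3 (642 vertices) with
6-subject arms.  These sizes were chosen so the whole study runs
interactively; all operators are resolution-independent.

## What the synthetic tests do and do not show

Passing end-to-end recovery demonstrates that the feature operators
measure the planted signatures in the right direction and magnitude, that
normalization makes them comparable across subjects, and that the
classifier/clustering/evaluation chain recovers focal effects under
noise.  It does **not** demonstrate clinical performance: the phantoms
lack registration error, bias fields, partial-volume structure beyond the
point-spread, inter-subject anatomical variability beyond the jitter
fields, transmantle signs, and the ambiguous lesion borders of real FCD.
Real cohorts of the size modelled here yield detection rates far below
the synthetic 100 %.

## Known limitations

* Edge-graph geodesics overestimate true geodesic distance on coarse
  meshes; all radii are interpreted in edge-path metric.
* The FWHM calibration is exact on flat sheets only; on strongly folded
  meshes the effective kernel is mildly anisotropic.
* The crown detector assumes fold amplitudes roughly uniform across the
  surface (global outer-envelope quantile); deeply nested sulci of real
  cortex would need a local crown criterion.
* The mirror-image homotopic correspondence is exact by construction;
  real interhemispheric registration error is not modelled.
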