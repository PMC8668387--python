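# Methods

This note records how `vesselmorph` computes its biomarkers, the design
choices behind the numerical details, what the synthetic generators emulate,
and the package's known limitations.

## From binary image to vessel graph

The unit of analysis is a 2D binary image in which nonzero pixels are
vessel. The substrate pipeline is:

1. **Skeletonization.** Sequential thinning (Zhang–Suen, via scikit-image)
   reduces each vessel to a one-pixel centerline; the skeleton is a subset
   of the vessel pixels and preserves 8-connectivity of each component.
2. **Branch-point detection.** A branch pixel is a skeleton pixel with at
   least 3 of its 8 neighbors set. Thinning a junction of strokes more than
   a couple of pixels wide routinely emits two branch pixels 2–4 px apart
   for one physical bifurcation, so branch pixels within a merge radius
   (default 2 px, disk dilation connectivity) are clustered into one branch
   point whose representative is the member nearest the cluster centroid.
3. **Excision and labeling.** The 3×3 neighborhood of every branch pixel is
   set to zero; the surviving 8-connected components are the vessel
   segments. Components smaller than `min_segment_px` (default 3) are
   absorbed into the excised set — they are junction-gap orphans, not
   vessels. Segment length is the 8-connected chain length (axial step 1,
   diagonal √2); V̄L is the mean segment length after excision. The number
   of sub-vessels N_SV at a branch point is the count of distinct segment
   labels on the ring of pixels just outside its excised region (for a
   single branch pixel, the 5×5 window minus the 3×3 excision). Branch
   points with fewer than two incident segments are flagged degenerate and
   excluded from MD/BA.
4. **Diameters.** `diameters_px[i]` is twice the Euclidean distance
   transform of the binary image sampled at path pixel *i* — the textbook
   definition, kept as-is. For the diameters that enter Murray's deviation
   and mother selection, each segment additionally carries a **caliber**,
   an area-based mean width described next.

### The caliber estimator

Sampling 2×EDT on the centerline is noisy in a specific, angle-dependent
way: a digitized straight stroke has a boundary staircase whose period can
be long, so the minimum-distance value does not dither away along the path;
near junctions the union of strokes inflates it. The caliber instead:

- attributes every vessel pixel to its nearest labeled skeleton pixel
  (Voronoi partition of the vessel area by the centerline),
- trims a deterministic margin at each path end — at a junction end, the
  blob radius (EDT at the branch point + 1 px) plus two reference diameters,
  which covers the "hug zone" where two strokes have not yet separated; at a
  free end, half a reference diameter + 1 px for the rounded tip cap (the
  reference diameter is the median sampled diameter over the half of the
  path farthest from any branch point),
- divides the attributed area of the surviving run by its centerline
  length. The length uses the extent of the projections onto the run's
  principal axis when the run is straight (residual RMS < 0.6 px) — pixel
  jitter averages out in the fit — and chordal subsampling (7-px chords)
  for curved runs; chain length with √2 diagonal steps is avoided here
  because it overestimates Euclidean length by up to 8%. Half-step Voronoi
  corrections are added at the run ends.

On straight synthetic strokes of known width in general position this
estimator is unbiased to a few hundredths of a pixel; its accuracy is what
makes the cube-amplified Murray's deviation recoverable at mother widths of
10 px.

## Murray's deviation

For every non-degenerate branch point, the incident segment with the largest
caliber is the mother (ties broken by the longer segment, then the lowest
label); MD = |D_m³ − Σ D_d³| / D_m³. Branch points with any nonpositive
diameter are excluded with a warning. MD is computed for every branch point
with at least two incident segments; it is homogeneous of degree zero in the
diameters (scale-invariant).

## Bifurcation angle

Only branch points with exactly three sub-vessels carry an angle. For each
of the two daughters, the near-branch portion of the path is selected by the
daughter-length rule (whole daughter when its length L_D ≤ 3 px, half when
3 < L_D ≤ V̄L, the first fifth when L_D > V̄L, portion measured as path arc
length). The portion window opens where the path exits the junction blob, so
blob exclusion never shortens the fitted length; if fewer than 5 pixels
survive, the window is extended along the path.

The daughter direction is a total-least-squares (principal axis) fit.
When the binary image is available, the fit uses the daughter's full
cross-section — every vessel pixel attributed to the window's path pixels,
minus wedge pixels near the junction — rather than the 1-px skeleton: the
skeleton of a digitized line carries staircase structure with a period
comparable to the truncated windows, which can tilt a 20-px skeleton fit by
1–3°, while the cross-section fit averages the wall quantization and stays
within a fraction of a degree for ~40-px windows. Without an image, a
smoothed skeleton fit is used, with a second pass at narrow angles that
excludes the region where the daughters have not yet separated. Directions
are oriented away from the branch point and the angle is reported in
(0, 180]; collinear daughters (angle → 0) are flagged degenerate.

Accuracy depends on window length: with ~70-px fit windows the estimator
matches analytic angles to 0.2° across all orientations; at ~20-px windows,
worst-case errors of 2–3° at near-lattice directions are an information
limit of the raster, not a fitting defect.

## Fractal dimension

The image is zero-padded bottom/right to the next power-of-two square, the
box grid is anchored at the origin (no grid-offset averaging — single-grid
counting is bit-reproducible), and every dyadic scale from the padded size
down to 1 px enters the first-order fit of log N_S on log(1/S) with no
plateau trimming. A filled image reads 2.0 exactly, a 1-px line 1.0 exactly,
and a depth-5 Sierpinski carpet 1.88 against the closed-form 1.8928. A
single-pixel image has flat counts; the fit is declared degenerate and 0 is
returned with a warning.

## Spatial vascularity pattern

The lesion mask (largest component, if disconnected) is eroded with a disk
(default radius 3 px); the geometric center is the area centroid of the
eroded mask; r_max is the largest centroid-to-mask distance; the center
region is the eroded mask within `center_fraction × r_max` (default 0.5,
about a quarter of the area for a disk — the split radius, erosion element
and radius are unspecified upstream and are configurable here); the rest is
peripheral. Density is the vessel-pixel fraction of each region;
VDR = density_center / density_peripheral, with a zero peripheral density
mapped to VDR = +∞; SVP = 1 iff VDR ≥ 1 (the tie goes to 1). A lesion whose
regions cannot both be populated raises an error rather than returning a
silent zero. The interpretation layer maps (SVP, lesion size) to a
benign-/malignant-leaning label with the size threshold at 20 mm inclusive.

## Synthetic validation models

The generators replace hand-drawn CAD models with parameterized geometry.
All preset means are met exactly at spec level: per-junction values are
drawn around the preset (angles: normal, σ = 6°, clipped to (15°, 165°);
MD targets: normal, σ = 0.05, clipped to [0.02, 0.95]) and the last junction
solves the mean constraint, so measured deviations are purely
rasterization + estimation error.

- **Layout.** Junctions sit on a jittered 3×3 grid in a 1024×1024 canvas
  (margins sized so arms never overlap); 9 junctions per model fill the
  grid — enough for the model mean to stabilize against per-junction
  quantization noise. Strokes are rasterized as center-in-disk polylines
  (a pixel is on iff its center is within width/2 of the polyline),
  deterministic for a given spec.
- **BA models** (presets 120°/100°/80°): straight mothers (6 px wide,
  90 px) running into Y-junctions with straight 4-px, 60-px daughters
  symmetric about the mother's continuation. The mother is wider than the
  daughters so largest-diameter mother selection is unambiguous.
- **MD models** (presets 0.2/0.4/0.6): mother width 10 px; symmetric
  daughter widths solved from each junction's target m as
  w_d = w_m ((1 − m)/2)^(1/3).
- **General position.** Stroke directions are rejected within 6° of
  lattice-rational slopes (0, ±1/2, ±1, ±2, ∞): a constant-width stroke
  rasterized along such a direction has a systematically rounded width that
  no amount of averaging recovers. The validation therefore tests the
  estimators in general position, the condition an arbitrary CAD drawing
  represents.
- **Pattern models**: a disk lesion (radius 320 px) with short wavy strokes
  confined well inside the center region, or arcs confined to the
  periphery; by construction ≥ 90% (in practice 100%) of vessel pixels land
  in the designated region.
- **Complexity models**: three networks of increasing stroke count,
  waviness and branching (4 straight strokes → 24 wavy strokes with 12 side
  branches), giving strictly increasing mvFD.

With these conditions the end-to-end recovery errors are ≈ 0.1–0.25% for
the BA battery and ≈ 0.5–2% for the MD battery across seeds.

## Synthetic cohorts

`make_cohort` draws per-lesion parameter vectors for benign and malignant
groups from truncated normal distributions at the published group means and
standard deviations (e.g. MD mean 0.29 ± 0.13 vs 0.40 ± 0.12; BA mean
110.28 ± 24.21 vs 95.86 ± 10.37; mvFD 1.13 ± 0.09 vs 1.28 ± 0.03; VDR
0.70 ± 0.38 vs 1.95 ± 0.62), truncated at physical bounds (MD ≥ 0,
BA ∈ (0, 180], mvFD ∈ [1, 2], VDR > 0). SVP is Bernoulli with
P(SVP = 1) = 5/35 (benign) and 21/25 (malignant); lesion size is a
truncated normal 15.86 ± 7.81 mm on [5, 40]. Draws are independent across
parameters (the real covariance is unpublished); the (min, median, max)
order statistics of MD and BA are sorted after drawing and the mean clipped
into [min, max] so each row is internally consistent — which slightly
distorts those marginals relative to their nominal normals.

What the cohorts do **not** emulate: inter-parameter correlation,
measurement error of the upstream imaging chain, histologic subtypes, or
any image-level structure (the cohort rows are parameter vectors, not
images). Passing cohort tests therefore demonstrates the statistics
machinery and the published effect sizes' power — not in vivo
reproducibility.

## Statistics

Continuous group comparisons use the two-sided Wilcoxon rank-sum
(Mann–Whitney U, asymptotic with tie correction); the binary SVP uses
Pearson chi-squared on the 2×2 table without continuity correction
(configurable). ROC analysis computes AUC by the rank statistic (equal to
the concordant-pair fraction), auto-orients so AUC ≥ 0.5, takes the
operating point maximizing Youden's J (sensitivity + specificity − 1 — the
operating-point rule is unstated upstream; Youden is the standard choice in
breast-imaging ROC reports), and derives a 95% CI from a seeded stratified
bootstrap (2000 replicates) — chosen over DeLong for implementation
simplicity. Panels are combined by maximum-likelihood logistic regression;
on perfect separation the fit falls back to a ridge-penalized model with a
warning. Panel AUCs are in-sample (apparent) performance; no
cross-validation is claimed.

## Degenerate inputs and tie-breaks

- Empty image → "no vessels" error everywhere (CLI exit code 2).
- Single-pixel image → mvFD 0 with a degenerate flag and warning.
- Mother tie on diameter → longer segment, then lowest label.
- VDR tie (= 1) → SVP = 1.
- Zero bifurcations → MD/BA summary statistics reported as missing (None),
  never as zero.
- All-tied group comparison → p = 1 with a warning.

## Limitations

- All metrics are 2D; out-of-plane branching makes 2D angles
  underestimates of their 3D values, and a 2D slice under- or over-states
  density, complexity and connectivity.
- The caliber and BA estimators assume vessels a few pixels wide or more;
  at widths below ~3 px the quantization dominates.
- Box counting uses a single origin-anchored grid; mvFD values are
  comparable within this package but can differ in the second decimal from
  implementations that average grid offsets.
- The upstream segmentation (clutter filtering, vessel enhancement,
  binarization) is out of scope; all guarantees are conditional on a clean
  binary input.
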