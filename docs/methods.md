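# Methods

## Problem and scope

The package quantifies interfractional anatomical change in paediatric
abdominal radiotherapy from binary segmentation masks (body contour and GI
gas) of one planning scan and up to five weekly treatment scans per patient,
and simulates the residual corrections an optical surface-guidance (SGRT)
system would measure. It consumes masks only: segmentation itself and
grey-value (intensity-based) registration are out of scope, and all
registration steps therefore operate on mask surfaces.

## Coordinate conventions

All volumes are reoriented on load to a fixed patient frame: x = left–right,
y = posterior→anterior (+y anterior), z = inferior→superior. Coordinates are
voxel-centre based with 0-based indexing; the world position of voxel *i* is
`origin + i · spacing`. Masks are binarised at 0.5 so probabilistic and
0/255 masks load identically. This axis choice makes the anterior-posterior
SGRT translation the y-parameter (t_y) and the left–right-axis rotation the
x-parameter (r_x).

Rigid transforms carry (t_x, t_y, t_z) in mm and (r_x, r_y, r_z) in degrees,
rotations applied intrinsically about x then y then z about a stated centre
(body centroid for scan alignment, treatment isocenter for the SGRT
decomposition). Registration functions return the *pose offset* of the
moving surface relative to the fixed one (`moving = T(fixed)`): a treatment
scan whose wall sits 3 mm anterior of planning reports t_y = +3, and the
transform that aligns it back is `T.invert()`. This choice makes a net gas
loss appear as a negative t_y, matching the sign structure of the clinical
summaries the defaults are calibrated to.

## Mask post-processing

Manual contours carry stereotyped errors; cleanup is deliberately
conservative and idempotent:

* body: keep the largest 26-connected component, fill cavities slice-wise in
  axial planes (catches lumina open along z) and in 3D;
* gas: intersect with the body eroded by one voxel (excludes skin-adjacent
  air), then drop 26-connected components below `min_component_ml`
  (default 0.1 ml — below CBCT speckle scale, far below any real pocket).

The cleaned gas mask is always a subset of the cleaned body mask.

## Surface metrics

Surfaces are sub-voxel iso-surface vertices (marching cubes at level 0.5 on
the one-voxel zero-padded mask), which roughly halves the discretisation
bias of voxel-centre surfaces; the KD-tree nearest-neighbour distances are
validated against exhaustive all-pairs enumeration to 1e-6 mm in the test
suite.

Body separation pools both directions into a single distribution: for each
test-surface point, distance to the nearest reference point, negated when
the point lies inside the reference body; for each reference point, distance
to the nearest test point, negated when the point lies *outside* the test
body. Shrinkage is therefore negative from both directions. The pooled
distribution is summarised by its signed and unsigned means. Pooling (rather
than averaging two one-directional means) weights each sampled surface point
equally; with comparable surface areas the two rules differ negligibly.

The anterior-wall surrogate maps each (x, z) column in an analysis window to
the anterior face of its anterior-most body voxel. The default window keeps
the central 60% of the body's left–right width and the full z-range of the
common field of view; only columns present in both maps are compared, and
the per-column differences (test − reference, positive = distension) are
summarised the same way. Map heights are voxel-face quantised, so one voxel
is the resolution limit of any wall-displacement statement.

Gas volume is voxel count × voxel volume. `Gas_std` uses the sample (n−1)
SD across all included timepoints; `Gas_rel` is fraction − reference, so a
cohort losing gas relative to planning has negative mean `Gas_rel`.

## Registration

Scan alignment and the SGRT simulation share one ICP core: point-to-point
correspondences against a KD-tree, closed-form Kabsch updates, and adaptive
trimming — matches farther than 3× the median match distance are dropped,
capped at `2 · trim_fraction` of points per iteration (default
trim_fraction 0.1). The fixed-quantile trimming often described for trimmed
ICP was measured here to *create* local minima on fully overlapping anterior
domes (it discards exactly the boundary points that disambiguate sliding),
while the distance-adaptive rule keeps everything once the clouds agree and
still rejects the unmatched region when a fifth of one cloud is missing.

Smooth shallow surfaces admit sliding local minima regardless, so the solver
is multi-start: centroid init, principal-axes init (signs resolved toward
the identity), plus three seeded small-rotation restarts; the candidate with
the lowest trimmed mean residual wins. With this scheme, noise-free anterior
clouds perturbed within ±10 mm / ±5° are recovered to machine precision
(tested at 0.1 mm / 0.1° over 100 trials, and 0.5 mm / 0.5° with 20% of
columns missing). On voxelised masks, nearest-neighbour resampling limits
recovery to about half a voxel (tested at 0.5 mm / 0.5° on a 3 mm grid).

For each patient the weekly scans are registered to the reference scan by
whole-body-surface ICP, resampled into the reference grid (nearest
neighbour — binary preservation at half-voxel positional uncertainty), and
both scans are cropped to the intersection of their valid world extents so
metrics never compare anatomy against empty space. The SGRT step then
translates both scans so the isocenter (planning body centroid for synthetic
cohorts, where no plan exists) is the origin, extracts anterior clouds, and
registers treatment→planning; point-to-point residuals were chosen over
point-to-plane as the classic formulation — the anterior window is curved
enough that the distinction was not limiting.

## Synthetic cohorts

Two layers share one generative model.

The **truth layer** draws per-patient covariates and per-scan latent states:

* age = 2 + LogNormal(0.7, 0.75) years, capped at 19 (median ≈ 4);
  anaesthesia with probability 0.65 for ages < 5.5 y and never above
  (young children cannot reliably lie still); feeding tube independently
  with p = 12/21; sex with p(male) = 10/21;
* planning gas volume ≈ N(260, 80) ml; weekly volume = planning + patient
  trend (N(−86, 60) ml, the net reduction versus planning) + N(0, σ) noise
  with σ = 110 ml under anaesthesia versus 25 ml without (×LogNormal(0,
  0.25) patient jitter), floored at 5 ml;
* anterior-wall displacement = 2.5 mm per 100 ml of gas change (linear
  distension coupling); girth drift = −0.10 (tube) or −0.45 (no tube)
  mm/week ± 0.25;
* per-fraction setup error: translations N(0, 3 mm), rotations N(0, 1.5°),
  truncated at ±10 mm / ±5°.

The measurement-emulation map from latent states to metric tables adds the
residual variation the voxel pipeline would contribute (surface 2.2 mm, body
1.0 mm, t_y 2.2 mm, r_x 1.7°, plus small unsigned floors), dilutes the wall
signal in the whole-body metric (wall share 0.35 — the anterior window is a
minority of the body surface), and couples r_x negatively to gas change at
0.7°/100 ml. These constants were calibrated once so that a 21-patient
cohort lands on the reported clinical scales (mean `Gas_std` ≈ 74 ml, mean
unsigned body/surface separations ≈ 2 / 4 mm, correlation of `Gas_rel`
strongest with the anterior surface and with t_y, weaker and negative with
r_x) and were not revisited afterwards.

The **rendering layer** realises the same states as voxel masks: a
superellipsoid torso (exponent 2.5 — boxier than an ellipsoid, as torsos
are; closed-form volume available for checking), girth drift as a scale on
the two axial semiaxes, the wall displacement as a plateau-cosine outward
warp of the anterior half (plateau over the central ~55% of width/height so
the peak displacement equals the nominal shift and the warp is
translation-like over the window), and gas as the union of jittered
mid-abdominal ellipsoidal pockets grown until the voxelised volume matches
the target within half a voxel. The whole scan is then resampled under the
setup transform. The ground-truth log (volumes, shifts, scales, transforms)
is a deterministic function of (config, seed).

What the generator does **not** emulate: CBCT intensity physics (scatter,
streaks), organ-level bowel motion, non-rigid posture change, or
segmentation error beyond the cleanup operators' domain. Passing tests
therefore demonstrate the pipeline's correctness and sensitivity under the
modelled mechanism, not robustness to real-image artefacts.

Cohort-scale statistical checks (type-I error over 1000 seeds, mechanism
orderings over 100 seeds) run on the truth layer; rendering that many
cohorts would add voxel noise but thousands of CPU-minutes. The voxel path
is validated separately: analytic phantom values, brute-force distance
oracles, parameter recovery of wall displacement and setup transforms, and
a bit-reproducible end-to-end run. The rendered **reference fixture**
(`CohortSimConfig.reference_fixture()`) is a six-patient cohort on a
child-size ~1 l torso at 3 mm spacing with the gas process scaled to that
volume and the distension coupling raised to 8 mm/100 ml so wall shifts
stay above the voxel floor; it keeps end-to-end runs around a minute.

## Statistics

* **Mann-Whitney** (two-sided): exact by dynamic-programme enumeration of
  the conditional rank-sum distribution (midranks for ties) for
  n_a + n_b ≤ 20; normal approximation with tie correction above. Two-sided
  p = min(1, 2·min tail).
* **Spearman**: midrank correlation; exact permutation p for n ≤ 9, t
  approximation otherwise.
* **Exact conditional logistic regression** (binary outcome, one continuous
  covariate): inference conditions on the outcome total, under which the
  sufficient statistic T = Σxᵢyᵢ is uniform over same-total outcome vectors;
  subsets are enumerated when C(n, Σy) ≤ 2×10⁶ (all cohort-size cases),
  otherwise sampled by seeded Monte-Carlo. The coefficient is the
  conditional MLE (solving E_β[T] = T_obs); at the boundary of the support
  (complete separation) the median-unbiased estimate is returned and
  flagged. This is the one non-routine estimator in the design and is
  implemented from first principles, with enumeration oracles in the tests.
* **Multivariate OLS** (`Gas_std ~ age + GA` by default) via statsmodels,
  with collinear columns named on rank deficiency.
* Age is dichotomised at 3.5 years; α = 0.05, two-sided, uncorrected (the
  12-cell predictor grid additionally reports a Holm-adjusted column).
* **Sensitivity re-analysis**: all metrics recomputed excluding the planning
  scan, with a seeded random treatment scan as each patient's reference;
  patients with fewer than two treatment scans are dropped with a warning.

## Reproducibility

One global seed is fanned out to stages through `SeedSequence` offsets, so
any stage can be re-run from cached upstream outputs bit-identically. Runs
write a provenance record (config SHA-256, seed, package/numpy versions,
stage log). The acceptance script derives every random stream from its
`--seed` argument.

## Known limitations

* Half-voxel quantisation bounds all mask-level accuracies; sub-voxel claims
  are only valid for the point-cloud paths.
* The exact logistic model handles a single covariate (as used here);
  multi-covariate conditional inference is not implemented.
* The ICP residual-selection heuristic across restarts assumes the global
  minimum has a visibly lower trimmed residual; pathological symmetric
  surfaces (e.g. a perfect plane) remain ambiguous and planar clouds rely on
  window curvature.
* Truth-layer noise terms are Gaussian and independent across fractions;
  real interfractional variation is temporally correlated.
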