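# Methods

## Coordinate and laterality conventions

Pixel (row r, col c) of slice k maps to the millimetre point
(x = c·col_spacing, y = r·row_spacing, z = k·slice_spacing), 0-based.
x is medial–lateral, y anterior–posterior (posterior = −y), and z the
slice axis, normalised so it increases tibia → femur: after
classification, the slice-label sequence determines the anatomical
direction from the median positions of the `Fibula/Tibia` and `Femur`
runs, and the stack is reversed if needed. All detection and
segmentation models are left-knee models; a right-knee request flips
every slice horizontally immediately after ingest, so the classifier,
detector and segmenters always see left-frame images and the flip
happens before the detection step. Ground-truth meshes are kept in the
left frame throughout.

## The synthetic phantom population

The generator stands in for a clinical CT + segmented-mesh cohort. A
single template per bone is built by marching cubes over an analytic
implicit field (two condylar lobes plus a shaft for the distal femur; a
flat-topped plateau, shaft and anterior tuberosity for the proximal
tibia; a thin fibula cylinder) and lightly Laplacian-smoothed. Subjects
are the template plus a linear combination of three fixed displacement
fields:

| mode | meaning | default sd | units |
|---|---|---|---|
| 0 | global scale about the knee centre | 0.05 | dimensionless |
| 1 | condyle/plateau medial–lateral spread | 2.0 | mm |
| 2 | plateau/condyle slope (z ∝ ML coordinate) | 1.2 | mm at the rim |

plus iid vertex jitter (0.2 mm sd). The scale sd corresponds to a ~4 mm
sd of ML width on a ~70 mm knee, a realistic adult spread; sex is
assigned from the sign of the scale weight so it is a size-correlated
covariate without changing the marginal mode distribution. Because the
modes are linear displacement fields on one template, (a) all subjects
are in vertex correspondence by construction, and (b) the population's
shape space is exactly 3-dimensional, so statistical-shape-model recovery
(variance concentration, weight recovery) can be tested against known
truth.

Voxelisation takes planar cross-sections of each mesh at the slice
heights (even–odd loop nesting), rasterises them at 0.8 mm pixels / 1 mm
slices into a 200 × 200 px frame, paints bone / a soft-tissue ellipse /
air at three stored intensities (HU + 1024: 2224 / 1064 / 24) and adds
Gaussian noise (sd 20 by default). There is no partial-volume blending,
cortical/trabecular texture, pathology or patella — passing tests
therefore demonstrate the pipeline's geometric and statistical
correctness on clean anatomy, not robustness to real scanner physics.
Per-slice class labels come from the subject's own geometry: `Other`
outside the tissue range, `Fibula/Tibia` where the fibula exists,
`Knee` from the fibula head to the condylar top, `Femur` above. The
fibula head ends ~16 mm below the joint line and the tibial
plateau/tuberosity flare spans that gap, so each class boundary has a
visible image cue; the anterior tuberosity also breaks the tibia's
front/back near-symmetry, which planar-contour ICP needs to resolve
orientation.

## Learned stages

No deep-learning stack is pre-installed in this environment, and the
slice classes / boxes / masks of these phantoms are separable by much
smaller models, so the three image models are deliberately compact
scikit-learn networks behind the same contracts (train on
subject-disjoint splits, persist, report validation metrics):

- classifier — MLP (one hidden layer, 64 units) on 8×8-block-pooled,
  intensity-normalised slice images; 4-class softmax; label/probability
  argmax consistency guaranteed.
- ROI detector — MLP regressor on the same pooled features predicting
  box centre and size; the per-volume ROI is the 160 px square at the
  per-axis lower-median of the per-slice centres, clamped to the image.
- per-bone segmenters — a slice gate (MLP on the pooled crop, deciding
  whether this bone appears at all — the pooled view carries the
  condyle-vs-plateau shape context) multiplied by a per-pixel classifier
  on five local features (intensity, Gaussian blurs at σ = 2/4/8,
  gradient magnitude), thresholded at 0.5.

Label sequences are smoothed by sliding-window majority vote (window 5,
ties keep the original label), and the knee region is the longest
contiguous `Knee` run — scattered misclassifications inside the region
are healed by the vote, and stray islands outside lose to the main run.

Contours are traced with marching squares on the binary masks, which
directly yields ordered sub-pixel closed polylines; inner (hole)
contours are discarded and polylines shorter than 30 px are dropped as
segmentation noise (the threshold is a config value chosen so genuine
bone outlines — perimeter ≥ ~60 px on these phantoms — always survive).

## Transition and stacks

Per-slice segmented areas (positive pixels × pixel area) of the two
bones are scanned between their argmaxes (tibia argmax must precede the
femur argmax in tibia→femur order); the transition is the first slice at
which the femur curve meets or exceeds the tibia curve, with equality
resolving to that slice. The tibia stack keeps slices
[knee_start + trim, transition), the femur stack [transition,
knee_end − trim), trim = 5: the trim is applied at the stack ends away
from the joint, where end-of-region segmentation noise concentrates.
Slices whose contours were entirely filtered are skipped (the stack's z
list stays strictly increasing but may have gaps); the largest surviving
contour per slice is used.

## Shape models and morphing

SSM training: generalised Procrustes alignment (rigid only — no scaling,
so absolute size lives in the modes, consistent with the synthetic scale
mode) followed by SVD of the centred vertex matrix. Mode rows are
orthonormal, variances non-increasing; the mean mesh can optionally be
Laplacian-smoothed (`ssm_smooth_iters`, default 0) to idealise the base
shape.

Registration: closest-point queries are exact point-to-triangle
projections with KD-tree candidate faces (24 nearest face centroids) —
`rtree` is unavailable here, and exact projection is needed anyway for
the 1e-3 mm ICP recovery bar. Stack-to-base initialisation matches
centroids and in-plane principal axes (z stays the slice normal); the π
ambiguity of the principal axis is resolved by running ICP from both
candidates and keeping the lower residual. ICP alternates closest-point
correspondence with a Kabsch solve and returns the best iterate.

Morphing fixes correspondence as barycentric coordinates on the current
synthesized surface — making the surface point linear in the weights —
and solves a bound-constrained linear least squares for the first
`n_pc = 2` weights (|w_i| ≤ 3 sd_i, preventing extrapolation blow-up),
iterating to convergence; the mean squared distance is non-increasing
across outer iterations and a non-converged run returns the best iterate
with a flag. Two components are enough to capture the dominant scale and
spread variation while ignoring local imperfections; the third
(slope) mode is deliberately left unfitted, and its 1.2 mm-rim sd is the
main contributor to the residual prediction error.

## Implant geometry

All design operations are deterministic mesh geometry; no boolean engine
is available, so solids are built boolean-free. Femoral component: the
prediction is clipped by the cut plan — anterior, anterior chamfer,
distal (transverse), posterior chamfer, posterior planes whose offsets
are fractions of the condylar AP extent, plus medial/lateral trims as
fractions of ML — with normals pointing at the retained articular side.
The clipped patch is the articular surface; its inward offset by the
1.5 mm shell is the bone-facing surface; side walls stitched between the
boundary loops close the shell, and two 3 mm-radius pins are appended as
separate closed bodies. The cut-template fractions and pin dimensions
are editable config defaults (no published values exist for the generic
component). Tibial plate: the prediction is levelled so the
least-squares plateau plane (fitted to the top 12 % of the z-extent —
wide enough to span a tilted plateau top) is horizontal; the widest
point on the medial half sets the section height 2 mm further distal;
the largest closed intersection loop is extruded to 5 mm via constrained
Delaunay triangulation, with a posterior notch cut from the profile, a
partial-depth central bearing recess (built as two stacked extrusions)
and a distal fixation pin.

Resection mirrors design: the ground-truth femur is clipped by the same
plan (carried through the ICP alignment transform into the ground-truth
frame) and the ground-truth tibia sectioned at the same levelled plane.

## Fit metrics

Prediction RMSE samples the prediction surface uniformly (2000 points,
seeded), restricted to the z-band covered by the fitted contour stack —
the concrete reading of "the condylar regions", since that is the region
the stack constrains — ICP-aligns the samples to the ground truth and
takes the root mean squared closest-point distance. Component fit:
femur — the component is aligned by ICP of its articular (outer) surface
samples onto the ground truth (pins excluded), RMSE is evaluated over
the bone-facing surface (so the self-fit RMSE equals the shell
thickness, within tolerance), and OUH is the directed Hausdorff distance
from the component's boundary edge loops to the resected ground truth's
loops (all loops, resampled at 0.5 mm). Tibia — RMSE and OUH compare the
full base profile against the equivalent ground-truth profile after
rigid 2-D alignment; the posterior notch and bearing cut are excluded
from the comparison because the plate interfaces with the resected bone
through its base profile only. The 3 mm OUH flag is inclusive and
config-overridable.

Cohort utilities use Welch (unequal-variance) two-sample t-tests with a
1.5 × IQR outlier rule applied per group (replacing manual
quantile–quantile inspection with a stated automatic rule), Spearman
correlations for continuous covariates, and significance thresholds
p ≤ 0.05 and |r| ≥ 0.5.

## Problem sizes and numerical choices

The shipped experiments run on one CPU at desk scale: templates meshed
at 1.25 mm pitch (≈7 k vertices/bone), 200 × 200 px volumes of 92
slices, cohorts of 20 training + 10 held-out subjects for the end-to-end
benchmark, 50 phantoms for transition detection, 500–2000 surface
samples for ICP/RMSE with fixed seeds. ICP tolerance is 1e-6 mm mean
improvement; morphing runs at most 25 outer iterations with a 1e-8
objective tolerance; degenerate inputs (collinear ICP sources, empty
stacks, all-empty masks, non-intersecting area curves, cut plans that
empty the mesh) raise typed, stage-tagged errors rather than crashing.

## Known limitations

- The phantoms are clean, three-mode, single-knee anatomies; results do
  not speak to scanner artefacts, osteoarthritic deformity, implants in
  the field of view, or bilateral scans.
- The learned stages are small networks adequate for the phantom domain;
  real CT would need substantially larger models behind the same
  contracts.
- Fillets and chamfers on the implants are omitted (they do not enter
  the RMSE/OUH metrics as defined); the femoral cut-template fractions
  are package defaults, not published implant geometry.
- Non-rigid registration of uncorresponded training meshes is out of
  scope: shape-model training assumes vertex correspondence, which the
  generator guarantees by construction.
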