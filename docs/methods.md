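# Methods

This note documents the models, conventions and numerical choices behind
`mssm`, the reasoning where the design was genuinely open, and what the
synthetic experiments do and do not demonstrate.

## Feature model

**Depth surfaces.** Gray matter is sampled on surfaces at fractional
depths 0.2, 0.4, 0.6, 0.8 of the cortical ribbon, where the surface at
fraction f has vertices `(1−f)·white_i + f·pial_i`.  The white→pial
straight segment is the correspondence the surface reconstruction
provides; Laplace-field streamlines or equivolumetric laminar models are
deliberately out of scope.

**White-matter surfaces.** WM intensity is sampled 0.5 and 1.0 mm below
the gray/white border, displacing each vertex along its inward normal.
Vertex normals are the angle-weighted average of incident face normals:
deterministic, independent of face ordering, and exactly radial on the
spherical phantoms up to mesh discretisation (~1e-4 relative).

**Ratios.** The 8 contrast features are GM(depth)/WM(offset).  The
direction is a convention — the ratio could equally be inverted (a config
flag flips it); GM/WM was chosen so that T1-like contrast gives values
below 1 that move *toward* 1 as gray/white contrast is lost, i.e. disease
increases the feature.  Ratios are undefined (NaN, never silently zero)
where the WM sample is non-positive or any sample falls outside the grid.

**Sampling.** World-mm coordinates map to continuous voxel indices
through the inverse affine; interpolation is trilinear (nearest-neighbour
available for ablation).  All coordinates are world-space mm, RAS, with
0-based voxel indices; nothing ever addresses the grid directly.

## Surface smoothing

Smoothing is iterative neighbour averaging (each pass replaces a value by
the mean over the vertex and its one-ring, self included with the weight
of one neighbour), the classical surface-based approximation of a
Gaussian kernel.  The number of passes is calibrated empirically per
mesh: a unit impulse is smoothed step by step and the Euclidean
distance-weighted standard deviation compared with the target
σ = FWHM/2.3548.  Because integer pass counts quantise the achievable
width — on coarse meshes a single pass can already overshoot σ for
FWHM 5 mm — the final pass is a fractional relaxation `(1−λ)·v + λ·avg(v)`
with λ solved in closed form (the impulse second moment is linear in λ).
Calibration is cached per (mesh, FWHM).  Undefined vertices are excluded
from every average and stay undefined.  All 9 features are smoothed with
the same kernel by default; a flag exempts thickness.

Verified properties: constants are fixed points, the elementwise maximum
principle holds, smoothing commutes with adding a constant, total mass on
the closed icosphere drifts <1% per 10 passes, and the impulse-response σ
lands within 15% of the target on every mesh used.

## Vertex-wise PLS reduction

At each vertex the 9 features over training subjects are min-max
normalised to [0,1]; features and the {0,1} label are centred; the first
PLS1 weight vector is the closed form `w = Xᶜᵀyᶜ/‖Xᶜᵀyᶜ‖` (equal to the
NIPALS first component for a single response — asserted against an
independent NIPALS oracle to 1e-8).  Exactly one component is extracted.
Zero-variance features get weight 0 before normalisation; a vertex with
all-zero cross-covariance is undefined.  The sign is fixed so the
component correlates non-negatively with the label in training (with this
weight rule the training covariance is `‖Xᶜᵀyᶜ‖ ≥ 0` automatically; the
explicit flip keeps the convention robust to any future weight rule).
Transforms of validation/test/transfer subjects reuse the training
min/max and centring constants verbatim and are not clipped to [0,1].
The reduction is fitted on the training split only; a flag refits on
train+validation for a final model.

## Group statistics

Vertex-wise contrasts are unadjusted pooled-variance two-sample t-tests
(phantom and the motivating cohorts are matched by design; a
covariate-adjusted GLM is a flag away).  Cohen's d uses the pooled SD.
FDR is Benjamini–Hochberg at q=0.05 (q=0.1 exposed) in a single family
pooled over all defined vertices of both hemispheres — the conservative
single-family reading.

Because the PLS reduction is supervised, fitting it and testing group
differences on the same subjects would inflate the vertex statistics
(under a global null the projected group difference behaves like a
max-covariance statistic over 9 directions, not a t-statistic).  The
group-statistics study therefore fits the reduction on the training split
and contrasts held-out subjects only, for the multiscale *and* the
thickness map so both use identical group sizes.  The 200-cohort
global-null calibration confirms the realised false-discovery fraction
stays at the nominal level under this design.

**Extra regions.** Per patient, y = mean multiscale value over vertices
significant for the multiscale map but not for thickness; x_all / x_sig =
mean thickness over the whole cortex / over thickness-significant
vertices.  Pearson and Spearman correlations of y with a cognitive score
are reported raw and partialled on x_all or x_sig; partialling is by
residualising both variables on the control (for one control variable
this equals the standard recursive partial-correlation formula —
cross-checked against `pingouin`), with rank transformation first for the
Spearman variant.  An empty extra region returns an explicit empty
result, never NaN.

## Classification

Splits are stratified by label, assigned by ranking a stable per-subject
hash of (seed, subject_id): the top ⌊f_test·n⌋ of each stratum are test,
the next ⌈f_val·n⌉ validation, the rest training.  Ranks never depend on
who else is enrolled, so when stratum sizes are multiples of the split
denominator, removing a test subject leaves every other assignment
unchanged (exact fractions and universal removal-invariance are jointly
impossible for arbitrary n).  The test split is fixed before any fitting
and never touches the normalisation, reduction, models or threshold.

Class weights are `w_c = n/(K·n_c)`.  Families whose scikit-learn
implementation accepts class weights use the native loss/criterion
reweighting (SVMs, logistic regression, random forest); the neural
network, k-NN and Gaussian process accept neither class nor sample
weights, so those families get deterministic minority-class replication
up to the majority count — equivalent to the weights up to integer
rounding.  SVM probabilities come from explicit Platt calibration on
internal stratified folds.  Hyperparameters are fixed small defaults
(16-unit single-hidden-layer network, 100-tree forest, k=5, default RBF
GP); the selection machinery treats each configured family as one
candidate.

Selection: each family is trained with 5 random initialisations × 4
stratified CV folds over train+validation, giving 20 held-out-fold AUROCs
whose mean ranks the family (deterministic learners vary across
initialisations only through the fold shuffling; ties break
alphabetically for determinism).  The top 3 are refitted on the training
split (train+validation behind a flag) and ensembled by arithmetic mean
of class-1 probabilities.  The decision threshold scans midpoints of
sorted unique validation scores, minimising FP+FN, ties resolving to the
lower threshold (favouring sensitivity).  AUROC is the trapezoidal ROC
area (= normalised Mann–Whitney U with half-credit ties); AUPRC is the
step-wise, non-interpolated PR area.  Transfer applies the fitted
normalisation, reduction, ensemble and threshold to a second cohort with
no refitting.  The same machinery runs on any scalar feature (e.g.
hippocampal volume normalised by intracranial volume) as a baseline.

The per-vertex reduced map is vectorised per subject as the classifier
input; at phantom scale all vertices are used (a top-k-by-effect-size cap
exists for larger meshes).

## The phantom

Geometry is a sphere-based ribbon: white surface an icosphere (default
subdivision 4 = 2562 vertices, radius 40 mm; experiments use desk-scale
162-vertex, 25 mm spheres), pial surface one local thickness outward
along the vertex normal.  Folded cortex is deliberately absent: no tested
property depends on folding, and the sphere admits exact analytic ground
truth.  Voxels (default 1×1×1.2 mm) are labelled by the innermost region
containing their centre (WM inside white, GM between the surfaces with
the local pial radius resolved via the nearest white vertex in direction,
CSF outside), assigned T1-like means (WM 110, GM 75, CSF 20), multiplied
by a smooth bias field and degraded with Gaussian noise (σ=4).

The bias field is the sum of 3 cosine modes with random directions and
phases, normalised to unit peak and scaled to ±10%, wavelength 150 mm —
the head-scale regime in which B0/B1 non-uniformity is smooth relative to
the ~3 mm GM-WM sampling separation, so ratio features should cancel it.
The pipeline the phantom emulates removes bias in preprocessing; the
phantom injects it instead, precisely to test that claim.

Healthy between-subject variation: a small global thickness offset
(σ=0.05 mm) plus independent per-vertex thickness variability (σ=0.2 mm)
— without the local term synthetic thickness maps would be perfectly
correlated across vertices within subject, making whole-map group
"significance" an all-or-nothing event — and a global GM-intensity offset
(σ=1).

Disease-like effects are confined to polar-cap "signature" masks:
thinning (delta subtracted from thickness) in a small cap, contrast loss
(GM intensity moved toward WM by a fraction of the gap) in a larger cap
containing it, each with per-subject Gaussian jitter (10% of the delta).
No quantitative effect sizes exist to copy for contrast change, so the
defaults are chosen for experimental power, not biological fidelity: the
strong "AD-like" cohort uses 0.8 mm thinning + 0.3 contrast loss (which
drives phantom classification close to ceiling), and the "MCI-like"
transfer cohort scales all deltas by 0.2 — early-stage pathology mild
enough that transfer performance is clearly degraded yet well above
chance, mirroring the qualitative diagnosis-vs-prognosis ordering.  A
synthetic impairment score (higher = worse) is generated per subject from
the realised deltas plus noise, giving the extra-region correlation a
known generating model.

**What the phantom does not model:** MR sequence physics, Rician noise,
partial-volume mixtures (voxels are hard-labelled), folded geometry,
lesions, cross-scanner effects.  Passing tests therefore demonstrate the
correctness and calibration of the *procedure* — recovery of constructed
ground truth, FDR control, leakage-free protocol, qualitative
orderings — not clinical performance on real MRI.

## Problem sizes

The multi-seed study uses 10 seeds × (40 affected + 40 control) subjects
on the 162-vertex phantom, with matched mild-effect and null cohorts; the
null-FDR calibration uses 200 cohorts of 10+10 subjects on a 42-vertex
phantom; ground-truth recovery uses a thick-ribbon (8 mm), fine-voxel
(0.5 mm) single subject so that every sampling point clears the
partial-volume shell.  These sizes were chosen so a full study runs in
CPU-minutes while every assertion remains comfortably inside its
statistical band.

## Known limitations

- The removal-invariance of split assignments is exact only when stratum
  sizes are multiples of the split denominator (see above).
- On very coarse meshes the 5 mm kernel reduces to a single fractional
  averaging pass; the FWHM calibration still holds but the kernel shape
  is triangular rather than Gaussian.
- The spherical phantom's direction-based voxel labelling blurs effects
  at signature-mask rims by about one inter-vertex spacing; tests
  therefore evaluate mask interiors or means.
- FreeSurfer binary surface support is read-only and assumes the dialect
  written by the classic reconstruction suite.
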