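# mssm — multiscale structural mapping of the cortex

`mssm` implements a surface-based morphometry pipeline that quantifies
cortical tissue integrity at two spatial scales from a single T1-weighted
volume: the macrostructural scale (cortical thickness) and the
microstructural scale (gray/white-matter intensity contrast sampled at
multiple cortical depths).  It is aimed at researchers studying
neurodegeneration — the motivating application is separating Alzheimer's
disease patients from controls and flagging mildly impaired individuals on
the disease path — and at method developers who need a fully synthetic,
analytically controlled test bed for vertex-wise statistics and
classification.

## The method

Given a white-surface mesh (gray/white interface) and a pial-surface mesh
(gray/CSF interface) with 1:1 vertex correspondence, plus the intensity
volume:

1. **Depth sampling.** Intermediate surfaces are built at 20/40/60/80% of
   the cortical thickness (linear interpolation along the white→pial
   segment), and two subjacent white-matter surfaces 0.5 and 1.0 mm below
   the gray/white border (inward along the vertex normal).  The volume is
   sampled trilinearly at every vertex of every surface.
2. **Contrast ratios.** Each GM depth over each WM offset gives
   4 × 2 = 8 ratios per vertex.  Because a smooth intensity bias multiplies
   numerator and denominator almost equally, the ratios are normalised for
   the local imaging environment.  Thickness `‖pial_i − white_i‖` joins as
   the 9th feature.
3. **Smoothing.** Each feature map is smoothed on the surface with an
   iterative neighbour-averaging kernel calibrated to a Gaussian FWHM of
   5 mm (σ = FWHM/2.3548, verified on the impulse response).
4. **Vertex-wise PLS.** At each vertex the 9 features (min-max normalised
   on training subjects) are reduced to one component by PLS1 against the
   binary diagnosis: `w = Xᶜᵀyᶜ / ‖Xᶜᵀyᶜ‖`, sign-fixed to increase with
   disease.
5. **Group statistics.** Vertex-wise pooled-variance t-tests with
   Benjamini–Hochberg FDR correction, Cohen's d effect-size maps, and the
   "extra region" analysis: correlation of the mean multiscale value over
   vertices significant for the multiscale map but *not* for thickness with
   a cognitive score, raw and partialled on mean thickness.
6. **Classification.** Stratified 60/20/20 split fixed before any fitting;
   nine model families (four SVM kernels, neural network, random forest,
   logistic regression, k-NN, Gaussian process), each with
   inverse-prevalence class weights, scored by 5 initialisations × 4-fold
   CV AUROC (20 values averaged); the top 3 ensembled by probability
   averaging; threshold chosen to minimise FP+FN; AUROC/AUPRC/accuracy/
   sensitivity/specificity reported.  A trained model transfers unchanged
   to a second cohort.

Because real cohort data cannot ship with the package, a first-class
synthetic phantom module generates spherical cortical ribbons with
piecewise T1-like intensities, a smooth multiplicative bias field, noise,
and disease-like effects (cortical thinning, contrast loss) confined to
signature vertex masks — all with analytic ground truth.

## A worked example

```
$ python examples/02_group_statistics.py
significant vertices (FDR q=0.05): multiscale 34.0% vs thickness 12.3%
|d_multiscale| > |d_thickness| in 100% of the contrast-only vertices
extra region: 36 vertices
score vs mean multiscale value: Pearson +0.36, Spearman +0.34
partialled on whole-cortex mean thickness: Pearson +0.41
```

The phantom cohort here has thinning confined to a small polar cap and
contrast loss over a larger cap: thickness alone finds ~12% of vertices,
the multiscale map ~34% — it recovers the contrast-affected territory
thickness cannot see — and the multiscale signal in those "extra" vertices
predicts the impairment score even after controlling for thickness.
`examples/01_phantom_and_features.py`, `03_classification.py` and
`04_transfer.py` walk the other capabilities (feature extraction,
ensemble classification, transfer to a milder cohort).

## Command-line pipeline

Each stage reads/writes a workspace directory and a provenance record:

```
mssm phantom  --config run.yaml --seed 1 --out run/ --n-affected 20 --n-control 20
mssm sample   --seed 1 --out run/
mssm smooth   --seed 1 --out run/
mssm pls      --seed 1 --out run/
mssm stats    --seed 1 --out run/
mssm train    --seed 1 --out run/
mssm evaluate --seed 1 --out run/
mssm transfer --seed 1 --out mci_run/ --train-dir run/
```

Surfaces are PLY/OFF (FreeSurfer binary surfaces read-only), volumes
NIfTI-1, cohort tables CSV, per-vertex maps CSV or `.npy` with a JSON
sidecar, evaluation reports JSON.

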