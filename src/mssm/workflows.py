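"""End-to-end phantom experiments composing the pipeline stages.

These are the study designs the package is exercised with: build a
two-group synthetic cohort, extract and smooth the multiscale feature
stacks, reduce them vertex-wise with PLS, and either (a) run the
vertex-wise group statistics comparing the multiscale map against
thickness alone, or (b) train and evaluate the ensemble classifier,
optionally transferring it unchanged to a second (milder) cohort.

Default experiment scale is deliberately desk-sized: a 162-vertex
icosphere of radius 25 mm and 40 subjects per group, which preserves
every property under study (the features, reduction, statistics and
classifiers are resolution-agnostic) while keeping a multi-seed study
in CPU minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classify
from .config import RunConfig
from .group_stats import StatMap, vertex_ttest
from .mesh import SurfaceMesh
from .phantom import (
    EffectSpec,
    PhantomConfig,
    SyntheticCohort,
    cap_mask,
    make_cohort,
    white_icosphere,
)
from .sampling import contrast_features
from .smoothing import smooth_stack
from .vertex_pls import PLSModel, fit_vertex_pls, transform


def demo_phantom_config(subdivisions: int = 2, base_radius_mm: float = 25.0,
                        **kwargs) -> PhantomConfig:
    """Desk-scale phantom: 162-vertex cortex, 25 mm radius, default tissue model."""
    return PhantomConfig(subdivisions=subdivisions, base_radius_mm=base_radius_mm,
                         **kwargs)


def demo_effect(mesh: SurfaceMesh,
                thickness_delta_mm: float = 0.8,
                contrast_delta: float = 0.3,
                thickness_frac: float = 0.12,
                contrast_frac: float = 0.33) -> EffectSpec:
    """Signature-region effect: thinning in a polar cap, contrast loss in a
    larger cap containing it (the contrast effect extends beyond the
    thickness effect, the configuration in which the multiscale map adds
    sensitivity over thickness alone)."""
    n = mesh.n_vertices
    z = np.array([0.0, 0.0, 1.0])
    return EffectSpec(
        thickness_mask=cap_mask(mesh, z, max(4, int(round(thickness_frac * n)))),
        thickness_delta_mm=thickness_delta_mm,
        contrast_mask=cap_mask(mesh, z, max(8, int(round(contrast_frac * n)))),
        contrast_delta=contrast_delta,
        thickness_subject_sd=0.1 * thickness_delta_mm,
        contrast_subject_sd=0.1 * contrast_delta,
    )


@dataclass
class CohortFeatures:
    """Smoothed feature stacks for a whole cohort on a shared mesh."""

    features: np.ndarray          # (n_subjects, n_vertices, 9)
    feature_names: list[str]
    labels: np.ndarray            # 0 = control, 1 = affected
    table: pd.DataFrame
    mesh: SurfaceMesh             # shared white-surface topology
    cohort: SyntheticCohort | None = None

    @property
    def thickness(self) -> np.ndarray:
        j = self.feature_names.index("thickness")
        return self.features[:, :, j]


def extract_cohort_features(cohort: SyntheticCohort,
                            run: RunConfig | None = None) -> CohortFeatures:
    """Sample, form ratios, and smooth the feature stack for every subject."""
    run = run or RunConfig()
    stacks = []
    for subj in cohort.subjects:
        stack = contrast_features(
            subj.white, subj.pial, subj.volume,
            depth_fractions=run.depth_fractions,
            wm_offsets=run.wm_offsets_mm,
            interpolation=run.interpolation,
            ratio_direction=run.ratio_direction,
        )
        stack = smooth_stack(stack, subj.white, run.smoothing_fwhm_mm,
                             smooth_thickness=run.smooth_thickness)
        stacks.append(stack.data)
    # binary encoding: the affected group (AD, MCI-C) is the positive class
    labels = cohort.table["label"].isin(["AD", "MCI-C"]).to_numpy().astype(int)
    return CohortFeatures(
        features=np.stack(stacks),
        feature_names=feature_names_from(run),
        labels=labels,
        table=cohort.table,
        mesh=cohort.subjects[0].white,
        cohort=cohort,
    )


def feature_names_from(run: RunConfig) -> list[str]:
    from .sampling import feature_names

    return feature_names(run.depth_fractions, run.wm_offsets_mm)


def build_feature_cohort(
    seed: int,
    n_affected: int = 40,
    n_control: int = 40,
    effect_scale: float = 1.0,
    phantom_config: PhantomConfig | None = None,
    run: RunConfig | None = None,
    affected_label: str = "AD",
    control_label: str = "CN",
) -> CohortFeatures:
    """Generate a phantom cohort and extract its smoothed features.

    ``effect_scale`` scales the signature-region deltas: 1 is the
    "AD-like" large effect, 0.5 an intermediate "MCI-like" effect, 0 a
    global-null cohort.
    """
    config = phantom_config or demo_phantom_config()
    run = run or RunConfig()
    mesh = white_icosphere(config)
    effect = demo_effect(mesh).scaled(effect_scale) if effect_scale > 0 else None
    cohort = make_cohort(config, effect, n_affected, n_control, seed,
                         affected_label=affected_label,
                         control_label=control_label)
    return extract_cohort_features(cohort, run)


# ---------------------------------------------------------------------------
# group statistics experiment
# ---------------------------------------------------------------------------

@dataclass
class StatsStudy:
    mssm_stat: StatMap
    thickness_stat: StatMap
    reduced: np.ndarray           # (n_subjects, n_vertices) multiscale maps
    pls_model: PLSModel
    test_rows: np.ndarray         # bool: subjects entering the group contrast


def stats_study(cf: CohortFeatures, q: float = 0.05, seed: int = 0) -> StatsStudy:
    """Vertex-wise group contrast of the reduced multiscale map and of
    thickness alone.

    The PLS reduction is supervised, so fitting it and testing group
    differences on the same subjects would bias the vertex statistics
    (and break FDR control under the null).  The reduction is therefore
    fitted on the training split and the contrast is run on the held-out
    subjects only — for both maps, so the comparison against thickness
    uses identical group sizes.
    """
    split = classify.make_splits(cf.table, seed=seed).to_numpy()
    fit_rows = split == "train"
    test_rows = ~fit_rows
    pls = fit_vertex_pls(cf.features[fit_rows], cf.labels[fit_rows],
                         cf.feature_names)
    reduced = transform(pls, cf.features)
    a = test_rows & (cf.labels == 1)
    b = test_rows & (cf.labels == 0)
    mssm_stat = vertex_ttest(reduced[a], reduced[b], q=q)
    ct_stat = vertex_ttest(cf.thickness[a], cf.thickness[b], q=q)
    return StatsStudy(mssm_stat, ct_stat, reduced, pls, test_rows)


def null_phantom_config() -> PhantomConfig:
    """Tiny phantom (42-vertex cortex, 12 mm radius) for Monte-Carlo null
    studies where hundreds of cohorts are simulated."""
    return PhantomConfig(subdivisions=1, base_radius_mm=12.0, margin_mm=3.0)


def null_fdr_fraction(seed: int, n_per_group: int = 10, q: float = 0.05) -> float:
    """Fraction of vertices declared significant in one global-null cohort.

    Builds an effect-free cohort, runs the full feature -> reduction ->
    group-contrast -> BH pipeline, and returns the significant fraction;
    averaging over many seeds estimates the realised false discovery
    fraction of the vertex statistics.
    """
    cf = build_feature_cohort(
        seed=seed, n_affected=n_per_group, n_control=n_per_group,
        effect_scale=0.0, phantom_config=null_phantom_config(),
    )
    st = stats_study(cf, q=q, seed=seed)
    n_def = int(st.mssm_stat.defined.sum())
    if n_def == 0:
        return 0.0
    return float(st.mssm_stat.significant.sum()) / n_def


# ---------------------------------------------------------------------------
# classification experiment
# ---------------------------------------------------------------------------

@dataclass
class ClassificationStudy:
    split: pd.Series
    pls_model: PLSModel | None
    model: classify.EnsembleModel
    report: classify.EvalReport
    X: np.ndarray                 # subject-by-feature matrix fed to the models
    columns: np.ndarray           # vertex indices retained as feature columns


def _finite_columns(X: np.ndarray) -> np.ndarray:
    return np.flatnonzero(np.all(np.isfinite(X), axis=0))


def classification_study(
    cf: CohortFeatures,
    seed: int,
    feature_mode: str = "mssm",
    run: RunConfig | None = None,
    split: pd.Series | None = None,
) -> ClassificationStudy:
    """Split, reduce, train the class-weighted ensemble, evaluate on test.

    feature_mode 'mssm' feeds the vertex-wise PLS-reduced map (fitted on
    training subjects only); 'thickness' feeds the smoothed thickness
    map directly (no reduction needed for a single feature per vertex).
    The test split is fixed before any fitting and never touches the
    normalisation, the reduction, or the models.
    """
    run = run or RunConfig()
    if split is None:
        split = classify.make_splits(cf.table, tuple(run.split_fractions), seed)
    split_arr = split.to_numpy()
    train_rows = split_arr == "train"

    pls_model = None
    if feature_mode == "mssm":
        pls_model = fit_vertex_pls(cf.features[train_rows], cf.labels[train_rows],
                                   cf.feature_names)
        maps = transform(pls_model, cf.features)
    elif feature_mode == "thickness":
        maps = cf.thickness
    else:
        raise ValueError(f"unknown feature_mode {feature_mode!r}")

    # vertex columns kept: defined for every non-test subject; test rows
    # with stray undefined values are zero-filled rather than inspected
    cols = _finite_columns(maps[split_arr != "test"])
    X = maps[:, cols]
    X = np.where(np.isfinite(X), X, 0.0)
    model = classify.train_ensemble(
        X, cf.labels, split_arr, seed=seed, families=run.models,
        n_initializations=run.n_initializations, n_folds=run.n_cv_folds,
        ensemble_size=run.ensemble_size, final_refit_on=run.final_refit_on,
    )
    report = classify.evaluate(model, X[split_arr == "test"],
                               cf.labels[split_arr == "test"])
    return ClassificationStudy(split, pls_model, model, report, X, cols)


def transfer_study(study: ClassificationStudy, cf2: CohortFeatures) -> classify.EvalReport:
    """Apply a trained study to a second cohort with no refitting.

    The second cohort's features pass through the SAME fitted PLS model
    (training-cohort normalisation bounds) and the same ensemble and
    threshold.
    """
    if study.pls_model is not None:
        maps2 = transform(study.pls_model, cf2.features)
    else:
        maps2 = cf2.thickness
    X2 = maps2[:, study.columns]
    X2 = np.where(np.isfinite(X2), X2, 0.0)
    return classify.transfer_predict(study.model, X2, cf2.labels)
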