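"""Stage-wise pipeline over an on-disk workspace, with provenance.

Each stage reads the previous stage's artifacts from the workspace
directory, writes its own, and records a JSON provenance file (stage,
seed, config hash, package versions, inputs) sufficient to reproduce
the stage bit-for-bit given the same seed.  Missing prerequisites raise
:class:`PipelineError` naming the absent artifact.

Stages: phantom -> sample -> smooth -> pls -> (stats | train -> evaluate);
``transfer`` applies a previously trained workspace to this one's cohort.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import __version__, classify
from .config import RunConfig, save_config
from .group_stats import effect_size_comparison, percent_significant, vertex_ttest
from .io_formats import (
    read_cohort,
    read_surface,
    read_volume,
    write_cohort,
    write_matrix,
    write_surface,
    write_volume,
)
from .phantom import PhantomConfig, make_cohort, white_icosphere
from .sampling import FeatureStack, contrast_features
from .smoothing import calibrate_kernel, smooth_stack
from .vertex_pls import fit_vertex_pls, transform
from .workflows import demo_effect


class PipelineError(RuntimeError):
    pass


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing prerequisite artifact {path} (run the '{produced_by}' stage first)"
        )
    return path


def _write_provenance(ws: Path, stage: str, config: RunConfig, seed: int,
                      inputs: list[str], extra: dict | None = None) -> None:
    import sklearn

    record = {
        "stage": stage,
        "seed": seed,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "versions": {
            "mssm": __version__,
            "numpy": np.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "inputs": inputs,
        **(extra or {}),
    }
    (ws / f"{stage}.provenance.json").write_text(
        json.dumps(record, indent=2, sort_keys=True) + "\n"
    )


def stage_phantom(
    ws: str | Path,
    config: RunConfig,
    seed: int,
    n_affected: int = 12,
    n_control: int = 12,
    effect_scale: float = 1.0,
    phantom: PhantomConfig | None = None,
    affected_label: str = "AD",
    control_label: str = "CN",
) -> Path:
    """Write per-subject surfaces (PLY) and volumes (NIfTI), cohort.csv, truth.json."""
    ws = Path(ws)
    ws.mkdir(parents=True, exist_ok=True)
    phantom = phantom or PhantomConfig(subdivisions=2, base_radius_mm=25.0)
    mesh = white_icosphere(phantom)
    effect = demo_effect(mesh).scaled(effect_scale) if effect_scale > 0 else None
    cohort = make_cohort(phantom, effect, n_affected, n_control, seed,
                         affected_label=affected_label, control_label=control_label)
    subj_dir = ws / "subjects"
    for subj, sid in zip(cohort.subjects, cohort.table["subject_id"]):
        write_surface(subj.white, subj_dir / f"{sid}_white.ply")
        write_surface(subj.pial, subj_dir / f"{sid}_pial.ply")
        write_volume(subj.volume, subj_dir / f"{sid}.nii")
    write_cohort(cohort.table[["subject_id", "label"]], ws / "cohort.csv")
    cohort.table.to_csv(ws / "cohort_full.csv", index=False)
    truth = {
        "effect_scale": effect_scale,
        "thickness_mask": (effect.thickness_mask.tolist() if effect else []),
        "contrast_mask": (effect.contrast_mask.tolist() if effect else []),
        "thickness_delta_mm": (effect.thickness_delta_mm if effect else 0.0),
        "contrast_delta": (effect.contrast_delta if effect else 0.0),
    }
    (ws / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    save_config(config, ws / "config.yaml")
    _write_provenance(ws, "phantom", config, seed, [],
                      {"n_affected": n_affected, "n_control": n_control})
    return ws


def stage_sample(ws: str | Path, config: RunConfig, seed: int) -> Path:
    """Raw (unsmoothed) 9-feature stacks for every subject -> features.npy."""
    ws = Path(ws)
    table = read_cohort(_require(ws / "cohort.csv", "phantom"))
    stacks = []
    names = None
    for sid in table["subject_id"]:
        white = read_surface(_require(ws / "subjects" / f"{sid}_white.ply", "phantom"))
        pial = read_surface(_require(ws / "subjects" / f"{sid}_pial.ply", "phantom"))
        vol = read_volume(_require(ws / "subjects" / f"{sid}.nii", "phantom"))
        stack = contrast_features(
            white, pial, vol,
            depth_fractions=config.depth_fractions,
            wm_offsets=config.wm_offsets_mm,
            interpolation=config.interpolation,
            ratio_direction=config.ratio_direction,
        )
        names = stack.names
        stacks.append(stack.data)
    write_matrix(np.stack(stacks), ws / "features.npy",
                 {"feature_names": names, "subjects": table["subject_id"].tolist()})
    _write_provenance(ws, "sample", config, seed, ["cohort.csv", "subjects/"])
    return ws


def stage_smooth(ws: str | Path, config: RunConfig, seed: int) -> Path:
    ws = Path(ws)
    features = np.load(_require(ws / "features.npy", "sample"))
    meta = json.loads((ws / "features.npy.json").read_text())
    table = read_cohort(ws / "cohort.csv")
    sid0 = table["subject_id"].iloc[0]
    smoothed = []
    for i, sid in enumerate(table["subject_id"]):
        white = read_surface(ws / "subjects" / f"{sid}_white.ply")
        stack = FeatureStack(features[i], meta["feature_names"])
        smoothed.append(
            smooth_stack(stack, white, config.smoothing_fwhm_mm,
                         smooth_thickness=config.smooth_thickness).data
        )
    spec = calibrate_kernel(read_surface(ws / "subjects" / f"{sid0}_white.ply"),
                            config.smoothing_fwhm_mm)
    write_matrix(np.stack(smoothed), ws / "smoothed.npy",
                 {"feature_names": meta["feature_names"],
                  "kernel": {"fwhm_mm": spec.fwhm_mm,
                             "n_iterations": spec.n_iterations,
                             "final_weight": spec.final_weight}})
    _write_provenance(ws, "smooth", config, seed, ["features.npy"])
    return ws


def _load_labels_split(ws: Path, config: RunConfig, seed: int) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    table = read_cohort(ws / "cohort.csv")
    labels = table["label"].isin(["AD", "MCI-C"]).to_numpy().astype(int)
    split_path = ws / "splits.csv"
    if not split_path.exists():
        split = classify.make_splits(table, tuple(config.split_fractions), seed)
        pd.DataFrame({"subject_id": table["subject_id"], "split": split}).to_csv(
            split_path, index=False
        )
    split = pd.read_csv(split_path)["split"].to_numpy()
    return table, labels, split


def stage_pls(ws: str | Path, config: RunConfig, seed: int) -> Path:
    """Fit the vertex-wise reduction on training subjects; reduce everyone."""
    ws = Path(ws)
    smoothed = np.load(_require(ws / "smoothed.npy", "smooth"))
    meta = json.loads((ws / "smoothed.npy.json").read_text())
    table, labels, split = _load_labels_split(ws, config, seed)
    train = split == "train"
    model = fit_vertex_pls(smoothed[train], labels[train], meta["feature_names"])
    reduced = transform(model, smoothed)
    np.savez(ws / "pls_model.npz",
             feature_min=model.feature_min, feature_max=model.feature_max,
             weights=model.weights, x_mean=model.x_mean, defined=model.defined)
    (ws / "pls_model.json").write_text(json.dumps(
        {"feature_names": model.feature_names, "fitted_on": model.fitted_on,
         "model_hash": model.content_hash()}, indent=2, sort_keys=True) + "\n")
    write_matrix(reduced, ws / "reduced.npy",
                 {"subjects": table["subject_id"].tolist()})
    _write_provenance(ws, "pls", config, seed, ["smoothed.npy", "splits.csv"])
    return ws


def stage_stats(ws: str | Path, config: RunConfig, seed: int) -> Path:
    """Vertex-wise group contrast of the reduced map and of thickness alone."""
    ws = Path(ws)
    reduced = np.load(_require(ws / "reduced.npy", "pls"))
    smoothed = np.load(_require(ws / "smoothed.npy", "smooth"))
    meta = json.loads((ws / "smoothed.npy.json").read_text())
    table, labels, split = _load_labels_split(ws, config, seed)
    thickness = smoothed[:, :, meta["feature_names"].index("thickness")]
    # the reduction was fitted on the training split; contrast held-out rows
    held = split != "train"
    a, b = held & (labels == 1), held & (labels == 0)
    mssm_stat = vertex_ttest(reduced[a], reduced[b], q=config.fdr_q)
    ct_stat = vertex_ttest(thickness[a], thickness[b], q=config.fdr_q)
    cmp_ = effect_size_comparison(mssm_stat, ct_stat)
    df = pd.DataFrame({
        "vertex_index": np.arange(mssm_stat.n_vertices),
        "t_mssm": mssm_stat.t, "p_mssm": mssm_stat.p, "d_mssm": mssm_stat.d,
        "sig_mssm": mssm_stat.significant.astype(int),
        "t_thickness": ct_stat.t, "p_thickness": ct_stat.p, "d_thickness": ct_stat.d,
        "sig_thickness": ct_stat.significant.astype(int),
        "d_difference": cmp_.d_difference,
    })
    df.to_csv(ws / "stats.csv", index=False)
    summary = {
        "percent_significant_mssm": percent_significant(mssm_stat),
        "percent_significant_thickness": percent_significant(ct_stat),
        "q": config.fdr_q,
        "n_extra_vertices": int((mssm_stat.significant & ~ct_stat.significant).sum()),
    }
    (ws / "stats_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    _write_provenance(ws, "stats", config, seed, ["reduced.npy", "smoothed.npy"])
    return ws


def stage_train(ws: str | Path, config: RunConfig, seed: int) -> Path:
    ws = Path(ws)
    reduced = np.load(_require(ws / "reduced.npy", "pls"))
    _, labels, split = _load_labels_split(ws, config, seed)
    cols = np.flatnonzero(np.all(np.isfinite(reduced[split != "test"]), axis=0))
    X = np.where(np.isfinite(reduced[:, cols]), reduced[:, cols], 0.0)
    model = classify.train_ensemble(
        X, labels, split, seed=seed, families=config.models,
        n_initializations=config.n_initializations, n_folds=config.n_cv_folds,
        ensemble_size=config.ensemble_size, final_refit_on=config.final_refit_on,
    )
    joblib.dump({"model": model, "columns": cols}, ws / "model.joblib")
    (ws / "selection.json").write_text(json.dumps(
        {"selection_scores": model.selection_scores,
         "members": [m.family for m in model.members],
         "threshold": model.threshold,
         "excluded": model.excluded,
         "model_hash": model.content_hash()}, indent=2, sort_keys=True) + "\n")
    _write_provenance(ws, "train", config, seed, ["reduced.npy", "splits.csv"])
    return ws


def _write_report(report: classify.EvalReport, ws: Path, prefix: str) -> None:
    (ws / f"{prefix}_report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    pd.DataFrame(report.roc_points).to_csv(ws / f"{prefix}_roc.csv", index=False)
    pd.DataFrame(report.pr_points).to_csv(ws / f"{prefix}_pr.csv", index=False)
    from .plots import save_roc_pr

    save_roc_pr(report, ws / f"{prefix}_curves.png")


def stage_evaluate(ws: str | Path, config: RunConfig, seed: int) -> Path:
    ws = Path(ws)
    bundle = joblib.load(_require(ws / "model.joblib", "train"))
    reduced = np.load(_require(ws / "reduced.npy", "pls"))
    _, labels, split = _load_labels_split(ws, config, seed)
    X = reduced[:, bundle["columns"]]
    test = split == "test"
    report = classify.evaluate(bundle["model"], X[test], labels[test])
    _write_report(report, ws, "eval")
    _write_provenance(ws, "evaluate", config, seed, ["model.joblib", "reduced.npy"])
    return ws


def stage_transfer(ws: str | Path, config: RunConfig, seed: int,
                   train_ws: str | Path) -> Path:
    """Apply the model (and PLS bounds) trained in ``train_ws`` to this cohort."""
    ws, train_ws = Path(ws), Path(train_ws)
    bundle = joblib.load(_require(train_ws / "model.joblib", "train"))
    pls_npz = np.load(_require(train_ws / "pls_model.npz", "pls"))
    pls_meta = json.loads((train_ws / "pls_model.json").read_text())
    from .vertex_pls import PLSModel

    pls = PLSModel(
        feature_min=pls_npz["feature_min"], feature_max=pls_npz["feature_max"],
        weights=pls_npz["weights"], x_mean=pls_npz["x_mean"],
        defined=pls_npz["defined"], feature_names=pls_meta["feature_names"],
        fitted_on=pls_meta["fitted_on"],
    )
    smoothed = np.load(_require(ws / "smoothed.npy", "smooth"))
    table = read_cohort(ws / "cohort.csv")
    labels = table["label"].isin(["AD", "MCI-C"]).to_numpy().astype(int)
    reduced = transform(pls, smoothed)
    X2 = reduced[:, bundle["columns"]]
    X2 = np.where(np.isfinite(X2), X2, 0.0)
    report = classify.transfer_predict(bundle["model"], X2, labels)
    _write_report(report, ws, "transfer")
    _write_provenance(ws, "transfer", config, seed,
                      [str(train_ws / "model.joblib"), "smoothed.npy"])
    return ws


STAGES = {
    "phantom": stage_phantom,
    "sample": stage_sample,
    "smooth": stage_smooth,
    "pls": stage_pls,
    "stats": stage_stats,
    "train": stage_train,
    "evaluate": stage_evaluate,
    "transfer": stage_transfer,
}
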