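"""Splits, class-weighted model zoo, ensemble selection and evaluation.

The classification stage mirrors common practice for small clinical
cohorts: a stratified 60/20/20 train/validation/test split fixed before
any fitting; a zoo of standard learners (four SVM kernels, a small
neural network, random forest, logistic regression, k-nearest
neighbours, Gaussian process), each trained with class weights
inversely related to class prevalence; each family scored by 5 random
initialisations x 4-fold cross-validated AUROC (20 values averaged);
the top 3 families ensembled by averaging their class-1 probabilities;
and a decision threshold chosen to minimise false positives plus false
negatives.  Reported metrics: AUROC, AUPRC, accuracy, sensitivity,
specificity, plus ROC and PR curve points.

A trained ensemble can be applied unchanged to a second cohort
(transfer), and the identical machinery runs on any single scalar
column (e.g. normalised hippocampal volume) as a baseline.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .config import DEFAULT_MODELS


class ClassifyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def _subject_priority(seed: int, subject_id: str) -> float:
    """Stable per-subject uniform in [0, 1) from the seed and the ID."""
    digest = hashlib.blake2b(
        f"{seed}:{subject_id}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") / 2.0**64


def make_splits(
    cohort: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> pd.Series:
    """Assign train/val/test per subject, stratified by label.

    Assignment ranks subjects within each label stratum by a stable
    hash of (seed, subject_id): the top floor(f_test*n) become test, the
    next ceil(f_val*n) validation, the rest training.  Because the rank
    order never depends on who else is present, removing a test subject
    from a stratum whose size is a multiple of the split denominator
    leaves every other subject's assignment unchanged.
    """
    f_train, f_val, f_test = fractions
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ClassifyError("split fractions must sum to 1")
    out = pd.Series("train", index=cohort.index, name="split")
    for _, idx in cohort.groupby("label", sort=True).groups.items():
        sub = cohort.loc[idx]
        prio = sub["subject_id"].map(lambda s: _subject_priority(seed, s))
        order = sub.index[np.argsort(-prio.to_numpy(), kind="stable")]
        n = len(order)
        k_test = int(np.floor(f_test * n))
        k_val = int(np.ceil(f_val * n))
        out.loc[order[:k_test]] = "test"
        out.loc[order[k_test:k_test + k_val]] = "val"
    return out


def class_weights(labels: np.ndarray) -> dict:
    """w_c = n_total / (K * n_c): inverse-prevalence class weights."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ClassifyError("class weights need at least two classes")
    n, k = len(labels), len(classes)
    return {c: n / (k * cnt) for c, cnt in zip(classes.tolist(), counts.tolist())}


# ---------------------------------------------------------------------------
# model zoo
# ---------------------------------------------------------------------------

# how each family honours class weights: the loss/criterion reweighting
# sklearn exposes, or deterministic minority replication where it does not
_WEIGHT_STRATEGY = {
    "svm_linear": "class_weight",
    "svm_sigmoid": "class_weight",
    "svm_polynomial": "class_weight",
    "svm_rbf": "class_weight",
    "neural_network": "resample",
    "random_forest": "class_weight",
    "logistic_regression": "class_weight",
    "k_nearest_neighbors": "resample",
    "gaussian_process": "resample",
}


def _calibrated_svc(init_seed: int, cw_arg: dict | None, **svc_kwargs):
    # SVC margins -> class probabilities via Platt scaling on internal folds
    base = SVC(class_weight=cw_arg, random_state=init_seed, **svc_kwargs)
    return CalibratedClassifierCV(
        base, method="sigmoid",
        cv=StratifiedKFold(3, shuffle=True, random_state=init_seed),
    )


def _build_estimator(family: str, init_seed: int, cw: dict | None):
    cw_arg = cw if _WEIGHT_STRATEGY[family] == "class_weight" else None
    if family == "svm_linear":
        return _calibrated_svc(init_seed, cw_arg, kernel="linear")
    if family == "svm_sigmoid":
        return _calibrated_svc(init_seed, cw_arg, kernel="sigmoid")
    if family == "svm_polynomial":
        return _calibrated_svc(init_seed, cw_arg, kernel="poly", degree=3)
    if family == "svm_rbf":
        return _calibrated_svc(init_seed, cw_arg, kernel="rbf")
    if family == "neural_network":
        return MLPClassifier(hidden_layer_sizes=(16,), max_iter=500,
                             random_state=init_seed)
    if family == "random_forest":
        return RandomForestClassifier(n_estimators=100, class_weight=cw_arg,
                                      random_state=init_seed)
    if family == "logistic_regression":
        return LogisticRegression(max_iter=2000, class_weight=cw_arg,
                                  random_state=init_seed)
    if family == "k_nearest_neighbors":
        return KNeighborsClassifier(n_neighbors=5)
    if family == "gaussian_process":
        return GaussianProcessClassifier(random_state=init_seed)
    raise ClassifyError(f"unknown model family {family!r}")


def _balanced_replication(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministically replicate minority samples up to the majority count.

    Equivalent, up to integer rounding, to inverse-prevalence sample
    weighting for learners that accept neither class nor sample weights.
    """
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    keep = []
    for c, cnt in zip(classes, counts):
        idx = np.flatnonzero(y == c)
        reps = int(np.ceil(n_max / cnt))
        keep.append(np.tile(idx, reps)[:n_max])
    keep = np.sort(np.concatenate(keep), kind="stable")
    return X[keep], y[keep]


@dataclass
class FittedMember:
    family: str
    estimator: object

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(X)
        pos = list(self.estimator.classes_).index(1)
        return proba[:, pos]


def _fit_family(family: str, X: np.ndarray, y: np.ndarray, init_seed: int) -> FittedMember:
    cw = class_weights(y)
    est = _build_estimator(family, init_seed, cw)
    if _WEIGHT_STRATEGY[family] == "resample":
        X, y = _balanced_replication(X, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return FittedMember(family, est)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve: P(score_pos > score_neg) + 0.5 P(tie)."""
    return float(roc_auc_score(labels, scores))


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (step-wise, non-interpolated)."""
    return float(average_precision_score(labels, scores))


def choose_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exhaustive scan minimising false positives plus false negatives.

    Candidates are midpoints of consecutive sorted unique scores plus
    sentinels below/above all scores; prediction is positive when
    score >= threshold; ties in error count resolve to the lowest
    threshold (favouring sensitivity).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    uniq = np.unique(scores)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best_t, best_err = None, None
    for t in candidates:  # ascending, so the first minimum is the lowest t
        pred = scores >= t
        err = int(np.sum(pred & (labels == 0)) + np.sum(~pred & (labels == 1)))
        if best_err is None or err < best_err:
            best_t, best_err = float(t), err
    return best_t


@dataclass
class EvalReport:
    auroc: float
    auprc: float
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float
    roc_points: dict = field(default_factory=dict)   # {"fpr": [...], "tpr": [...]}
    pr_points: dict = field(default_factory=dict)    # {"recall": [...], "precision": [...]}

    def to_dict(self) -> dict:
        return {
            "AUROC": self.auroc,
            "AUPRC": self.auprc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "threshold": self.threshold,
            "roc_points": self.roc_points,
            "pr_points": self.pr_points,
        }


def evaluate_scores(scores: np.ndarray, labels: np.ndarray, threshold: float) -> EvalReport:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    fpr, tpr, _ = roc_curve(labels, scores)
    precision, recall, _ = precision_recall_curve(labels, scores)
    return EvalReport(
        auroc=auroc(scores, labels),
        auprc=auprc(scores, labels),
        accuracy=(tp + tn) / len(labels),
        sensitivity=tp / (tp + fn) if (tp + fn) else float("nan"),
        specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
        threshold=float(threshold),
        roc_points={"fpr": fpr.tolist(), "tpr": tpr.tolist()},
        pr_points={"recall": recall.tolist(), "precision": precision.tolist()},
    )


# ---------------------------------------------------------------------------
# ensemble selection
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    members: list[FittedMember]          # exactly top-k fitted models
    selection_scores: dict               # family -> mean of 20 CV AUROCs
    threshold: float
    excluded: dict = field(default_factory=dict)  # family -> reason

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Ensemble probability: arithmetic mean of member probabilities."""
        return np.mean([m.predict_proba1(X) for m in self.members], axis=0)

    def content_hash(self) -> str:
        """Hash of the fitted state via deterministic probe predictions."""
        h = hashlib.sha256()
        rng = np.random.default_rng(0)
        n_features = _estimator_n_features(self.members[0].estimator)
        probe = rng.standard_normal((16, n_features))
        for m in self.members:
            h.update(m.family.encode())
            h.update(np.round(m.predict_proba1(probe), 12).tobytes())
        h.update(np.float64(self.threshold).tobytes())
        return h.hexdigest()


def _estimator_n_features(est) -> int:
    return int(est.n_features_in_)


def select_ensemble(
    X_select: np.ndarray,
    y_select: np.ndarray,
    seed: int,
    families: list[str] | None = None,
    n_initializations: int = 5,
    n_folds: int = 4,
    ensemble_size: int = 3,
    X_refit: np.ndarray | None = None,
    y_refit: np.ndarray | None = None,
) -> EnsembleModel:
    """Rank families by 5-init x 4-fold CV AUROC; ensemble the top 3.

    For each family and each of ``n_initializations`` seeds, a stratified
    ``n_folds``-fold CV over the selection data yields one AUROC per fold
    (20 values with the defaults); families are ranked by the mean.  For
    deterministic learners the initialisations differ only through the
    fold shuffling.  The top families are refitted on ``X_refit``
    (default: the selection data) and averaged.  The decision threshold
    is set afterwards by :func:`finalize_threshold`.
    """
    families = list(families or DEFAULT_MODELS)
    if len(families) < ensemble_size:
        raise ClassifyError(f"need at least {ensemble_size} model families")
    X_select = np.asarray(X_select, dtype=np.float64)
    y_select = np.asarray(y_select)
    if X_refit is None:
        X_refit, y_refit = X_select, y_select

    base = np.random.SeedSequence([seed, 0xC1A55])
    # candidate labels stay unique even if a family is listed twice
    seen: dict[str, int] = {}
    labels_ = []
    for family in families:
        seen[family] = seen.get(family, 0)
        labels_.append(family if seen[family] == 0 else f"{family}#{seen[family]}")
        seen[family] += 1
    scores: dict[str, float] = {}
    excluded: dict[str, str] = {}
    label_to_family = dict(zip(labels_, families))
    for fam_i, (label, family) in enumerate(zip(labels_, families)):
        aurocs = []
        try:
            for init in range(n_initializations):
                init_seed = int(
                    np.random.SeedSequence([seed, fam_i, init]).generate_state(1)[0]
                    % (2**31)
                )
                skf = StratifiedKFold(
                    n_splits=n_folds, shuffle=True, random_state=init_seed % (2**31)
                )
                for tr, te in skf.split(X_select, y_select):
                    member = _fit_family(family, X_select[tr], y_select[tr], init_seed)
                    aurocs.append(auroc(member.predict_proba1(X_select[te]), y_select[te]))
            scores[label] = float(np.mean(aurocs))
        except Exception as exc:  # family cannot produce probabilities etc.
            excluded[label] = f"{type(exc).__name__}: {exc}"
    if len(scores) < ensemble_size:
        raise ClassifyError(
            f"fewer than {ensemble_size} families produced valid CV scores; "
            f"exclusions: {excluded}"
        )
    ranked = sorted(scores, key=lambda f: (-scores[f], f))
    top = ranked[:ensemble_size]
    refit_seed = int(base.generate_state(1)[0] % (2**31))
    members = [_fit_family(label_to_family[f], np.asarray(X_refit),
                           np.asarray(y_refit), refit_seed)
               for f in top]
    return EnsembleModel(members=members, selection_scores=scores,
                         threshold=0.5, excluded=excluded)


def finalize_threshold(model: EnsembleModel, X_val: np.ndarray, y_val: np.ndarray) -> None:
    """Set the decision threshold minimising FP+FN on held-out validation data."""
    model.threshold = choose_threshold(model.predict_proba(X_val), y_val)


def evaluate(model: EnsembleModel, X: np.ndarray, y: np.ndarray) -> EvalReport:
    """Five metrics plus ROC/PR curves at the model's decision threshold."""
    return evaluate_scores(model.predict_proba(np.asarray(X, dtype=np.float64)),
                           y, model.threshold)


def transfer_predict(model: EnsembleModel, X2: np.ndarray, y2: np.ndarray) -> EvalReport:
    """Apply a trained ensemble to a second cohort without refitting anything.

    The second cohort's features must come from the SAME fitted
    normalisation and reduction; the threshold is the one chosen on the
    training cohort.
    """
    return evaluate(model, X2, y2)


def train_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    split: np.ndarray,
    seed: int,
    families: list[str] | None = None,
    n_initializations: int = 5,
    n_folds: int = 4,
    ensemble_size: int = 3,
    final_refit_on: str = "train",
) -> EnsembleModel:
    """Full training protocol on pre-split subject features.

    Selection runs by CV over train+validation; the chosen families are
    refitted on the training split (or train+val behind the flag); the
    threshold is chosen on the validation split.  Test rows are never
    touched.
    """
    split = np.asarray(split)
    tv = (split == "train") | (split == "val")
    tr = split == "train" if final_refit_on == "train" else tv
    model = select_ensemble(
        X[tv], y[tv], seed=seed, families=families,
        n_initializations=n_initializations, n_folds=n_folds,
        ensemble_size=ensemble_size, X_refit=X[tr], y_refit=y[tr],
    )
    finalize_threshold(model, X[split == "val"], y[split == "val"])
    return model


def scalar_baseline(
    values: np.ndarray,
    y: np.ndarray,
    split: np.ndarray,
    seed: int,
    families: list[str] | None = None,
    **kwargs,
) -> tuple[EnsembleModel, EvalReport]:
    """Run the identical ensemble machinery on a single scalar feature."""
    X = np.asarray(values, dtype=np.float64).reshape(-1, 1)
    model = train_ensemble(X, y, split, seed, families=families, **kwargs)
    split = np.asarray(split)
    report = evaluate(model, X[split == "test"], np.asarray(y)[split == "test"])
    return model, report
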