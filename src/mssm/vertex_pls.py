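"""Vertex-wise PLS1 reduction of the 9 features to one component.

At each vertex the features (thickness + 8 contrast ratios) of the
training subjects are min-max normalised to [0, 1], centred together
with the binary diagnosis label, and reduced along the first partial
least squares component — the direction in feature space with maximal
covariance with the label.  For a single response and one component the
weight vector has the closed form

    w = Xc' yc / ||Xc' yc||

(the normalised feature-label cross-covariance), which equals the first
NIPALS PLS1 weight.  The sign is fixed so the component increases with
the diagnosis label; PLS weights are otherwise sign-ambiguous and the
vertex maps would be incomparable across vertices.

Normalisation bounds and weights come from TRAINING subjects only and
are reused verbatim for validation, test, and transfer cohorts (values
for new subjects may fall outside [0, 1]; they are not clipped).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

N_FEATURES = 9


class PLSError(ValueError):
    pass


@dataclass
class PLSModel:
    """Per-vertex normalisation bounds and first-component weights."""

    feature_min: np.ndarray   # (n_vertices, n_features)
    feature_max: np.ndarray
    weights: np.ndarray       # (n_vertices, n_features), unit rows where defined
    x_mean: np.ndarray        # per-vertex mean of normalised training features
    defined: np.ndarray       # (n_vertices,) bool
    feature_names: list[str]
    fitted_on: str            # hash of the training subject set

    @property
    def n_vertices(self) -> int:
        return self.weights.shape[0]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for a in (self.feature_min, self.feature_max, self.weights,
                  self.x_mean, self.defined):
            h.update(np.ascontiguousarray(a).tobytes())
        h.update(",".join(self.feature_names).encode())
        return h.hexdigest()


def _check_features(features: np.ndarray, n_features: int = N_FEATURES) -> np.ndarray:
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 3:
        raise PLSError("features must be (n_subjects, n_vertices, n_features)")
    if features.shape[2] != n_features:
        raise PLSError(
            f"expected {n_features} features per vertex, got {features.shape[2]}"
        )
    return features


def fit_vertex_pls(
    features: np.ndarray,
    labels: np.ndarray,
    feature_names: list[str] | None = None,
) -> PLSModel:
    """Fit the per-vertex PLS1 reduction on training subjects only.

    features : (n_subjects, n_vertices, 9) smoothed feature stacks
    labels   : (n_subjects,) binary 0/1 diagnosis
    """
    X = _check_features(features)
    y = np.asarray(labels, dtype=np.float64)
    if y.ndim != 1 or len(y) != X.shape[0]:
        raise PLSError("labels must be one binary value per subject")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise PLSError("labels must be encoded {0, 1}")
    if (y == 0).sum() < 2 or (y == 1).sum() < 2:
        raise PLSError("need at least 2 training subjects per class")

    names = feature_names or [f"f{j}" for j in range(X.shape[2])]

    # subject-vertex cells with any undefined feature are excluded per vertex
    finite = np.all(np.isfinite(X), axis=2)          # (n_subj, n_vert)
    Xw = np.where(finite[:, :, None], X, np.nan)

    fmin = np.nanmin(Xw, axis=0)                     # (n_vert, n_feat)
    fmax = np.nanmax(Xw, axis=0)
    frange = fmax - fmin
    zero_var = frange <= 0
    safe_range = np.where(zero_var, 1.0, frange)
    Xn = (Xw - fmin) / safe_range
    Xn = np.where(zero_var[None, :, :], 0.0, Xn)     # zero-variance -> constant 0

    x_mean = np.nanmean(Xn, axis=0)
    yc = y - y.mean()
    Xc = Xn - x_mean
    Xc = np.where(np.isfinite(Xc), Xc, 0.0)          # undefined cells drop out

    w_raw = np.einsum("svf,s->vf", Xc, yc)
    w_raw[zero_var] = 0.0
    norms = np.linalg.norm(w_raw, axis=1)
    defined = norms > 1e-12
    weights = np.zeros_like(w_raw)
    weights[defined] = w_raw[defined] / norms[defined, None]

    # sign convention: component correlates non-negatively with the label.
    # With w ∝ Xc'yc the training covariance w'Xc'yc = ||Xc'yc|| >= 0 already;
    # the explicit flip keeps the convention robust to any future weight rule.
    cov = np.einsum("vf,vf->v", weights, w_raw)
    flip = cov < 0
    weights[flip] *= -1.0

    fitted_on = hashlib.sha256(
        np.ascontiguousarray(X).tobytes() + y.tobytes()
    ).hexdigest()[:16]

    return PLSModel(
        feature_min=fmin,
        feature_max=fmax,
        weights=weights,
        x_mean=np.where(np.isfinite(x_mean), x_mean, 0.0),
        defined=defined,
        feature_names=list(names),
        fitted_on=fitted_on,
    )


def transform(model: PLSModel, features: np.ndarray,
              feature_names: list[str] | None = None) -> np.ndarray:
    """Apply a fitted reduction: (n_subjects, n_vertices, 9) -> (n_subjects, n_vertices).

    Uses the TRAINING min/max and centring constants; never refits.
    Vertices undefined in the model, or with undefined features in a
    subject, are NaN in that subject's reduced map.
    """
    X = _check_features(features, model.weights.shape[1])
    if feature_names is not None and list(feature_names) != list(model.feature_names):
        raise PLSError(
            f"feature-name mismatch: model has {model.feature_names}, "
            f"got {list(feature_names)}"
        )
    frange = model.feature_max - model.feature_min
    zero_var = frange <= 0
    safe_range = np.where(zero_var, 1.0, frange)
    Xn = (X - model.feature_min) / safe_range
    Xn = np.where(zero_var[None, :, :], 0.0, Xn)
    reduced = np.einsum("svf,vf->sv", Xn - model.x_mean, model.weights)
    reduced[:, ~model.defined] = np.nan
    bad = ~np.all(np.isfinite(X), axis=2)
    reduced[bad] = np.nan
    return reduced
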