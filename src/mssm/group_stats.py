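"""Vertex-wise group statistics, FDR correction, effect-size comparison,
and the extra-region correlation analysis.

Group contrasts are unadjusted pooled-variance two-sample t-tests per
vertex (cohorts are matched by construction; a covariate-adjusted GLM
is available behind a flag).  Multiple comparisons are handled with the
Benjamini-Hochberg step-up procedure in a single family pooled over all
defined vertices.  Effect sizes are Cohen's d with the pooled standard
deviation.

The "extra region" analysis quantifies added value over thickness: for
each patient, y is the mean reduced multiscale value over vertices
significant for the multiscale map but NOT for thickness, and its
correlation with a cognitive score is reported raw and partialled on
either mean thickness over the whole cortex (x_all) or over the
thickness-significant vertices (x_sig).  Partial correlations use
residualisation on the control variable (rank-transformed first for the
Spearman variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class StatMap:
    t: np.ndarray
    p: np.ndarray
    d: np.ndarray               # Cohen's d
    significant: np.ndarray     # bool, BH-FDR at level q
    defined: np.ndarray         # bool
    q: float

    @property
    def n_vertices(self) -> int:
        return len(self.t)


def vertex_ttest(group_a: np.ndarray, group_b: np.ndarray, q: float = 0.05) -> StatMap:
    """Pooled-variance two-sample t-test at every vertex, BH-corrected.

    group_a, group_b : (n_subjects, n_vertices) reduced or thickness maps;
    NaN entries are omitted per vertex.  Vertices with fewer than two
    defined subjects in either group or zero pooled variance are undefined.
    """
    A = np.asarray(group_a, dtype=np.float64)
    B = np.asarray(group_b, dtype=np.float64)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("groups must be (n_subjects, n_vertices) on the same mesh")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")

    na = np.isfinite(A).sum(axis=0).astype(float)
    nb = np.isfinite(B).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = np.nanmean(A, axis=0)
        mb = np.nanmean(B, axis=0)
        va = np.nanvar(A, axis=0, ddof=1)
        vb = np.nanvar(B, axis=0, ddof=1)
        df = na + nb - 2.0
        pooled_var = ((na - 1.0) * va + (nb - 1.0) * vb) / df
        pooled_sd = np.sqrt(pooled_var)
        se = pooled_sd * np.sqrt(1.0 / na + 1.0 / nb)
        t = (ma - mb) / se
        d = (ma - mb) / pooled_sd

    defined = (na >= 2) & (nb >= 2) & np.isfinite(t) & (pooled_sd > 0)
    t = np.where(defined, t, np.nan)
    d = np.where(defined, d, np.nan)
    p = np.full_like(t, np.nan)
    p[defined] = 2.0 * stats.t.sf(np.abs(t[defined]), df[defined])
    # identical groups give p exactly 1 (t = 0)
    significant = bh_fdr(p, q)
    return StatMap(t=t, p=p, d=d, significant=significant, defined=defined, q=q)


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask over all defined p-values."""
    p = np.asarray(pvals, dtype=np.float64)
    mask = np.zeros(p.shape, dtype=bool)
    defined = np.isfinite(p)
    if defined.sum() == 0:
        return mask
    if np.any((p[defined] < 0) | (p[defined] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p[defined], alpha=q, method="fdr_bh")
    mask[defined] = reject
    return mask


def percent_significant(stat: StatMap) -> float:
    """Percentage of defined vertices passing the FDR threshold."""
    n_def = int(stat.defined.sum())
    if n_def == 0:
        return 0.0
    return 100.0 * float(stat.significant[stat.defined].sum()) / n_def


@dataclass
class EffectSizeComparison:
    d_difference: np.ndarray    # d_multiscale - d_thickness per vertex
    multiscale_better: np.ndarray  # |d_multiscale| > |d_thickness|
    defined: np.ndarray


def effect_size_comparison(mssm_stat: StatMap, ct_stat: StatMap) -> EffectSizeComparison:
    """Where is the multiscale map more effective than thickness alone?"""
    if mssm_stat.n_vertices != ct_stat.n_vertices:
        raise ValueError("stat maps must share the vertex set")
    defined = mssm_stat.defined & ct_stat.defined
    diff = np.where(defined, mssm_stat.d - ct_stat.d, np.nan)
    better = defined & (np.abs(mssm_stat.d) > np.abs(ct_stat.d))
    return EffectSizeComparison(diff, better, defined)


# ---------------------------------------------------------------------------
# extra-region correlation analysis
# ---------------------------------------------------------------------------

@dataclass
class CorrelationPair:
    pearson: float
    pearson_p: float
    spearman: float
    spearman_p: float


@dataclass
class ExtraRegionAnalysis:
    empty: bool
    extra_mask: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    y: np.ndarray = field(default_factory=lambda: np.array([]))       # per subject
    x_all: np.ndarray = field(default_factory=lambda: np.array([]))
    x_sig: np.ndarray = field(default_factory=lambda: np.array([]))
    raw: CorrelationPair | None = None
    partial_x_all: CorrelationPair | None = None
    partial_x_sig: CorrelationPair | None = None


def _residualize(v: np.ndarray, control: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(control), control])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def _corr_pair(a: np.ndarray, b: np.ndarray) -> CorrelationPair:
    pr = stats.pearsonr(a, b)
    sr = stats.spearmanr(a, b)
    return CorrelationPair(float(pr.statistic), float(pr.pvalue),
                           float(sr.statistic), float(sr.pvalue))


def _partial_pair(a: np.ndarray, b: np.ndarray, control: np.ndarray) -> CorrelationPair:
    # Pearson partial: residualise both on the control, correlate residuals.
    ra = _residualize(a, control)
    rb = _residualize(b, control)
    pr = stats.pearsonr(ra, rb)
    # Spearman partial: same on ranks
    ar, br, cr = (stats.rankdata(v).astype(float) for v in (a, b, control))
    sr = stats.pearsonr(_residualize(ar, cr), _residualize(br, cr))
    return CorrelationPair(float(pr.statistic), float(pr.pvalue),
                           float(sr.statistic), float(sr.pvalue))


def extra_region_correlation(
    mssm_maps: np.ndarray,
    thickness_maps: np.ndarray,
    scores: np.ndarray,
    mssm_significant: np.ndarray,
    ct_significant: np.ndarray,
) -> ExtraRegionAnalysis:
    """Correlate mean multiscale value in the "extra" vertices with a score.

    mssm_maps, thickness_maps : (n_subjects, n_vertices) for the patient group
    scores : (n_subjects,) cognitive score (e.g. FAQ)
    mssm_significant, ct_significant : boolean vertex masks from the group
        contrasts.  The extra region is significant-in-multiscale minus
        significant-in-thickness (disjoint from the latter by construction).
    """
    mssm_maps = np.asarray(mssm_maps, dtype=np.float64)
    thickness_maps = np.asarray(thickness_maps, dtype=np.float64)
    scores = np.asarray(scores, dtype=np.float64)
    extra = np.asarray(mssm_significant, bool) & ~np.asarray(ct_significant, bool)
    assert not np.any(extra & np.asarray(ct_significant, bool))
    if extra.sum() == 0:
        return ExtraRegionAnalysis(empty=True, extra_mask=extra)

    y = np.nanmean(mssm_maps[:, extra], axis=1)
    x_all = np.nanmean(thickness_maps, axis=1)
    if ct_significant.sum() > 0:
        x_sig = np.nanmean(thickness_maps[:, np.asarray(ct_significant, bool)], axis=1)
    else:
        x_sig = np.full(len(scores), np.nan)

    raw = _corr_pair(y, scores)
    partial_all = _partial_pair(y, scores, x_all)
    partial_sig = (
        _partial_pair(y, scores, x_sig) if np.all(np.isfinite(x_sig)) else None
    )
    return ExtraRegionAnalysis(
        empty=False,
        extra_mask=extra,
        y=y,
        x_all=x_all,
        x_sig=x_sig,
        raw=raw,
        partial_x_all=partial_all,
        partial_x_sig=partial_sig,
    )
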