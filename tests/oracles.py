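"""Independent reference implementations used only to check the package.

These deliberately use the most literal/brute-force formulation of each
quantity (NIPALS iteration, explicit step-up scan, pair counting) and
share no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np


def nipals_pls1_weight(X: np.ndarray, y: np.ndarray, max_iter: int = 500,
                       tol: float = 1e-12) -> np.ndarray:
    """First PLS1 weight vector by the classical NIPALS iteration.

    X (n, p) and y (n,) are centred internally.  For a single response
    the iteration converges in one step to w = X'y/||X'y||; running the
    loop anyway keeps this an independent oracle.
    """
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    w = Xc.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        return np.zeros(X.shape[1])
    w = w / nw
    for _ in range(max_iter):
        t = Xc @ w
        # PLS1: the y-score is yc itself; recompute the weight from it
        w_new = Xc.T @ yc
        w_new /= np.linalg.norm(w_new)
        if np.linalg.norm(w_new - w) < tol:
            break
        w = w_new
    if w @ (Xc.T @ yc) < 0:
        w = -w
    return w


def bh_stepup(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg by the literal step-up definition.

    Find the largest i with p_(i) <= i*q/m; reject every p <= p_(i).
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = 0.0
    for i in range(m, 0, -1):
        if sorted_p[i - 1] <= i * q / m:
            thresh = sorted_p[i - 1]
            break
    else:
        return np.zeros(m, dtype=bool)
    return p <= thresh


def pair_counting_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC as P(score_pos > score_neg) + 0.5 P(tie) over all pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def exhaustive_min_errors(scores: np.ndarray, labels: np.ndarray) -> int:
    """Minimum FP+FN over every possible threshold (including +/- inf)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    candidates = np.concatenate([[-np.inf], np.unique(scores), [np.inf]])
    best = len(labels)
    for t in candidates:
        pred = scores >= t
        err = int(np.sum(pred & (labels == 0)) + np.sum(~pred & (labels == 1)))
        best = min(best, err)
    return best


def pooled_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """(t, p, Cohen's d) by the literal pooled-variance formulas."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sa2 = np.sum((a - a.mean()) ** 2) / (na - 1)
    sb2 = np.sum((b - b.mean()) ** 2) / (nb - 1)
    sp = np.sqrt(((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2))
    tval = (a.mean() - b.mean()) / (sp * np.sqrt(1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(tval), na + nb - 2)
    d = (a.mean() - b.mean()) / sp
    return float(tval), float(p), float(d)
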