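"""ROC differentiation of participant groups and logistic added-value models.

AUC is computed as the Mann-Whitney concordance probability (ties counted
half), identical to the trapezoidal area under the empirical ROC curve.  The
optimal criterion maximizes the Youden index J = SE + SP - 100 (ties broken
toward higher specificity).  The p-value against AUC = 0.5 uses the
Hanley-McNeil standard error with a two-sided normal approximation.

The added-value analysis fits an (unpenalized, IRLS) logistic regression on
marker combinations and feeds the predicted probabilities back through the
ROC machinery; models are fitted and evaluated on the same sample, as is
conventional for this analysis, which makes combined AUCs optimistically
biased — they are comparisons within one cohort, not validated classifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats as st

__all__ = [
    "RocResult",
    "LogisticFit",
    "roc_curve",
    "auc",
    "youden_optimal",
    "auc_pvalue",
    "logistic_fit",
    "combined_roc",
]


@dataclass
class RocResult:
    auc: float
    sensitivity: float  # percent, at the optimal criterion
    specificity: float  # percent
    criterion: float
    pvalue: float
    n_pos: int
    n_neg: int
    flipped: bool = False  # True when scores were negated for AUC >= 0.5


@dataclass
class LogisticFit:
    coef: np.ndarray  # intercept first
    converged: bool
    iterations: int
    loglik: float
    separation_warning: bool = False


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    return y


def _orient(scores, labels) -> tuple[np.ndarray, np.ndarray, bool]:
    s = np.asarray(scores, dtype=float)
    y = _check_labels(labels)
    flipped = auc_raw(s, y) < 0.5
    return (-s if flipped else s), y, flipped


def auc_raw(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC without orientation (may be < 0.5)."""
    ranks = st.rankdata(scores)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(scores, labels) -> np.ndarray:
    """Empirical ROC as rows of ``(criterion, sensitivity%, specificity%)``.

    Classification rule: positive when score > criterion.  Criteria are the
    observed score values plus a sentinel below the minimum; the orientation
    is auto-detected so AUC >= 0.5 (scores negated when needed; see
    ``RocResult.flipped`` from :func:`combined_roc`).
    """
    s, y, _ = _orient(scores, labels)
    thr = np.concatenate([[-np.inf], np.unique(s)])
    n_pos = y.sum()
    n_neg = len(y) - n_pos
    rows = []
    for c in thr:
        pred = s > c
        se = 100.0 * np.sum(pred & (y == 1)) / n_pos
        sp = 100.0 * np.sum(~pred & (y == 0)) / n_neg
        rows.append((c, se, sp))
    return np.array(rows)


def auc(scores, labels) -> float:
    """Oriented Mann-Whitney AUC in [0.5, 1] (ties counted half)."""
    s, y, _ = _orient(scores, labels)
    return auc_raw(s, y)


def youden_optimal(roc: np.ndarray) -> tuple[float, float, float]:
    """Criterion maximizing J = SE + SP - 100; ties -> highest specificity.

    Returns ``(criterion, sensitivity%, specificity%)``.
    """
    if len(roc) == 0:
        raise ValueError("empty ROC curve")
    j = roc[:, 1] + roc[:, 2] - 100.0
    best = np.flatnonzero(j == j.max())
    pick = best[np.argmax(roc[best, 2])]
    return float(roc[pick, 0]), float(roc[pick, 1]), float(roc[pick, 2])


def auc_pvalue(auc_value: float, n_pos: int, n_neg: int) -> float:
    """Two-sided p against AUC = 0.5 (Hanley-McNeil normal approximation)."""
    if n_pos < 3 or n_neg < 3:
        raise ValueError("need at least 3 subjects per class")
    a = float(auc_value)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a**2 / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a**2) + (n_neg - 1) * (q2 - a**2)) / (
        n_pos * n_neg
    )
    if var <= 0:
        return 0.0 if a != 0.5 else 1.0
    z = (a - 0.5) / np.sqrt(var)
    return float(2.0 * st.norm.sf(abs(z)))


def logistic_fit(
    X, y, tol: float = 1e-8, max_iter: int = 100
) -> LogisticFit:
    """Unpenalized logistic regression by iteratively reweighted least squares.

    ``X`` is (n, p) without the intercept column (added internally).
    Convergence: gradient max-norm < ``tol``.  Perfect separation is flagged
    (diverging coefficients) and the current fit returned with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    y = _check_labels(y)
    n, p = X.shape
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant predictor column (besides the intercept)")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear predictor columns")
    beta = np.zeros(p + 1)
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = mu * (1.0 - mu)
        grad = design.T @ (y - mu)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        wx = design * np.maximum(w, 1e-10)[:, None]
        try:
            step = np.linalg.solve(design.T @ wx, grad)
        except np.linalg.LinAlgError:
            separation = True
            break
        beta = beta + step
        if np.max(np.abs(beta)) > 1e3:
            separation = True
            break
    # perfect separation also shows up as full saturation of the fitted
    # probabilities (the likelihood sup is on the boundary)
    mu = 1.0 / (1.0 + np.exp(-np.clip(design @ beta, -35, 35)))
    if np.all(np.abs(mu - y) < 1e-6):
        separation = True
    if separation or (not converged and it == max_iter):
        if separation:
            warnings.warn(
                "possible perfect separation: coefficients diverging", stacklevel=2
            )
        else:
            warnings.warn("logistic IRLS did not converge", stacklevel=2)
    eta = design @ beta
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return LogisticFit(
        coef=beta, converged=converged, iterations=it, loglik=ll,
        separation_warning=separation,
    )


def predicted_probabilities(fit: LogisticFit, X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    eta = np.column_stack([np.ones(X.shape[0]), X]) @ fit.coef
    return 1.0 / (1.0 + np.exp(-eta))


def combined_roc(X, y) -> RocResult:
    """ROC of logistic predicted probabilities for a marker combination.

    With a single predictor the probabilities are a monotone transform of
    the marker, so the result equals the raw-marker ROC.  Fitted and
    evaluated on the same sample (no cross-validation).
    """
    y = _check_labels(y)
    fit = logistic_fit(X, y)
    p = predicted_probabilities(fit, X)
    s, yy, flipped = _orient(p, y)
    a = auc_raw(s, yy)
    crit, se, sp = youden_optimal(roc_curve(p, y))
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    return RocResult(
        auc=a,
        sensitivity=se,
        specificity=sp,
        criterion=crit,
        pvalue=auc_pvalue(a, n_pos, n_neg),
        n_pos=n_pos,
        n_neg=n_neg,
        flipped=flipped,
    )


def single_marker_roc(scores, labels) -> RocResult:
    """Full ROC summary (AUC, Youden SE/SP, p) for one raw marker."""
    y = _check_labels(labels)
    a = auc(scores, y)
    crit, se, sp = youden_optimal(roc_curve(scores, y))
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    s, _, flipped = _orient(scores, y)
    return RocResult(a, se, sp, crit, auc_pvalue(a, n_pos, n_neg), n_pos, n_neg, flipped)
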