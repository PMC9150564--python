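"""ROI-level statistical battery: omnibus tests, post-hocs and correlations.

Implements the analysis set used for three-group dementia cohorts: one-way
ANOVA (raw data or printed summary statistics) with Scheffe post-hoc,
tie-corrected Kruskal-Wallis with Conover-Iman post-hoc, Pearson chi-squared
for sex tables, Spearman rank correlation, and partial correlation
(Pearson-on-residuals, with an optional rank-transformed variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats as st

__all__ = [
    "TestResult",
    "PairResult",
    "anova_oneway",
    "scheffe_posthoc",
    "kruskal_wallis",
    "conover_posthoc",
    "chi_squared",
    "spearman",
    "partial_correlation",
    "normality_diagnostic",
]


@dataclass
class PairResult:
    pair: tuple
    statistic: float
    pvalue: float
    significant: bool


@dataclass
class TestResult:
    """Statistic, p-value and optional post-hoc pairs."""

    name: str
    statistic: float
    pvalue: float
    df: tuple | float | None = None
    pairs: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    @property
    def significant_pairs(self) -> list[tuple]:
        return [p.pair for p in self.pairs if p.significant]


def _as_groups(groups) -> list[np.ndarray]:
    if isinstance(groups, dict):
        return [np.asarray(v, dtype=float) for v in groups.values()]
    return [np.asarray(g, dtype=float) for g in groups]


def anova_oneway(groups=None, summaries=None) -> TestResult:
    """One-way fixed-effects ANOVA from raw groups or (n, mean, sd) triples.

    With summary triples the sums of squares are reconstructed exactly:
    SSB = sum n_g (m_g - m)^2, SSW = sum (n_g - 1) s_g^2, and
    F = (SSB/(k-1)) / (SSW/(N-k)) with p from F(k-1, N-k).
    """
    if (groups is None) == (summaries is None):
        raise ValueError("pass exactly one of groups= or summaries=")
    if groups is not None:
        gs = _as_groups(groups)
        summaries = [(len(g), float(np.mean(g)), float(np.std(g, ddof=1))) for g in gs]
    ns = np.array([s[0] for s in summaries], dtype=float)
    means = np.array([s[1] for s in summaries], dtype=float)
    sds = np.array([s[2] for s in summaries], dtype=float)
    k = len(ns)
    if k < 2 or np.any(ns < 2):
        raise ValueError("need >= 2 groups with n >= 2 each")
    n_tot = ns.sum()
    grand = float(np.sum(ns * means) / n_tot)
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(np.sum((ns - 1) * sds**2))
    df1, df2 = k - 1, int(n_tot - k)
    if ssw == 0:
        if ssb == 0:
            raise ValueError("zero within- and between-group variance: F undefined")
        return TestResult("anova", np.inf, 0.0, (df1, df2))
    f = (ssb / df1) / (ssw / df2)
    return TestResult(
        "anova", f, float(st.f.sf(f, df1, df2)), (df1, df2),
        extra={"ssb": ssb, "ssw": ssw, "grand_mean": grand},
    )


def scheffe_posthoc(groups, alpha: float = 0.05) -> TestResult:
    """Scheffe all-pairs comparison after a one-way ANOVA (raw data only).

    Pair (i, j) is significant when
    ``(m_i - m_j)^2 / (MSW (1/n_i + 1/n_j)) > (k-1) F_crit(alpha; k-1, N-k)``;
    the reported pair p-value is ``sf(F_pair/(k-1))`` on the same F
    distribution, the standard Scheffe adjustment.
    """
    if isinstance(groups, (list, tuple)) and groups and isinstance(groups[0], tuple) \
            and len(groups[0]) == 3 and np.isscalar(groups[0][0]):
        raise ValueError("Scheffe post-hoc needs raw data, not summary triples")
    gs = _as_groups(groups)
    omnibus = anova_oneway(groups=gs)
    k = len(gs)
    df1, df2 = omnibus.df
    msw = omnibus.extra["ssw"] / df2
    crit = (k - 1) * st.f.isf(alpha, df1, df2)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            num = (np.mean(gs[i]) - np.mean(gs[j])) ** 2
            fp = num / (msw * (1 / len(gs[i]) + 1 / len(gs[j]))) if msw > 0 else np.inf
            p = float(st.f.sf(fp / (k - 1), df1, df2))
            pairs.append(PairResult((i, j), float(fp), p, bool(fp > crit)))
    return TestResult("scheffe", omnibus.statistic, omnibus.pvalue, omnibus.df, pairs)


def kruskal_wallis(groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-squared p (df = k-1).

    All-identical samples return H = 0, p = 1 (no evidence of a difference).
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(gs)
    n = len(pooled)
    ranks = st.rankdata(pooled)
    splits = np.cumsum([len(g) for g in gs])[:-1]
    rank_groups = np.split(ranks, splits)
    h = 12.0 / (n * (n + 1)) * sum(
        len(r) * (np.mean(r) - (n + 1) / 2.0) ** 2 for r in rank_groups
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if tie_corr == 0:  # every value identical
        return TestResult("kruskal_wallis", 0.0, 1.0, len(gs) - 1)
    h /= tie_corr
    df = len(gs) - 1
    return TestResult("kruskal_wallis", float(h), float(st.chi2.sf(h, df)), df)


def conover_posthoc(groups, alpha: float = 0.05, bonferroni: bool = False) -> TestResult:
    """Conover-Iman rank post-hoc after Kruskal-Wallis.

    t statistics on pooled mid-ranks with the pooled tie-corrected rank
    variance S^2 and the KW-deflated scale S^2 (N-1-H)/(N-k); two-sided p
    from t(N-k).  Pair p-values are unadjusted by default (``bonferroni=True``
    multiplies by the number of pairs).  Groups of size 1 are excluded.
    """
    gs = _as_groups(groups)
    omnibus = kruskal_wallis(gs)
    h = omnibus.statistic
    pooled = np.concatenate(gs)
    n = len(pooled)
    k = len(gs)
    ranks = st.rankdata(pooled)
    splits = np.cumsum([len(g) for g in gs])[:-1]
    rank_groups = np.split(ranks, splits)
    s2 = (np.sum(ranks**2) - n * (n + 1) ** 2 / 4.0) / (n - 1)
    scale = s2 * (n - 1 - h) / (n - k)
    df = n - k
    n_pairs = k * (k - 1) // 2
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            if len(gs[i]) < 2 or len(gs[j]) < 2:
                pairs.append(PairResult((i, j), np.nan, np.nan, False))
                continue
            se = np.sqrt(scale * (1.0 / len(gs[i]) + 1.0 / len(gs[j])))
            if se == 0:
                pairs.append(PairResult((i, j), 0.0, 1.0, False))
                continue
            t = (np.mean(rank_groups[i]) - np.mean(rank_groups[j])) / se
            p = float(2.0 * st.t.sf(abs(t), df))
            if bonferroni:
                p = min(1.0, p * n_pairs)
            pairs.append(PairResult((i, j), float(t), p, bool(p < alpha)))
    return TestResult("conover", h, omnibus.pvalue, omnibus.df, pairs)


def chi_squared(table) -> TestResult:
    """Pearson chi-squared test of independence (no continuity correction)."""
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.number):
        raise ValueError("contingency table must be non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in the contingency table")
    chi2, p, dof, _ = st.chi2_contingency(table, correction=False)
    return TestResult("chi_squared", float(chi2), float(p), dof)


def spearman(x, y) -> TestResult:
    """Spearman rank correlation (mid-ranks) with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired vectors of length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = st.spearmanr(x, y)
    return TestResult("spearman", float(rho), float(p), len(x) - 2)


def partial_correlation(x, y, covariates, method: str = "pearson") -> TestResult:
    """Correlation of x and y after least-squares removal of covariates.

    ``covariates`` is (n,) or (n, k).  p-value from the t distribution with
    df = n - k - 2.  ``method='spearman'`` rank-transforms all variables
    first (rank partial correlation).  Collinear covariates raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if z.shape[0] != len(x):
        z = z.T
    n, k = z.shape
    if len(x) != n or len(y) != n:
        raise ValueError("x, y and covariates must share the sample dimension")
    if n <= k + 3:
        raise ValueError(f"need n > {k + 3} samples for {k} covariates")
    if method == "spearman":
        x, y = st.rankdata(x), st.rankdata(y)
        z = np.column_stack([st.rankdata(c) for c in z.T])
    design = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear covariates")
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    # a variable fully explained by the covariates has no residual signal
    if np.linalg.norm(rx) <= 1e-10 * np.linalg.norm(x - x.mean()) or \
            np.linalg.norm(ry) <= 1e-10 * np.linalg.norm(y - y.mean()):
        return TestResult("partial_correlation", 0.0, 1.0, n - k - 2, extra={"method": method})
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    r = float(np.dot(rx, ry) / denom)
    df = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * st.t.sf(abs(t), df))
    return TestResult("partial_correlation", r, p, df, extra={"method": method})


def normality_diagnostic(x) -> TestResult:
    """Kolmogorov-Smirnov normality check (reported, never an automatic switch)."""
    x = np.asarray(x, dtype=float)
    stat, p = st.kstest((x - x.mean()) / x.std(ddof=1), "norm")
    return TestResult("ks_normality", float(stat), float(p))
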