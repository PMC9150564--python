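"""Mass-univariate voxel-wise GLM: ANCOVA/regression, FDR, cluster extent.

``fit_glm`` runs ordinary least squares for every voxel at once (data is
voxels x subjects); ``contrast_test`` evaluates t (one-row) or F (multi-row)
contrasts with exact t/F p-values; ``fdr_bh`` applies Benjamini-Hochberg
step-up control within the analysis mask; ``cluster_filter`` removes
connected components below the extent threshold (face connectivity by
default, the common SPM convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DesignMatrix",
    "GLMFit",
    "StatMap",
    "ClusterSet",
    "make_design",
    "fit_glm",
    "contrast_test",
    "fdr_bh",
    "cluster_filter",
]


@dataclass
class DesignMatrix:
    """Subjects x regressors with column names; must be full column rank."""

    X: np.ndarray
    names: list

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise ValueError("design shape and names disagree")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            # name the first column that is linearly dependent on its predecessors
            for j in range(1, self.X.shape[1] + 1):
                if np.linalg.matrix_rank(self.X[:, :j]) < j:
                    raise ValueError(
                        f"rank-deficient design: column {self.names[j - 1]!r} is "
                        "collinear with earlier columns"
                    )
            raise ValueError("rank-deficient design")


def make_design(
    subjects: pd.DataFrame,
    groups: bool = True,
    covariates: tuple = ("age",),
    intercept: bool = True,
) -> DesignMatrix:
    """Cell-means group indicators plus centered covariates.

    With ``groups=True`` one indicator column per group level is included and
    the intercept is dropped (cell-means coding keeps the design full rank).
    """
    cols, names = [], []
    if groups:
        for g in pd.unique(subjects["group"]):
            cols.append((subjects["group"] == g).to_numpy(float))
            names.append(f"group_{g}")
    elif intercept:
        cols.append(np.ones(len(subjects)))
        names.append("intercept")
    for c in covariates:
        v = subjects[c].to_numpy(float)
        cols.append(v - v.mean())
        names.append(c)
    return DesignMatrix(np.column_stack(cols), names)


@dataclass
class GLMFit:
    beta: np.ndarray  # voxels x regressors
    sigma2: np.ndarray  # voxels, residual variance (df-adjusted)
    df: int
    design: DesignMatrix
    xtx_inv: np.ndarray


@dataclass
class StatMap:
    stat: np.ndarray
    p: np.ndarray
    kind: str  # "t" or "F"
    df: tuple


@dataclass
class ClusterSet:
    labels: np.ndarray
    sizes: dict
    peaks: dict = field(default_factory=dict)  # label -> (index tuple, stat)

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


def fit_glm(data: np.ndarray, design: DesignMatrix) -> GLMFit:
    """Voxel-wise OLS.  ``data`` is (n_voxels, n_subjects)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    X = design.X
    n, p = X.shape
    if data.shape[1] != n:
        raise ValueError("data subject dimension does not match the design")
    if n < p + 2:
        raise ValueError("need at least regressors + 2 subjects")
    pinv = np.linalg.pinv(X)
    beta = data @ pinv.T
    resid = data - beta @ X.T
    df = n - p
    sigma2 = np.sum(resid**2, axis=1) / df
    return GLMFit(beta=beta, sigma2=sigma2, df=df,
                  design=design, xtx_inv=np.linalg.inv(X.T @ X))


def contrast_test(fit: GLMFit, contrast) -> StatMap:
    """t test (one-row contrast) or F test (multi-row) per voxel."""
    c = np.atleast_2d(np.asarray(contrast, dtype=float))
    if c.shape[1] != fit.beta.shape[1]:
        raise ValueError("contrast not conformable with the design")
    if not np.any(c):
        raise ValueError("zero contrast")
    if c.shape[0] == 1:
        cv = float((c @ fit.xtx_inv @ c.T).item())
        se = np.sqrt(fit.sigma2 * cv)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (fit.beta @ c.ravel()) / se
        p = 2.0 * st.t.sf(np.abs(t), fit.df)
        return StatMap(stat=t, p=p, kind="t", df=(fit.df,))
    q = c.shape[0]
    if np.linalg.matrix_rank(c) < q:
        raise ValueError("contrast rows are linearly dependent")
    cb = fit.beta @ c.T  # voxels x q
    m = np.linalg.inv(c @ fit.xtx_inv @ c.T)
    quad = np.einsum("vq,qr,vr->v", cb, m, cb)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = quad / (q * fit.sigma2)
    p = st.f.sf(f, q, fit.df)
    return StatMap(stat=f, p=p, kind="F", df=(q, fit.df))


def fdr_bh(p, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up.  Returns (rejection mask, p threshold).

    The threshold is the largest p-value rejected (0 when nothing passes).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    thr = float(p[reject].max()) if reject.any() else 0.0
    return reject, thr


_STRUCTURES = {
    "face": ndi.generate_binary_structure(2, 1),
    "face+edge": ndi.generate_binary_structure(2, 2),
}


def cluster_filter(
    mask: np.ndarray,
    min_extent: int = 100,
    connectivity: str = "face",
    stat: np.ndarray | None = None,
) -> ClusterSet:
    """Label connected components and drop those below ``min_extent`` voxels.

    2-D masks accept connectivity 'face' (4-neighborhood, default) or
    'face+edge' (8-neighborhood); for 3-D masks the three standard
    structures ('face', 'face+edge', 'face+edge+corner') are generated.
    Optionally records each surviving cluster's peak |stat| location.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 2:
        if connectivity not in _STRUCTURES:
            raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
        structure = _STRUCTURES[connectivity]
    else:
        order = {"face": 1, "face+edge": 2, "face+edge+corner": 3}
        structure = ndi.generate_binary_structure(mask.ndim, order[connectivity])
    labeled, n = ndi.label(mask, structure=structure)
    sizes_all = ndi.sum_labels(mask, labeled, index=np.arange(1, n + 1))
    out = np.zeros_like(labeled)
    sizes, peaks = {}, {}
    new = 0
    for lab, size in enumerate(sizes_all, start=1):
        if size < min_extent:
            continue
        new += 1
        sel = labeled == lab
        out[sel] = new
        sizes[new] = int(size)
        if stat is not None:
            flat = np.where(sel, np.abs(stat), -np.inf)
            idx = np.unravel_index(np.argmax(flat), mask.shape)
            peaks[new] = (idx, float(stat[idx]))
    return ClusterSet(labels=out, sizes=sizes, peaks=peaks)
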