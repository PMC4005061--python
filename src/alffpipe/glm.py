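"""Voxelwise two-sample comparison with covariate adjustment.

The group comparison is an ordinary least-squares fit per voxel,

    y = X b + e,    X = [1, g, c_1, ...],

with the group column coded +1 for group A and -1 for group B, covariates
mean-centered, and the group effect tested with t = c'b / sqrt(s2 c'(X'X)^-1 c)
on n - p residual degrees of freedom. Without a covariate this t is exactly
the classical pooled-variance two-sample t; the sign encodes the direction
(positive means group A larger). The gray-matter covariate can be a single
number per subject (e.g. total GM volume) or a voxelwise map per subject, in
which case the covariate column is re-filled at every voxel (an ANCOVA on
images). P-values are two-tailed Student-t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .image_io import BrainMask, ScalarMap, _require_same_grid

__all__ = ["DesignMatrix", "GlmResult", "build_design", "fit_voxelwise_glm", "t_to_p"]

log = logging.getLogger(__name__)

_RANK_TOL = 1e-10


@dataclass
class DesignMatrix:
    """Subjects x predictors with named columns and a group contrast."""

    X: np.ndarray
    columns: list[str]
    contrast: np.ndarray
    positive_label: str
    negative_label: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.contrast = np.asarray(self.contrast, dtype=np.float64)
        n, p = self.X.shape
        if len(self.columns) != p or self.contrast.shape != (p,):
            raise ValueError("columns/contrast length must equal the design width")
        if np.linalg.matrix_rank(self.X) < p:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.columns)


def build_design(
    groups: list[str],
    covariates: dict[str, np.ndarray] | None = None,
    positive_label: str | None = None,
) -> DesignMatrix:
    """Intercept + (+1/-1) group column + mean-centered covariate columns.

    ``positive_label`` picks which group is coded +1 (default: the label of
    the first subject). Covariates given here are scalar per subject; a
    voxelwise covariate is supplied to :func:`fit_voxelwise_glm` instead and
    occupies a placeholder column.
    """
    labels = list(dict.fromkeys(groups))  # unique, in order of appearance
    if len(labels) != 2:
        raise ValueError(f"need exactly two distinct group labels, got {labels}")
    pos = positive_label if positive_label is not None else labels[0]
    if pos not in labels:
        raise ValueError(f"positive_label {pos!r} not among group labels {labels}")
    neg = labels[1] if pos == labels[0] else labels[0]
    g = np.where(np.asarray(groups) == pos, 1.0, -1.0)
    if np.all(g == g[0]):
        raise ValueError("one group is empty")

    cols = [np.ones(len(groups)), g]
    names = ["intercept", "group"]
    for name, vals in (covariates or {}).items():
        v = np.asarray(vals, dtype=np.float64)
        if v.shape != (len(groups),):
            raise ValueError(f"covariate {name!r} must have one value per subject")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"covariate {name!r} has non-finite values")
        cols.append(v - v.mean())
        names.append(name)
    X = np.column_stack(cols)
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    return DesignMatrix(X, names, contrast, pos, neg)


@dataclass
class GlmResult:
    tmap: ScalarMap
    pmap: ScalarMap
    df: int
    betas: dict[str, ScalarMap] = field(default_factory=dict)
    n_flagged: int = 0  # voxels zeroed for voxelwise rank deficiency


def t_to_p(t: np.ndarray | float, df: int) -> np.ndarray | float:
    """Two-tailed p-value under Student t with ``df`` degrees of freedom."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return 2.0 * scipy.stats.t.sf(np.abs(t), df)


def fit_voxelwise_glm(
    maps: list[ScalarMap],
    design: DesignMatrix,
    mask: BrainMask,
    voxelwise_covariate: list[ScalarMap] | None = None,
    covariate_name: str = "gm",
) -> GlmResult:
    """OLS fit at every masked voxel; t and two-tailed p for the group contrast.

    When ``voxelwise_covariate`` is given, the design gains one column that
    is re-filled (and re-centered) per voxel from the subjects' maps. A voxel
    where that column is (numerically) constant makes the local design rank
    deficient; such voxels get t = 0, p = 1, are counted in ``n_flagged``,
    and never abort the whole map.
    """
    n = design.n_subjects
    if len(maps) != n:
        raise ValueError(f"got {len(maps)} maps for {n} design rows")
    for i, m in enumerate(maps):
        _require_same_grid(maps[0].grid, m.grid, f"fit_voxelwise_glm (map {i})")
    _require_same_grid(maps[0].grid, mask.grid, "fit_voxelwise_glm (mask)")
    grid = maps[0].grid
    mv = mask.data
    Y = np.stack([m.data[mv] for m in maps], axis=0)  # (n, V)
    V = Y.shape[1]

    if voxelwise_covariate is None:
        X = design.X
        c = design.contrast
        p = X.shape[1]
        df = n - p
        if df < 1:
            raise ValueError("not enough subjects for the design")
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ (X.T @ Y)                    # (p, V)
        resid = Y - X @ beta
        rss = np.einsum("nv,nv->v", resid, resid)
        sigma2 = rss / df
        cvar = float(c @ XtX_inv @ c)
        denom = np.sqrt(np.maximum(sigma2 * cvar, 0.0))
        eff = c @ beta
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom > 0, eff / denom, 0.0)
        flagged = np.zeros(V, dtype=bool)
        beta_v = beta.T                               # (V, p)
        names = design.columns
    else:
        if len(voxelwise_covariate) != n:
            raise ValueError("need one covariate map per subject")
        for i, m in enumerate(voxelwise_covariate):
            _require_same_grid(grid, m.grid, f"fit_voxelwise_glm (covariate {i})")
        C = np.stack([m.data[mv] for m in voxelwise_covariate], axis=0)  # (n, V)
        C = C - C.mean(axis=0, keepdims=True)
        p = design.n_predictors + 1
        df = n - p
        if df < 1:
            raise ValueError("not enough subjects for the design")
        names = design.columns + [covariate_name]
        c = np.concatenate([design.contrast, [0.0]])
        Xv = np.empty((V, n, p))
        Xv[:, :, :-1] = design.X[None, :, :]
        Xv[:, :, -1] = C.T
        flagged = C.std(axis=0) < _RANK_TOL
        # make flagged voxels solvable, zero them afterwards
        if flagged.any():
            Xv[flagged, :, -1] = np.linspace(-1, 1, n)[None, :]
        XtX = np.einsum("vnp,vnq->vpq", Xv, Xv)
        XtX_inv = np.linalg.inv(XtX)
        Xty = np.einsum("vnp,vn->vp", Xv, Y.T[:, :])
        beta_v = np.einsum("vpq,vq->vp", XtX_inv, Xty)  # (V, p)
        resid = Y.T - np.einsum("vnp,vp->vn", Xv, beta_v)
        rss = np.einsum("vn,vn->v", resid, resid)
        sigma2 = rss / df
        cvar = np.einsum("p,vpq,q->v", c, XtX_inv, c)
        denom = np.sqrt(np.maximum(sigma2 * cvar, 0.0))
        eff = beta_v @ c
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom > 0, eff / denom, 0.0)
        t[flagged] = 0.0
        if flagged.any():
            log.warning(
                "fit_voxelwise_glm: %d voxels had a constant covariate column; "
                "t set to 0 there", int(flagged.sum()),
            )

    pvals = np.asarray(t_to_p(t, df))
    pvals[flagged] = 1.0

    def _embed(vec: np.ndarray, kind: str) -> ScalarMap:
        out = np.zeros(grid.shape)
        out[mv] = vec
        return ScalarMap(grid, out, kind=kind)

    betas = {name: _embed(beta_v[:, j], "effect") for j, name in enumerate(names)}
    return GlmResult(
        tmap=_embed(t, "tstat"),
        pmap=_embed(pvals, "pvalue"),
        df=df,
        betas=betas,
        n_flagged=int(flagged.sum()),
    )
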