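"""Voxelwise association of parametric BPnd images with behavioral scores.

The model at each in-mask voxel is ordinary least squares of BPnd on an
intercept, the behavioral score, and (by default) the global-mean BPnd of
each scan as a nuisance covariate; the reported statistic is the t of the
score coefficient with ``df = n_scans - n_columns``.  Statistical maps are
thresholded at an uncorrected voxelwise p and grouped into connected
clusters.  Scatter values for peak voxels are partial-regression
(residualized, standardized) pairs whose correlation reproduces the GLM t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "GlmDesign",
    "GlmResult",
    "gaussian_smooth",
    "fit_voxel_glm",
    "threshold_and_cluster",
    "residualized_scatter",
    "scatter_t",
]

#: |t| assigned to voxels with an exactly zero residual (perfect fit).
T_CAP = 1e12

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gaussian_smooth(data: np.ndarray, fwhm_mm: float,
                    voxel_size_mm=1.0, mask: np.ndarray | None = None) -> np.ndarray:
    """Separable Gaussian smoothing with kernel renormalization at boundaries.

    ``fwhm_mm`` is converted to a per-axis sigma in voxels using the voxel
    size (scalar or per-axis).  Smoothing is mask-aware (normalized
    convolution): the kernel weight falling outside the volume or the mask is
    redistributed, so a constant image stays exactly constant.  ``fwhm <= 0``
    returns the input unchanged with a warning.
    """
    data = np.asarray(data, dtype=float)
    if fwhm_mm <= 0:
        warnings.warn("fwhm <= 0: smoothing is the identity", stacklevel=2)
        return data.copy()
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (data.ndim,))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vs
    m = np.ones_like(data) if mask is None else np.asarray(mask, dtype=float)
    num = ndimage.gaussian_filter(data * m, sigma_vox, mode="constant")
    den = ndimage.gaussian_filter(m, sigma_vox, mode="constant")
    out = np.zeros_like(data)
    inside = den > 1e-12
    out[inside] = num[inside] / den[inside]
    if mask is not None:
        out[np.asarray(mask) <= 0] = 0.0
    return out


@dataclass
class GlmDesign:
    """Per-scan design: behavioral score, optional global-mean covariate.

    ``global_mean`` may be a vector (one value per scan), ``None`` (computed
    from the image stack within the brain mask), or the string ``"scale"``
    for proportional scaling: each scan is divided by its global mean and no
    covariate column is added, giving a two-column design (df = n - 2, the
    convention under which 20 scans yield t(18)).
    """

    score: np.ndarray
    global_mean: np.ndarray | str | None = None
    intercept: bool = True

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if np.ptp(self.score) == 0:
            raise ValueError("behavioral score must not be constant")


@dataclass
class GlmResult:
    t_map: np.ndarray
    df: int
    beta_maps: np.ndarray      # (n_columns, *shape)
    mask: np.ndarray
    design_matrix: np.ndarray
    score_column: int
    capped: np.ndarray         # voxels with zero residual (|t| capped)

    @property
    def p_map(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return 2.0 * stats.t.sf(np.abs(self.t_map), self.df)


def _stack(images) -> np.ndarray:
    vols = []
    for img in images:
        vols.append(img.get_fdata() if hasattr(img, "get_fdata") else np.asarray(img, dtype=float))
    return np.stack(vols, axis=0)


def fit_voxel_glm(images, design: GlmDesign, mask: np.ndarray,
                  brain_mask: np.ndarray | None = None) -> GlmResult:
    """Per-voxel OLS of BPnd on the design; t-statistic of the score column.

    ``images`` is a sequence of 3-D images (or arrays) on one grid, one per
    scan.  ``mask`` restricts the statistics (e.g. the striatum);
    ``brain_mask`` (default: ``mask``) defines the region over which each
    scan's global mean is computed when the design asks for it.
    """
    y4 = _stack(images)
    n = y4.shape[0]
    m = (mask.get_fdata() if hasattr(mask, "get_fdata") else np.asarray(mask)) > 0
    if m.shape != y4.shape[1:]:
        raise ValueError("mask shape does not match image grid")
    bm = m if brain_mask is None else np.asarray(brain_mask) > 0

    y = y4[:, m]  # (n_scans, V)
    gmean = np.array([v[bm].mean() for v in y4])

    cols = []
    names = []
    if design.intercept:
        cols.append(np.ones(n))
        names.append("intercept")
    cols.append(design.score)
    names.append("score")
    score_col = len(cols) - 1
    if isinstance(design.global_mean, str):
        if design.global_mean != "scale":
            raise ValueError("global_mean must be a vector, None, or 'scale'")
        y = y / gmean[:, None]
    else:
        gcov = gmean if design.global_mean is None else np.asarray(design.global_mean, float)
        if gcov.shape != (n,):
            raise ValueError("global_mean covariate must have one value per scan")
        cols.append(gcov)
        names.append("global_mean")
    x = np.column_stack(cols)
    if design.score.shape != (n,):
        raise ValueError("score must have one value per scan")

    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        bad = []
        for j in range(x.shape[1]):
            others = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(x):
                bad.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    dof = n - x.shape[1]
    if dof < 1:
        raise ValueError("need more scans than design columns")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y                       # (p, V)
    resid = y - x @ beta
    rss = np.sum(resid**2, axis=0)
    sigma2 = rss / dof
    se = np.sqrt(sigma2 * xtx_inv[score_col, score_col])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vals = beta[score_col] / se
    # an (up to rounding) exact linear fit has no finite t: cap and flag it
    y_ss = np.maximum(np.sum((y - y.mean(axis=0)) ** 2, axis=0), 1e-300)
    capped_v = rss / y_ss < 1e-24
    t_vals[capped_v] = np.sign(beta[score_col][capped_v]) * T_CAP

    shape = y4.shape[1:]
    t_map = np.full(shape, np.nan)
    t_map[m] = t_vals
    beta_maps = np.full((x.shape[1],) + shape, np.nan)
    beta_maps[:, m] = beta
    capped = np.zeros(shape, dtype=bool)
    capped[m] = capped_v
    return GlmResult(t_map=t_map, df=dof, beta_maps=beta_maps, mask=m,
                     design_matrix=x, score_column=score_col, capped=capped)


def threshold_and_cluster(result: GlmResult, p_thresh: float = 0.05,
                          sign: str = "both", connectivity: int = 26,
                          affine: np.ndarray | None = None) -> pd.DataFrame:
    """Suprathreshold clusters of the t-map.

    Voxels with two-sided p below ``p_thresh`` (restricted to ``sign`` =
    "positive"/"negative"/"both") are grouped by 26- (default) or
    6-connectivity.  Each row reports cluster size, the peak t and its voxel
    coordinate, and — when an affine is given — the peak coordinate mapped to
    template space (pass-through of the input affine; no registration).
    """
    t_crit = stats.t.isf(p_thresh / 2.0, result.df)
    t = result.t_map
    with np.errstate(invalid="ignore"):
        supra = np.abs(t) > t_crit
        if sign == "positive":
            supra &= t > 0
        elif sign == "negative":
            supra &= t < 0
        elif sign != "both":
            raise ValueError("sign must be 'positive', 'negative', or 'both'")
    supra &= result.mask
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    labels, n_clusters = ndimage.label(supra, structure=structure)
    rows = []
    for lab in range(1, n_clusters + 1):
        idx = np.argwhere(labels == lab)
        ts = t[tuple(idx.T)]
        peak = idx[np.argmax(np.abs(ts))]
        row = {"cluster": lab, "size": int(idx.shape[0]),
               "peak_t": float(t[tuple(peak)]),
               "peak_i": int(peak[0]), "peak_j": int(peak[1]), "peak_k": int(peak[2])}
        if affine is not None:
            xyz = affine @ np.append(peak, 1.0)
            row.update({"peak_x_mm": float(xyz[0]), "peak_y_mm": float(xyz[1]),
                        "peak_z_mm": float(xyz[2])})
        rows.append(row)
    cols = ["cluster", "size", "peak_t", "peak_i", "peak_j", "peak_k"]
    if affine is not None:
        cols += ["peak_x_mm", "peak_y_mm", "peak_z_mm"]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values("size", ascending=False).reset_index(drop=True) if len(out) else out


def residualized_scatter(values: np.ndarray, design_matrix: np.ndarray,
                         score_column: int) -> pd.DataFrame:
    """Partial-regression pairs for one voxel (or ROI mean) across scans.

    Both the response and the score column are residualized on the remaining
    design columns and z-scored (ddof = 1).  The correlation of the returned
    pairs carries the same information as the GLM t at that voxel:
    ``t = r sqrt(df / (1 - r^2))`` (see :func:`scatter_t`).
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(design_matrix, dtype=float)
    z = np.delete(x, score_column, axis=1)
    s = x[:, score_column]

    def resid(v: np.ndarray) -> np.ndarray:
        if z.shape[1] == 0:
            return v - 0.0
        coef, *_ = np.linalg.lstsq(z, v, rcond=None)
        return v - z @ coef

    ry = resid(y)
    rs = resid(s)
    if np.allclose(ry, 0) or np.allclose(rs, 0):
        raise ValueError("zero-variance residuals; scatter undefined")

    def zscore(v: np.ndarray) -> np.ndarray:
        return (v - v.mean()) / v.std(ddof=1)

    return pd.DataFrame({"score_resid": zscore(rs), "bpnd_resid": zscore(ry)})


def scatter_t(pairs: pd.DataFrame, df: int) -> float:
    """GLM t recomputed from residualized-scatter pairs.

    For z-scored partial residuals the OLS slope equals the partial
    correlation r, and the score t of the full GLM is
    ``r sqrt(df / (1 - r^2))`` with the GLM's residual df.
    """
    r = float(np.corrcoef(pairs["score_resid"], pairs["bpnd_resid"])[0, 1])
    return r * np.sqrt(df / (1.0 - r**2))
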