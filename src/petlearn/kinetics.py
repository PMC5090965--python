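"""Reference-tissue kinetic modelling: SRTM and Logan graphical analysis.

The simplified reference tissue model (SRTM) describes a target-region
time-activity curve in terms of a reference-region curve with three
parameters: the relative delivery ``R1 = K1/K1'``, the target efflux rate
``k2`` (1/min), and the non-displaceable binding potential ``BP``.  The model
curve is

    C_t(t) = R1 C_ref(t) + (k2 - R1 k2a) [C_ref * e^{-k2a t}](t),
    k2a = k2 / (1 + BP).

Fitting uses the basis-function method: for each candidate ``k2a`` on a
log-spaced grid the model is linear in ``(R1, k2 - R1 k2a)`` and is solved by
least squares against the frame-averaged curve; the grid minimum is refined by
golden-section search.

Logan graphical analysis with a fixed reference efflux rate ``k2' = k2/R1``
regresses

    y(T) = int_0^T C_t / C_t(T)   on   x(T) = [int_0^T C_ref + C_ref(T)/k2'] / C_t(T)

over late frames (mid-time >= t*); the slope is the distribution volume ratio
(DVR) and ``BPnd = DVR - 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tac import DEFAULT_FINE_DT_S, TAC, FrameSchedule, frame_average

__all__ = [
    "KineticParams",
    "LoganFit",
    "RoiChange",
    "fit_srtm",
    "estimate_k2prime",
    "logan_ref_bpnd",
    "parametric_bpnd_image",
    "roi_percent_change",
    "percent_change_ttest",
]


@dataclass(frozen=True)
class KineticParams:
    """SRTM parameters.  Rates are per minute; ``r1`` and ``bp`` are unitless."""

    r1: float
    k2: float
    bp: float
    bp_clamped: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.r1 <= 0:
            raise ValueError("R1 must be positive")
        if self.k2 <= 0:
            raise ValueError("k2 must be positive")
        if self.bp < 0:
            raise ValueError("BP must be nonnegative")

    @property
    def k2a(self) -> float:
        """Apparent target clearance k2 / (1 + BP), 1/min."""
        return self.k2 / (1.0 + self.bp)

    @property
    def k2prime(self) -> float:
        """Reference-region efflux rate k2 / R1, 1/min."""
        return self.k2 / self.r1


@dataclass(frozen=True)
class LoganFit:
    """Result of a Logan reference-tissue fit."""

    dvr: float
    intercept: float
    t_star: float
    n_points: int
    r_squared: float

    @property
    def bpnd(self) -> float:
        return self.dvr - 1.0


@dataclass(frozen=True)
class RoiChange:
    """Pre/post ROI-mean BPnd and the percent change 100 (post - pre) / pre."""

    pre_bpnd: float
    post_bpnd: float

    @property
    def percent_change(self) -> float:
        if self.pre_bpnd == 0:
            return float("nan")
        return 100.0 * (self.post_bpnd - self.pre_bpnd) / self.pre_bpnd


def _srtm_design(ref_fine: np.ndarray, ref_frames: np.ndarray, k2a: float,
                 schedule: FrameSchedule, dt_s: float) -> np.ndarray:
    from .tac import expconv

    conv = expconv(ref_fine, k2a / 60.0, dt_s) / 60.0  # units: conc x min
    basis = frame_average(conv, schedule, dt_s)
    return np.column_stack([ref_frames, basis])


def _srtm_rss(target: np.ndarray, design: np.ndarray) -> tuple[float, np.ndarray]:
    theta, rss, *_ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ theta
    return float(resid @ resid), theta


def fit_srtm(target: TAC, ref: TAC,
             k2a_bounds: tuple[float, float] = (0.01, 1.0),
             n_grid: int = 64,
             dt_s: float = DEFAULT_FINE_DT_S) -> KineticParams:
    """Basis-function SRTM fit of a target TAC against a reference TAC.

    ``k2a`` is searched on a log-spaced grid over ``k2a_bounds`` (1/min) and
    refined by golden-section search between the neighbours of the grid
    minimum.  A negative fitted BP is clamped to zero with a warning
    (``bp_clamped`` flag set).
    """
    from scipy.optimize import minimize_scalar

    from .tac import interp_fine

    if not np.array_equal(target.schedule.durations_s, ref.schedule.durations_s):
        raise ValueError("target and reference TACs must share a frame schedule")
    if not np.any(ref.values) or not np.any(target.values):
        raise ValueError("degenerate (all-zero) TAC")

    ref_fine = interp_fine(ref, dt_s)
    y = target.values
    schedule = target.schedule

    grid = np.geomspace(k2a_bounds[0], k2a_bounds[1], n_grid)
    rss = np.array([
        _srtm_rss(y, _srtm_design(ref_fine, ref.values, k, schedule, dt_s))[0]
        for k in grid
    ])
    i = int(np.argmin(rss))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]

    def objective(log_k2a: float) -> float:
        return _srtm_rss(y, _srtm_design(ref_fine, ref.values, np.exp(log_k2a),
                                         schedule, dt_s))[0]

    if hi > lo:
        res = minimize_scalar(objective, bracket=None,
                              bounds=(np.log(lo), np.log(hi)), method="bounded",
                              options={"xatol": 1e-8})
        k2a = float(np.exp(res.x))
        best_rss = float(res.fun)
        if best_rss > rss[i]:  # refinement never worse than the grid minimum
            k2a, best_rss = float(grid[i]), float(rss[i])
    else:
        k2a = float(grid[i])

    _, theta = _srtm_rss(y, _srtm_design(ref_fine, ref.values, k2a, schedule, dt_s))
    r1 = float(theta[0])
    k2 = float(theta[1] + r1 * k2a)
    if r1 <= 0 or k2 <= 0:
        raise ValueError("SRTM fit produced nonpositive R1 or k2")
    bp = k2 / k2a - 1.0
    clamped = False
    if bp < 0:
        warnings.warn("fitted BP < 0; clamped to 0", stacklevel=2)
        bp, clamped = 0.0, True
    return KineticParams(r1=r1, k2=k2, bp=bp, bp_clamped=clamped)


def estimate_k2prime(ref: TAC, signal_rich: list[TAC],
                     combine: str = "median", **fit_kwargs) -> float:
    """Global reference efflux rate from SRTM fits of signal-rich regions.

    Each region's ``k2/R1`` is pooled by ``combine`` ("median" or "mean");
    regions whose fit fails are excluded.
    """
    if not signal_rich:
        raise ValueError("need at least one signal-rich TAC")
    vals = []
    for tac in signal_rich:
        try:
            vals.append(fit_srtm(tac, ref, **fit_kwargs).k2prime)
        except (ValueError, np.linalg.LinAlgError) as e:
            warnings.warn(f"excluding failed SRTM fit: {e}", stacklevel=2)
    if not vals:
        raise ValueError("all SRTM fits failed; cannot estimate k2'")
    pool = {"median": np.median, "mean": np.mean}[combine]
    return float(pool(vals))


def _cum_trapz_origin(vals: np.ndarray, mid_min: np.ndarray) -> np.ndarray:
    """Cumulative trapezoid of a framed curve with an implicit (0, 0) point."""
    t = np.concatenate([[0.0], mid_min])
    v = np.concatenate([[0.0], vals])
    return np.cumsum(np.diff(t) * (v[1:] + v[:-1]) / 2.0)


def logan_ref_bpnd(target: TAC, ref: TAC, k2prime: float,
                   t_star: float = 30.0) -> LoganFit:
    """Logan reference-tissue fit with fixed ``k2prime`` (1/min).

    Frames with mid-time (minutes) >= ``t_star`` enter the regression; frames
    with nonpositive target concentration are dropped with a warning.
    """
    if k2prime <= 0:
        raise ValueError("k2prime must be positive")
    if not np.array_equal(target.schedule.durations_s, ref.schedule.durations_s):
        raise ValueError("target and reference TACs must share a frame schedule")
    mid = target.schedule.mid_min
    int_t = _cum_trapz_origin(target.values, mid)
    int_r = _cum_trapz_origin(ref.values, mid)

    late = mid >= t_star
    usable = late & (target.values > 0)
    if np.any(late & ~usable):
        warnings.warn("dropping late frames with nonpositive target activity",
                      stacklevel=2)
    if usable.sum() < 3:
        raise ValueError("fewer than 3 usable frames at mid-time >= t_star")

    ct = target.values[usable]
    y = int_t[usable] / ct
    x = (int_r[usable] + ref.values[usable] / k2prime) / ct
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    ss_res = float(np.sum((y - slope * x - intercept) ** 2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LoganFit(dvr=slope, intercept=intercept, t_star=float(t_star),
                    n_points=int(usable.sum()), r_squared=r2)


def parametric_bpnd_image(dynamic, ref: TAC, k2prime: float,
                          t_star: float = 30.0, mask=None,
                          missing: float = np.nan):
    """Voxelwise Logan BPnd image from a 4D dynamic image.

    ``dynamic`` is a nibabel image or a 4D array (x, y, z, frame) on the
    reference TAC's schedule; ``mask`` restricts the computation.  Voxels
    outside the mask, and voxels whose fit fails, are set to ``missing``
    (failures are counted and reported in a warning).  Returns a nibabel image
    when the input is one, else an array.
    """
    import nibabel as nib

    is_img = hasattr(dynamic, "get_fdata")
    data = dynamic.get_fdata() if is_img else np.asarray(dynamic, dtype=float)
    if data.ndim != 4 or data.shape[3] != len(ref):
        raise ValueError("dynamic image must be 4D with one volume per frame")
    if mask is None:
        m = np.ones(data.shape[:3], dtype=bool)
    else:
        m = (mask.get_fdata() if hasattr(mask, "get_fdata") else np.asarray(mask)) > 0
        if m.shape != data.shape[:3]:
            raise ValueError("mask shape does not match image grid")

    mid = ref.schedule.mid_min
    late = mid >= t_star
    if late.sum() < 3:
        raise ValueError("fewer than 3 frames at mid-time >= t_star")
    int_r = _cum_trapz_origin(ref.values, mid)

    vox = data[m, :]                      # (V, F)
    t = np.concatenate([[0.0], mid])
    w = np.diff(t)
    int_v = np.cumsum(w * (vox + np.concatenate(
        [np.zeros((vox.shape[0], 1)), vox[:, :-1]], axis=1)) / 2.0, axis=1)

    ct = vox[:, late]
    ok = np.all(ct > 0, axis=1)
    out_vals = np.full(vox.shape[0], missing, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = int_v[:, late] / ct
        x = (int_r[late][None, :] + ref.values[late][None, :] / k2prime) / ct
        xm = x.mean(axis=1, keepdims=True)
        ym = y.mean(axis=1, keepdims=True)
        sxx = np.sum((x - xm) ** 2, axis=1)
        slope = np.sum((x - xm) * (y - ym), axis=1) / sxx
    good = ok & np.isfinite(slope) & (sxx > 0)
    out_vals[good] = slope[good] - 1.0
    n_fail = int(np.sum(~good))
    if n_fail:
        warnings.warn(f"{n_fail} in-mask voxels failed the Logan fit", stacklevel=2)

    out = np.full(data.shape[:3], missing, dtype=float)
    out[m] = out_vals
    if is_img:
        return nib.Nifti1Image(out, dynamic.affine, dtype=np.float64)
    return out


def _roi_mean(img, mask) -> float:
    data = img.get_fdata() if hasattr(img, "get_fdata") else np.asarray(img, dtype=float)
    m = (mask.get_fdata() if hasattr(mask, "get_fdata") else np.asarray(mask)) > 0
    if m.shape != data.shape:
        raise ValueError("mask shape does not match image grid")
    if not m.any():
        raise ValueError("empty ROI mask")
    return float(np.nanmean(data[m]))


def roi_percent_change(pre_img, post_img, roi_mask) -> RoiChange:
    """ROI-mean BPnd before and after, and the percent change."""
    return RoiChange(pre_bpnd=_roi_mean(pre_img, roi_mask),
                     post_bpnd=_roi_mean(post_img, roi_mask))


def percent_change_ttest(changes_a: np.ndarray, changes_b: np.ndarray):
    """Two-sample t-test between per-animal percent changes of two conditions.

    Returns ``(t, df, p)`` with ``df = n1 + n2 - 2`` (equal-variance test, as
    appropriate for small matched designs).
    """
    from scipy import stats

    a = np.asarray(changes_a, dtype=float)
    b = np.asarray(changes_b, dtype=float)
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), int(a.size + b.size - 2), float(res.pvalue)
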