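"""Generative models for reference and target time-activity curves and small
dynamic phantoms.

The reference-region input is modelled as a difference of two exponentials,
``C_ref(t) = A (e^{-l_slow t} - e^{-l_fast t})`` — smooth, nonnegative and with
closed-form frame averages.  Target-region curves follow the simplified
reference tissue model (SRTM):

    C_t(t) = R1 C_ref(t) + (k2 - R1 k2a) [C_ref * e^{-k2a t}](t),
    k2a = k2 / (1 + BP),

computed on a fine grid and averaged over each frame.  Optional Gaussian frame
noise has standard deviation ``noise_sd0 / sqrt(frame duration in s)``, a
count-statistics proxy in which longer frames are less noisy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ..kinetics import KineticParams
from ..tac import (
    DEFAULT_FINE_DT_S,
    TAC,
    FrameSchedule,
    expconv,
    fine_grid,
    frame_average,
    interp_fine,
)

__all__ = [
    "ReferenceModelParams",
    "reference_curve",
    "simulate_reference_tac",
    "srtm_curve",
    "simulate_target_tac",
    "simulate_dynamic_image",
]


@dataclass(frozen=True)
class ReferenceModelParams:
    """Difference-of-exponentials reference input.

    amplitude
        Peak scale (kBq/mL); the curve maximum is below ``amplitude``.
    lambda_fast, lambda_slow
        Uptake and washout rates (1/min), ``lambda_fast > lambda_slow > 0``.
    """

    amplitude: float = 100.0
    lambda_fast: float = 1.0
    lambda_slow: float = 0.05

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if not (self.lambda_fast > self.lambda_slow > 0):
            raise ValueError("require lambda_fast > lambda_slow > 0")


def reference_curve(params: ReferenceModelParams, t_s: np.ndarray) -> np.ndarray:
    """Instantaneous reference concentration at times ``t_s`` (seconds)."""
    t_min = np.asarray(t_s, dtype=float) / 60.0
    return params.amplitude * (
        np.exp(-params.lambda_slow * t_min) - np.exp(-params.lambda_fast * t_min)
    )


def _exp_frame_mean(lam_per_min: float, start_s: np.ndarray, dur_s: np.ndarray) -> np.ndarray:
    """Exact frame mean of exp(-lam t) (t in minutes, frames in seconds)."""
    a = start_s / 60.0
    d = dur_s / 60.0
    return (np.exp(-lam_per_min * a) - np.exp(-lam_per_min * (a + d))) / (lam_per_min * d)


def simulate_reference_tac(params: ReferenceModelParams,
                           schedule: FrameSchedule | None = None) -> TAC:
    """Analytic frame-averaged reference TAC on ``schedule`` (default 90-min)."""
    schedule = schedule or FrameSchedule.default_90min()
    s, d = schedule.start_s, schedule.durations_s
    vals = params.amplitude * (
        _exp_frame_mean(params.lambda_slow, s, d) - _exp_frame_mean(params.lambda_fast, s, d)
    )
    return TAC(schedule, vals)


def srtm_curve(ref_fine: np.ndarray, params: KineticParams, dt_s: float) -> np.ndarray:
    """Noiseless SRTM target curve on the fine grid of ``ref_fine``."""
    k2a_s = params.k2a / 60.0  # rates are per minute; the grid is in seconds
    conv = expconv(ref_fine, k2a_s, dt_s)
    return params.r1 * ref_fine + (params.k2 - params.r1 * params.k2a) / 60.0 * conv


def _ref_fine(ref, schedule: FrameSchedule, dt_s: float) -> np.ndarray:
    if isinstance(ref, ReferenceModelParams):
        return reference_curve(ref, fine_grid(schedule, dt_s))
    if isinstance(ref, TAC):
        return interp_fine(ref, dt_s)
    raise TypeError("ref must be a TAC or ReferenceModelParams")


def simulate_target_tac(ref, params: KineticParams,
                        schedule: FrameSchedule | None = None,
                        noise_sd0: float = 0.0,
                        seed: int | np.random.Generator | None = None,
                        dt_s: float = DEFAULT_FINE_DT_S) -> TAC:
    """SRTM-consistent target TAC from a reference input.

    ``ref`` may be a closed-form :class:`ReferenceModelParams` or a measured
    :class:`TAC` (linearly interpolated through the origin).  ``noise_sd0``
    sets per-frame Gaussian noise sd ``noise_sd0 / sqrt(duration_s)``.
    """
    if params.r1 <= 0 or params.k2 <= 0:
        raise ValueError("R1 and k2 must be positive")
    if params.bp < 0:
        raise ValueError("BP must be nonnegative")
    schedule = schedule or FrameSchedule.default_90min()
    curve = srtm_curve(_ref_fine(ref, schedule, dt_s), params, dt_s)
    vals = frame_average(curve, schedule, dt_s)
    if noise_sd0 > 0:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        vals = vals + rng.normal(0.0, noise_sd0 / np.sqrt(schedule.durations_s))
    return TAC(schedule, vals)


def simulate_dynamic_image(shape: tuple[int, int, int],
                           roi_masks: Mapping[str, np.ndarray],
                           kinetic_map: Mapping[str, KineticParams],
                           ref: ReferenceModelParams | TAC | None = None,
                           schedule: FrameSchedule | None = None,
                           noise_sd0: float = 0.0,
                           seed: int | np.random.Generator | None = None,
                           voxel_size_mm: float = 0.5,
                           dt_s: float = DEFAULT_FINE_DT_S):
    """Small 4D dynamic phantom with per-ROI SRTM kinetics.

    Every voxel of a named ROI follows that ROI's SRTM parameters; independent
    frame noise is added per voxel.  Voxels outside all masks stay zero.
    Returns ``(img4d, mask_imgs)`` as nibabel NIfTI-1 images with isotropic
    ``voxel_size_mm``.

    ROIs whose parameters have ``bp == 0`` and ``r1 == 1`` reproduce the
    reference curve exactly and serve as the reference region.
    """
    import nibabel as nib

    schedule = schedule or FrameSchedule.default_90min()
    ref = ref if ref is not None else ReferenceModelParams()

    names = list(roi_masks)
    if set(names) - set(kinetic_map):
        raise ValueError("kinetic_map must cover every ROI mask")
    total = np.zeros(shape, dtype=int)
    for name in names:
        m = np.asarray(roi_masks[name], dtype=bool)
        if m.shape != tuple(shape):
            raise ValueError(f"mask {name!r} shape {m.shape} != image shape {shape}")
        total += m
    if np.any(total > 1):
        raise ValueError("ROI masks overlap")

    ref_fine = _ref_fine(ref, schedule, dt_s)
    n_frames = len(schedule)
    data = np.zeros(shape + (n_frames,), dtype=np.float64)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    for name in names:
        m = np.asarray(roi_masks[name], dtype=bool)
        curve = frame_average(srtm_curve(ref_fine, kinetic_map[name], dt_s), schedule, dt_s)
        data[m, :] = curve
    if noise_sd0 > 0:
        sd = noise_sd0 / np.sqrt(schedule.durations_s)
        data += rng.normal(0.0, 1.0, size=data.shape) * sd

    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((voxel_size_mm,) * 3 + (1.0,))
    mask_imgs = {
        name: nib.Nifti1Image(np.asarray(roi_masks[name], dtype=np.uint8), affine)
        for name in names
    }
    return img, mask_imgs
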