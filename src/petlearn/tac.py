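"""Time-activity curves and PET frame schedules.

A dynamic PET acquisition is binned into frames of increasing duration; the
measured quantity per frame is the mean radioactivity concentration over the
frame (kBq/mL).  All reference-tissue modelling in :mod:`petlearn.kinetics`
and the generative models in :mod:`petlearn.synth.pet` operate on the frame
schedule through this module, and on a common fine time grid whose spacing
divides every frame duration so that frame averages are exact grid means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSchedule", "TAC", "DEFAULT_FINE_DT_S", "fine_grid", "frame_average", "expconv"]

#: Default fine-grid spacing (seconds).  Divides 10/30/60/180/600 s frames exactly.
DEFAULT_FINE_DT_S = 2.0


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered PET frame durations in seconds."""

    durations_s: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.durations_s, dtype=float)
        if d.ndim != 1 or d.size == 0:
            raise ValueError("frame durations must be a non-empty 1-D sequence")
        if not np.all(d > 0):
            raise ValueError("all frame durations must be positive")
        object.__setattr__(self, "durations_s", d)

    @classmethod
    def default_90min(cls) -> "FrameSchedule":
        """The 90-min dynamic schedule: 6x10 s, 6x30 s, 11x60 s, 15x180 s, 3x600 s."""
        d = np.concatenate([
            np.full(6, 10.0), np.full(6, 30.0), np.full(11, 60.0),
            np.full(15, 180.0), np.full(3, 600.0),
        ])
        return cls(d)

    def __len__(self) -> int:
        return int(self.durations_s.size)

    @property
    def start_s(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.durations_s)[:-1]])

    @property
    def end_s(self) -> np.ndarray:
        return np.cumsum(self.durations_s)

    @property
    def mid_s(self) -> np.ndarray:
        return self.start_s + self.durations_s / 2.0

    @property
    def mid_min(self) -> np.ndarray:
        return self.mid_s / 60.0

    @property
    def total_s(self) -> float:
        return float(np.sum(self.durations_s))


@dataclass
class TAC:
    """A framed time-activity curve: one mean concentration per frame."""

    schedule: FrameSchedule
    values: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.schedule),):
            raise ValueError(
                f"TAC has {v.size} values for {len(self.schedule)} frames"
            )
        self.values = v

    def __len__(self) -> int:
        return len(self.schedule)


def fine_grid(schedule: FrameSchedule, dt_s: float = DEFAULT_FINE_DT_S) -> np.ndarray:
    """Time points (seconds) from 0 to the scan end, spaced ``dt_s`` apart.

    ``dt_s`` must divide every frame duration so that frame boundaries fall on
    grid points; this makes frame averaging an exact trapezoid over grid cells.
    """
    rem = np.mod(schedule.durations_s, dt_s)
    if not np.allclose(np.minimum(rem, dt_s - rem), 0.0, atol=1e-9):
        raise ValueError(f"dt_s={dt_s} does not divide every frame duration")
    n = int(round(schedule.total_s / dt_s))
    return np.linspace(0.0, schedule.total_s, n + 1)


def frame_average(curve: np.ndarray, schedule: FrameSchedule,
                  dt_s: float = DEFAULT_FINE_DT_S) -> np.ndarray:
    """Trapezoid mean of a fine-grid curve over each frame."""
    t = fine_grid(schedule, dt_s)
    if curve.shape != t.shape:
        raise ValueError("curve must be sampled on fine_grid(schedule, dt_s)")
    i0 = np.rint(schedule.start_s / dt_s).astype(int)
    i1 = np.rint(schedule.end_s / dt_s).astype(int)
    out = np.empty(len(schedule))
    for j, (a, b) in enumerate(zip(i0, i1)):
        out[j] = np.trapezoid(curve[a:b + 1], dx=dt_s) / (schedule.durations_s[j])
    return out


def expconv(f: np.ndarray, k_per_s: float, dt_s: float) -> np.ndarray:
    """Trapezoidal convolution of ``f`` (on a uniform grid) with exp(-k t).

    Computed with the O(n) recursion
    ``y[i] = y[i-1] e^{-k dt} + dt/2 (f[i] + f[i-1] e^{-k dt})``,
    which is the trapezoid rule applied to each step of
    ``y(t) = \\int_0^t f(s) e^{-k (t - s)} ds``.
    """
    from scipy.signal import lfilter

    ekdt = np.exp(-k_per_s * dt_s)
    inc = dt_s / 2.0 * (f[1:] + f[:-1] * ekdt)
    y = np.empty_like(f, dtype=float)
    y[0] = 0.0
    # first-order recursion y[i] = ekdt * y[i-1] + inc[i-1], done by an IIR filter
    y[1:] = lfilter([1.0], [1.0, -ekdt], inc)
    return y


def interp_fine(tac: TAC, dt_s: float = DEFAULT_FINE_DT_S) -> np.ndarray:
    """Piecewise-linear fine-grid curve through (0, 0) and the frame mid-points.

    Used when a measured (framed) curve must serve as a continuous input, e.g.
    as the reference input of the SRTM basis functions.
    """
    t = fine_grid(tac.schedule, dt_s)
    xp = np.concatenate([[0.0], tac.schedule.mid_s])
    fp = np.concatenate([[0.0], tac.values])
    return np.interp(t, xp, fp)
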