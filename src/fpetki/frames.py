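"""Frame schedules and frame-averaging of continuous activity curves.

All times are minutes from injection; activity is kBq/mL.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous or gapped sequence of acquisition frames.

    Parameters
    ----------
    start, end : arrays of frame start/end times in minutes. Frames must be
        strictly ordered and non-overlapping.
    """

    start: np.ndarray
    end: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start, dtype=float)
        end = np.asarray(self.end, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        if start.ndim != 1 or start.shape != end.shape or start.size == 0:
            raise ValueError("start/end must be equal-length 1-D arrays")
        if np.any(end <= start):
            raise ValueError("each frame must have end > start")
        if np.any(start[1:] < end[:-1] - 1e-12):
            raise ValueError("frames must not overlap")

    @classmethod
    def uniform(cls, duration: float = 50.0, frame_length: float = 1.0) -> "FrameSchedule":
        """Equal-length frames covering [0, duration] minutes."""
        n = int(round(duration / frame_length))
        edges = np.arange(n + 1) * frame_length
        return cls(edges[:-1], edges[1:])

    @property
    def n_frames(self) -> int:
        return self.start.size

    @property
    def mid(self) -> np.ndarray:
        return 0.5 * (self.start + self.end)

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    @property
    def duration(self) -> float:
        return float(self.end[-1])

    def is_uniform(self, tol: float = 1e-9) -> bool:
        contiguous = np.allclose(self.start[1:], self.end[:-1], atol=tol)
        equal = np.ptp(self.lengths) <= tol
        return bool(contiguous and equal)

    @property
    def frame_length(self) -> float:
        if not self.is_uniform():
            raise ValueError("frame_length is only defined for uniform schedules")
        return float(self.lengths[0])

    def average(self, t: np.ndarray, c: np.ndarray) -> np.ndarray:
        """Average an instantaneous curve ``c(t)`` over each frame interval.

        Uses the trapezoid cumulative integral of the (piecewise-linear)
        curve, so the conservation identity
        ``sum(average * lengths) == trapz(c, t)`` holds exactly when the
        frame edges coincide with the span of ``t``.
        """
        t = np.asarray(t, dtype=float)
        c = np.asarray(c, dtype=float)
        if t[0] > self.start[0] + 1e-9 or t[-1] < self.end[-1] - 1e-9:
            raise ValueError("frame schedule extends beyond the sampled grid")
        from scipy.integrate import cumulative_trapezoid

        integral = np.concatenate(([0.0], cumulative_trapezoid(c, t)))
        lo = np.interp(self.start, t, integral)
        hi = np.interp(self.end, t, integral)
        return (hi - lo) / self.lengths


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-averaged radioactivity concentration for one region or voxel."""

    frames: FrameSchedule
    activity: np.ndarray  # kBq/mL, one value per frame
    name: str = ""

    def __post_init__(self) -> None:
        activity = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "activity", activity)
        if activity.shape != (self.frames.n_frames,):
            raise ValueError("activity must have one value per frame")
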