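"""General linear model separating task uptake from baseline synthesis.

Each (metabolite-corrected) TAC is modelled as a weighted sum of

* one ramp-and-hold regressor per task block (slope exactly 1 kBq per frame
  inside the block, 0 before, held at its end-of-block value afterwards —
  trapped activity persists under irreversible kinetics),
* a baseline regressor (average time course of the non-excluded gray-matter
  series), and
* a head-motion regressor (first principal component of the six rigid-body
  motion parameters).

No orthogonalization is applied; collinearity is surfaced through the
design's condition number. Filtering and fitting are both linear, so
applying the same low-pass filter to data and design leaves the
coefficients of noise-free signal unchanged.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .frames import FrameSchedule
from .types import TaskSchedule

__all__ = [
    "lowpass_filter",
    "build_baseline_regressor",
    "motion_regressor",
    "GlmDesign",
    "GlmFit",
    "fit_glm",
    "adjust_tac",
]


def lowpass_filter(
    y: np.ndarray,
    frame_length: float | FrameSchedule,
    cutoff_period: float = 2.5,
) -> np.ndarray:
    """Zero-phase low-pass filter with half-power at ``cutoff_period`` minutes.

    FFT-domain raised-cosine amplitude response: unity below 0.818*f_c,
    zero above 1.318*f_c, half-power (1/sqrt(2)) exactly at the cutoff
    frequency f_c = 1/cutoff_period. The series is mirror-padded to its own
    length on both sides before the FFT, and the whole operation is linear.
    Requires uniform sampling; DC gain is exactly 1.
    """
    if isinstance(frame_length, FrameSchedule):
        if not frame_length.is_uniform():
            raise ValueError("low-pass filtering requires a uniform frame schedule")
        dt = frame_length.frame_length
    else:
        dt = float(frame_length)
    y = np.asarray(y, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples to filter")
    pad = n - 1
    padded = np.concatenate([y[pad:0:-1], y, y[-2 : -pad - 2 : -1]], axis=0)
    freqs = np.fft.rfftfreq(padded.shape[0], d=dt)
    fc = 1.0 / cutoff_period
    # raised-cosine transition of width fc/2 positioned so |H(fc)|^2 = 1/2
    width = 0.5 * fc
    x_half = np.arccos(2.0 * np.sqrt(0.5) - 1.0) / np.pi  # ~0.364
    f1 = fc - x_half * width
    f2 = f1 + width
    H = np.ones_like(freqs)
    rolloff = (freqs > f1) & (freqs < f2)
    H[rolloff] = 0.5 * (1.0 + np.cos(np.pi * (freqs[rolloff] - f1) / width))
    H[freqs >= f2] = 0.0
    out = np.fft.irfft(np.fft.rfft(padded, axis=0) * H[:, None], n=padded.shape[0], axis=0)
    out = out[pad : pad + n]
    return out[:, 0] if squeeze else out


def build_baseline_regressor(
    tacs: dict[str, np.ndarray],
    exclude: set[str] | frozenset[str] | list[str] = (),
) -> np.ndarray:
    """Unweighted mean time course of all non-excluded gray-matter series."""
    exclude = set(exclude)
    keep = [name for name in tacs if name not in exclude]
    if not keep:
        raise ValueError("no series left after applying the exclusion mask")
    return np.mean([np.asarray(tacs[name], dtype=float) for name in keep], axis=0)


def motion_regressor(motion: np.ndarray) -> np.ndarray:
    """First principal component of the six rigid-body motion parameters.

    Columns are centered; the sign is fixed so the component correlates
    positively with the highest-variance column. Constant (zero-variance)
    motion yields a zero regressor with a warning.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must have six columns")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames of motion parameters")
    centered = motion - motion.mean(axis=0)
    if np.allclose(centered, 0.0):
        warnings.warn("constant motion parameters; motion regressor is zero")
        return np.zeros(motion.shape[0])
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    pc1 = u[:, 0] * s[0]
    dominant = int(np.argmax(centered.var(axis=0)))
    if np.dot(pc1, centered[:, dominant]) < 0:
        pc1 = -pc1
    return pc1


def task_ramp(frames: FrameSchedule, onset: float, duration: float) -> np.ndarray:
    """Ramp-and-hold regressor: slope 1 (kBq) per frame inside the block.

    Defined as the frame average of the continuous unit-rate ramp
    min(max(t-onset, 0), duration), expressed in frames, so it registers
    exactly with frame-averaged data.
    """
    if not frames.is_uniform():
        raise ValueError("task ramps assume a uniform frame schedule")
    flen = frames.frame_length

    def ramp_integral(t: np.ndarray) -> np.ndarray:
        # integral of min(max(t-onset,0),duration) from 0 to t
        u = np.clip(t - onset, 0.0, duration)
        return 0.5 * u**2 + duration * np.clip(t - onset - duration, 0.0, None)

    avg = (ramp_integral(frames.end) - ramp_integral(frames.start)) / frames.lengths
    return avg / flen


@dataclass(frozen=True)
class GlmDesign:
    """Design matrix with named columns (task_1..task_B, baseline, motion)."""

    matrix: np.ndarray
    names: tuple[str, ...]
    frames: FrameSchedule
    task: TaskSchedule

    @classmethod
    def build(
        cls,
        frames: FrameSchedule,
        task: TaskSchedule,
        baseline: np.ndarray,
        motion: np.ndarray | None = None,
    ) -> "GlmDesign":
        baseline = np.asarray(baseline, dtype=float)
        if baseline.shape != (frames.n_frames,):
            raise ValueError("baseline regressor must have one value per frame")
        cols = []
        names = []
        for j in range(task.n_blocks):
            onset, _ = task.block_interval(j)
            cols.append(task_ramp(frames, onset, task.duration))
            names.append(f"task_{j + 1}")
        cols.append(baseline)
        names.append("baseline")
        if motion is not None:
            motion = np.asarray(motion, dtype=float)
            if motion.shape != (frames.n_frames,):
                raise ValueError("motion regressor must have one value per frame")
            cols.append(motion)
            names.append("motion")
        return cls(matrix=np.column_stack(cols), names=tuple(names), frames=frames, task=task)

    @property
    def n_task(self) -> int:
        return sum(1 for n in self.names if n.startswith("task_"))

    @property
    def condition_number(self) -> float:
        # ignore all-zero columns (e.g. zero-motion sessions) for conditioning
        m = self.matrix
        live = m[:, np.ptp(m, axis=0) > 0] if np.any(np.ptp(m, axis=0) > 0) else m
        return float(np.linalg.cond(live))

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


@dataclass(frozen=True)
class GlmFit:
    """OLS fit of one TAC: coefficients and per-column signal components."""

    design: GlmDesign
    beta: np.ndarray
    fitted_tac: np.ndarray

    @property
    def components(self) -> np.ndarray:
        return self.design.matrix * self.beta

    def component(self, name: str) -> np.ndarray:
        i = self.design.names.index(name)
        return self.design.matrix[:, i] * self.beta[i]

    @property
    def residual(self) -> np.ndarray:
        return self.fitted_tac - self.design.matrix @ self.beta

    @property
    def residual_variance(self) -> float:
        r = self.residual
        dof = max(r.size - self.design.matrix.shape[1], 1)
        return float(r @ r / dof)

    def beta_of(self, name: str) -> float:
        return float(self.beta[self.design.names.index(name)])

    @property
    def task_betas(self) -> np.ndarray:
        return np.array([self.beta_of(f"task_{j + 1}") for j in range(self.design.n_task)])


def fit_glm(tac: np.ndarray, design: GlmDesign, rank_tol: float = 1e-10) -> GlmFit:
    """Ordinary least squares of a (filtered) TAC on the design matrix."""
    y = np.asarray(tac, dtype=float)
    X = design.matrix
    if y.shape != (X.shape[0],):
        raise ValueError("TAC length must match the design")
    live = np.ptp(X, axis=0) > 0
    scale = np.where(live, np.abs(X).max(axis=0), 1.0)
    rank = np.linalg.matrix_rank(X[:, live] / scale[live], tol=rank_tol)
    if rank < int(np.sum(live)):
        raise ValueError("design matrix is rank-deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return GlmFit(design=design, beta=beta, fitted_tac=y)


def adjust_tac(
    tac: np.ndarray,
    fit: GlmFit,
    remove: tuple[str, ...] = ("task", "motion"),
) -> np.ndarray:
    """Subtract the fitted task and/or motion components from a TAC."""
    out = np.asarray(tac, dtype=float).copy()
    for name in fit.design.names:
        kind = "task" if name.startswith("task_") else name
        if kind in remove:
            out -= fit.component(name)
    return out
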