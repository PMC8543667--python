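"""Gjedde-Patlak graphical analysis and condition-level net influx.

For an irreversibly trapped tracer the normalized plot

    x(t) = int_0^t Cp dtau / Cp(t)    [min]
    y(t) = C_tissue(t) / Cp(t)        [dimensionless]

becomes linear once the reversible compartments equilibrate; the slope is
the net influx constant Ki = K1*k3/(k2+k3). Task-specific influx is
obtained from the GLM uptake-slope coefficients (kBq/mL per frame) by
dividing by the frame length times the mean parent plasma over the block;
an equivalent construction via the Patlak slope of the baseline plus an
extended task ramp is provided as a cross-check.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .frames import FrameSchedule
from .glm import GlmFit, task_ramp
from .types import InputFunctionSet, TaskSchedule

__all__ = [
    "patlak_transform",
    "PatlakResult",
    "fit_ki",
    "task_ki",
    "task_ki_patlak_difference",
    "ConditionKi",
    "weight_and_average",
    "percent_signal_change",
]


def _parent_on_mid(inputs: InputFunctionSet, mids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cp = np.interp(mids, inputs.t, inputs.parent)
    integral = np.concatenate(
        ([0.0], cumulative_trapezoid(inputs.parent, inputs.t))
    )
    cp_int = np.interp(mids, inputs.t, integral)
    return cp, cp_int


def patlak_transform(
    tac: np.ndarray,
    frames: FrameSchedule,
    inputs: InputFunctionSet,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized-time / normalized-activity series at the frame midpoints.

    The plasma integral uses the trapezoid rule on the input grid.
    """
    tac = np.asarray(tac, dtype=float)
    if tac.shape != (frames.n_frames,):
        raise ValueError("TAC length must match the frame schedule")
    mids = frames.mid
    cp, cp_int = _parent_on_mid(inputs, mids)
    if np.any(cp <= 0):
        raise ValueError("parent plasma must be positive at every frame midpoint")
    return cp_int / cp, tac / cp


@dataclass(frozen=True)
class PatlakResult:
    ki: float  # 1/min
    intercept: float
    t_star: float
    n_points: int
    r_squared: float


def fit_ki(
    x: np.ndarray,
    y: np.ndarray,
    t_mid: np.ndarray,
    t_star: float = 25.0,
) -> PatlakResult:
    """OLS slope/intercept over the points with frame midpoint >= t_star."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t_mid = np.asarray(t_mid, dtype=float)
    mask = t_mid >= t_star - 1e-12
    if int(mask.sum()) < 3:
        raise ValueError("need at least 3 frames past t_star for the Patlak fit")
    xs, ys = x[mask], y[mask]
    A = np.column_stack([xs, np.ones_like(xs)])
    (slope, intercept), *_ = np.linalg.lstsq(A, ys, rcond=None)
    fitted = A @ np.array([slope, intercept])
    ss_res = float(np.sum((ys - fitted) ** 2))
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PatlakResult(
        ki=float(slope),
        intercept=float(intercept),
        t_star=float(t_star),
        n_points=int(mask.sum()),
        r_squared=r2,
    )


def _mean_parent_over_block(inputs: InputFunctionSet, lo: float, hi: float) -> float:
    mask = (inputs.t >= lo) & (inputs.t <= hi)
    if mask.sum() < 2:
        raise ValueError("input grid too coarse over the task block")
    return float(np.trapezoid(inputs.parent[mask], inputs.t[mask]) / (hi - lo))


def task_ki(
    glm_fit: GlmFit,
    inputs: InputFunctionSet,
    task: TaskSchedule | None = None,
) -> np.ndarray:
    """Per-block task net influx from the GLM uptake-slope coefficients.

    Ki_j = beta_j / (frame_length * mean parent plasma over block j), which
    converts the fitted within-block uptake slope (kBq/mL per frame) into
    an influx constant (1/min).
    """
    task = task or glm_fit.design.task
    frames = glm_fit.design.frames
    flen = frames.frame_length
    out = np.empty(task.n_blocks)
    for j in range(task.n_blocks):
        lo, hi = task.block_interval(j)
        cp_bar = _mean_parent_over_block(inputs, lo, hi)
        if cp_bar <= 0:
            raise ValueError("mean parent plasma over the block must be positive")
        out[j] = glm_fit.task_betas[j] / (flen * cp_bar)
    return out


def task_ki_patlak_difference(
    glm_fit: GlmFit,
    inputs: InputFunctionSet,
    t_star: float = 25.0,
) -> np.ndarray:
    """Cross-check: task influx as a Patlak-slope difference.

    For each block the fitted uptake slope is re-expressed as a ramp
    covering the whole scan (as if the block's uptake-rate change applied
    throughout), the Patlak slope of baseline + extended ramp is computed,
    and the baseline slope subtracted. Under a near-flat parent plasma
    curve this coincides with the beta-conversion rule.
    """
    design = glm_fit.design
    frames = design.frames
    task = design.task
    baseline_comp = glm_fit.component("baseline")
    x, y_base = patlak_transform(baseline_comp, frames, inputs)
    base = fit_ki(x, y_base, frames.mid, t_star=t_star)
    extended = task_ramp(frames, 0.0, frames.end[-1])
    out = np.empty(task.n_blocks)
    for j in range(task.n_blocks):
        comp = baseline_comp + glm_fit.task_betas[j] * extended
        _, y = patlak_transform(comp, frames, inputs)
        out[j] = fit_ki(x, y, frames.mid, t_star=t_star).ki - base.ki
    return out


@dataclass(frozen=True)
class ConditionKi:
    """Baseline and condition-level net influx with performance weighting."""

    ki_baseline: float
    ki_blocks: tuple[float, ...]
    weights: tuple[float, ...]
    conditions: tuple[str, ...]
    ki_gain: float
    ki_loss: float
    ki_gain_unweighted: float
    ki_loss_unweighted: float

    @property
    def psc_gain(self) -> float:
        return percent_signal_change(self.ki_gain, self.ki_baseline)

    @property
    def psc_loss(self) -> float:
        return percent_signal_change(self.ki_loss, self.ki_baseline)

    @property
    def psc_diff(self) -> float:
        return percent_signal_change(self.ki_gain - self.ki_loss, self.ki_baseline)


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    if np.all(weights == 0):
        raise ValueError("all-zero performance weights in a condition")
    return float(np.sum(values * weights) / np.sum(weights))


def weight_and_average(
    ki_blocks: np.ndarray,
    conditions: tuple[str, ...],
    weights: np.ndarray,
    ki_baseline: float,
) -> ConditionKi:
    """Weight per-block task Ki by task performance and average per condition."""
    ki_blocks = np.asarray(ki_blocks, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not (len(conditions) == ki_blocks.size == weights.size):
        raise ValueError("blocks, conditions and weights must align")
    if np.any((weights < 0) | (weights > 1)):
        raise ValueError("weights must lie in [0, 1]")
    out = {}
    for cond in ("gain", "loss"):
        idx = [j for j, c in enumerate(conditions) if c == cond]
        if idx:
            out[cond] = _weighted_mean(ki_blocks[idx], weights[idx])
            out[cond + "_u"] = float(np.mean(ki_blocks[idx]))
        else:
            out[cond] = float("nan")
            out[cond + "_u"] = float("nan")
    return ConditionKi(
        ki_baseline=float(ki_baseline),
        ki_blocks=tuple(float(v) for v in ki_blocks),
        weights=tuple(float(w) for w in weights),
        conditions=tuple(conditions),
        ki_gain=out["gain"],
        ki_loss=out["loss"],
        ki_gain_unweighted=out["gain_u"],
        ki_loss_unweighted=out["loss_u"],
    )


def percent_signal_change(ki_task: float, ki_baseline: float) -> float:
    """Task-specific change expressed relative to baseline: Ki_task/Ki_baseline*100."""
    if ki_baseline <= 0:
        raise ValueError("baseline Ki must be positive for percent signal change")
    return float(ki_task / ki_baseline * 100.0)
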