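"""Tissue time-activity simulation with task-modulated trapping.

The measured signal follows the measurement equation used throughout the
package:

    measured(t) = (1 - vB) * (C_free + C_trapped + C_omfd)(t) + vB * C_wb(t)

where the parent tracer follows the irreversible two-tissue model with a
piecewise-constant trapping rate (baseline k3 plus the per-block task
deltas) and the 3-OMFD metabolite contributes a one-tissue component driven
by the metabolite plasma curve with brain-wide uniform kinetics.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..frames import FrameSchedule, TimeActivityCurve
from ..kinetics import conv_1tc, solve_2tc_irreversible
from ..types import InputFunctionSet, KineticParams, TaskSchedule

#: default metabolite (3-OMFD) brain kinetics, uniform across regions.
DEFAULT_METABOLITE_KINETICS: tuple[float, float] = (0.06, 0.05)  # K1m, k2m


@dataclass(frozen=True)
class TacTruth:
    """Ground truth recorded alongside a simulated TAC."""

    ki_baseline: float
    ki_blocks: tuple[float, ...]  # net-influx increment per task block
    parent_tissue: np.ndarray  # (1-vB)*(free+trapped), frame-averaged
    omfd_tissue: np.ndarray  # metabolite tissue component, frame-averaged
    noise_free: np.ndarray  # frame-averaged measured signal without noise
    seed: int | None = None


def _require_frames_within(frames: FrameSchedule, inputs: InputFunctionSet) -> None:
    if frames.start[0] < inputs.t[0] - 1e-9 or frames.end[-1] > inputs.t[-1] + 1e-9:
        raise ValueError("frame schedule extends beyond the input-function grid")


def simulate_tac(
    params: KineticParams,
    inputs: InputFunctionSet,
    task: TaskSchedule | None = None,
    frames: FrameSchedule | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    metabolite_kinetics: tuple[float, float] = DEFAULT_METABOLITE_KINETICS,
    name: str = "",
) -> tuple[TimeActivityCurve, TacTruth]:
    """Simulate one region's measured TAC plus its ground truth.

    The input grid is used as the integration grid, so pass the generator's
    fine (1 s) grid for oracle-quality solutions.
    """
    frames = frames or FrameSchedule.uniform()
    task = task or TaskSchedule(onsets=(), conditions=())
    _require_frames_within(frames, inputs)
    task.validate_within(inputs.t[-1] + 1e-9)

    t = inputs.t
    seg_mid = 0.5 * (t[:-1] + t[1:])
    k3_seg = task.k3_series(seg_mid, params.k3, params.task_k3_delta)
    if np.any(k3_seg < 0):
        raise ValueError("task_k3_delta drives k3 negative inside a block")

    c1, c2 = solve_2tc_irreversible(t, inputs.parent, params.K1, params.k2, k3_seg)
    K1m, k2m = metabolite_kinetics
    c_omfd = conv_1tc(t, inputs.metabolite, K1m, k2m)

    tissue = c1 + c2 + c_omfd
    measured = (1.0 - params.vB) * tissue + params.vB * inputs.whole_blood

    fa = frames.average
    parent_tissue = (1.0 - params.vB) * fa(t, c1 + c2)
    omfd_frames = fa(t, c_omfd)
    noise_free = fa(t, measured)

    activity = noise_free
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        activity = noise_free + rng.normal(0.0, noise_sd, size=noise_free.shape)

    ki_blocks = tuple(
        params.ki_with_delta(dict(params.task_k3_delta).get(j, 0.0)) - params.ki
        for j in range(task.n_blocks)
    )
    truth = TacTruth(
        ki_baseline=params.ki,
        ki_blocks=ki_blocks,
        parent_tissue=parent_tissue,
        omfd_tissue=omfd_frames,
        noise_free=noise_free,
        seed=seed,
    )
    return TimeActivityCurve(frames=frames, activity=activity, name=name), truth


def simulate_reference_tac(
    params: KineticParams,
    inputs: InputFunctionSet,
    frames: FrameSchedule | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    metabolite_kinetics: tuple[float, float] = DEFAULT_METABOLITE_KINETICS,
    name: str = "reference",
) -> tuple[TimeActivityCurve, TacTruth]:
    """Reference-region TAC: trapping disabled (k3 must be 0)."""
    if params.k3 != 0.0 or params.task_k3_delta:
        raise ValueError("reference region must have k3 = 0 and no task modulation")
    return simulate_tac(
        params,
        inputs,
        task=None,
        frames=frames,
        noise_sd=noise_sd,
        seed=seed,
        metabolite_kinetics=metabolite_kinetics,
        name=name,
    )
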