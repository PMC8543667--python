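"""Whole-session synthesis: blood, tissue, motion and behavior together.

A session bundles everything the quantification pipeline consumes, plus a
ground-truth record for recovery testing. All randomness derives from one
seed, so sessions are bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..config import RunConfig
from ..frames import FrameSchedule
from ..kinetics import internal_grid
from ..types import InputFunctionSet, KineticParams, TaskSchedule
from .blood_model import make_input_functions, metabolite_bolus_fraction
from .mid import MidTrial, simulate_mid_session
from .tac import TacTruth, simulate_reference_tac, simulate_tac

# mnemonic offsets deriving per-component substreams from the session seed
_TAC_SEED, _MOTION_SEED, _MID_SEED = 101, 211, 307


@dataclass
class SyntheticSession:
    """In-memory synthetic session with recorded ground truth."""

    config: RunConfig
    frames: FrameSchedule
    task: TaskSchedule
    inputs: InputFunctionSet  # true input functions on the fine grid
    tacs: dict[str, np.ndarray]  # measured (possibly noisy) TACs
    truths: dict[str, TacTruth]
    motion: np.ndarray  # n_frames x 6
    trials: list[MidTrial]
    f_bolus: np.ndarray  # pure-bolus metabolite fraction on inputs.t

    @property
    def reference_name(self) -> str:
        return self.config.reference_name


# alias kept for API symmetry with the run configuration
SimulationSpec = RunConfig


def simulate_session(config: RunConfig | None = None, seed: int | None = None) -> SyntheticSession:
    """Generate a full synthetic session from a run configuration."""
    config = config or RunConfig()
    if seed is None:
        seed = config.seed
    frames = config.frames.build()
    task = config.task.build()
    schedule = config.administration.build()
    blood = config.blood_model.build()

    t = internal_grid(schedule.scan_duration)
    inputs = make_input_functions(schedule, blood, t)
    f_bolus = metabolite_bolus_fraction(blood, t)

    tacs: dict[str, np.ndarray] = {}
    truths: dict[str, TacTruth] = {}
    for i, region in enumerate(config.regions):
        region_seed = seed + _TAC_SEED + i
        if region.role == "reference":
            params = KineticParams(K1=region.K1, k2=region.k2, k3=0.0, vB=config.quant.vB)
            tac, truth = simulate_reference_tac(
                params,
                inputs,
                frames,
                noise_sd=config.noise_sd,
                seed=region_seed,
                metabolite_kinetics=config.metabolite_kinetics,
                name=region.name,
            )
        else:
            from ..types import k3_for_ki

            params = KineticParams(
                K1=region.K1,
                k2=region.k2,
                k3=k3_for_ki(region.K1, region.k2, region.ki_baseline),
                vB=config.quant.vB,
            )
            if region.task_ki:
                block_ki = {
                    j: region.task_ki[c]
                    for j, c in enumerate(task.conditions)
                    if c in region.task_ki
                }
                params = params.with_task_ki(block_ki)
            tac, truth = simulate_tac(
                params,
                inputs,
                task,
                frames,
                noise_sd=config.noise_sd,
                seed=region_seed,
                metabolite_kinetics=config.metabolite_kinetics,
                name=region.name,
            )
        tacs[region.name] = tac.activity
        truths[region.name] = truth

    rng = np.random.default_rng(seed + _MOTION_SEED)
    motion = rng.normal(0.0, config.motion_sd, size=(frames.n_frames, 6))

    trials = simulate_mid_session(
        rt_model=config.mid.rt_model(),
        n_blocks=task.n_blocks,
        trials_per_block=config.mid.trials_per_block,
        staircase_step=config.mid.staircase_step,
        initial_limit=config.mid.initial_limit,
        manipulation_bias=config.mid.manipulation_bias,
        conditions=task.conditions,
        amounts=config.mid.amounts,
        rt_noise_sd=config.mid.rt_noise_sd,
        seed=seed + _MID_SEED,
    )
    return SyntheticSession(
        config=config,
        frames=frames,
        task=task,
        inputs=inputs,
        tacs=tacs,
        truths=truths,
        motion=motion,
        trials=trials,
        f_bolus=f_bolus,
    )


def write_session(session: SyntheticSession, out_dir: str | Path) -> Path:
    """Write a session to disk in the package's tabular formats.

    Blood samples are written at the configured sampling interval; the
    pure-bolus metabolite fraction table and the ground-truth JSON sidecar
    accompany them.
    """
    from .. import io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = session.config

    io.write_tac_table(out / "tacs.tsv", session.frames, session.tacs)

    ts = np.arange(0.0, session.inputs.t[-1] + 1e-9, cfg.blood_sample_interval)
    wb = np.interp(ts, session.inputs.t, session.inputs.whole_blood)
    plasma = np.interp(ts, session.inputs.t, session.inputs.total_plasma)
    io.write_blood_table(out / "blood.tsv", ts, wb, plasma)

    io.write_motion_table(out / "motion.tsv", session.motion)
    io.write_trial_log(out / "trials.csv", session.trials)

    # subsample the fraction curve for a compact file; it is smooth
    sub = slice(None, None, 10)
    io.write_curve_table(
        out / "metabolite_bolus_fraction.tsv",
        session.inputs.t[sub],
        session.f_bolus[sub],
        "omfd_fraction",
    )

    truth_payload = {
        name: {
            "ki_baseline": tr.ki_baseline,
            "ki_blocks": list(tr.ki_blocks),
            "seed": tr.seed,
        }
        for name, tr in session.truths.items()
    }
    io.write_json(out / "truth.json", truth_payload)
    cfg.to_file(out / "config.yaml")
    return out
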