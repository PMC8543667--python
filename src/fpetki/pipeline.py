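"""End-to-end quantification: blood -> metabolite correction -> GLM -> Patlak.

`run_quantification` is deterministic given its inputs and configuration
(no random numbers are drawn anywhere in the pipeline), and every output
carries the configuration hash for provenance.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import io
from .blood import BloodSamples, adapt_metabolite_fraction, assemble_input_functions, fit_plasma_ratio
from .config import RunConfig
from .frames import FrameSchedule
from .glm import GlmDesign, GlmFit, build_baseline_regressor, fit_glm, lowpass_filter, motion_regressor, task_ramp
from .metabolite import ReferenceOneTissueModel, OneTissueFit, correct_tacs, estimate_omfd_tissue, tissue_fraction
from .patlak import (
    ConditionKi,
    PatlakResult,
    fit_ki,
    patlak_transform,
    task_ki,
    task_ki_patlak_difference,
    weight_and_average,
)
from .types import InputFunctionSet, TaskSchedule


@dataclass
class SessionInputs:
    """Everything the quantification consumes, loaded or passed in memory."""

    frames: FrameSchedule
    tacs: dict[str, np.ndarray]
    blood: BloodSamples
    motion: np.ndarray
    trials: pd.DataFrame
    f_bolus: tuple[np.ndarray, np.ndarray]  # (time_min, fraction)


def load_session(session_dir: str | Path) -> SessionInputs:
    d = Path(session_dir)
    frames, tacs = io.read_tac_table(d / "tacs.tsv")
    blood = io.read_blood_table(d / "blood.tsv")
    motion = io.read_motion_table(d / "motion.tsv")
    trials = io.read_trial_log(d / "trials.csv")
    f_bolus = io.read_curve_table(d / "metabolite_bolus_fraction.tsv")
    return SessionInputs(frames=frames, tacs=tacs, blood=blood, motion=motion, trials=trials, f_bolus=f_bolus)


def session_inputs_from_synthetic(session) -> SessionInputs:
    """Adapt an in-memory synthetic session, sampling blood like the writer."""
    cfg = session.config
    ts = np.arange(0.0, session.inputs.t[-1] + 1e-9, cfg.blood_sample_interval)
    blood = BloodSamples(
        time=ts,
        whole_blood=np.interp(ts, session.inputs.t, session.inputs.whole_blood),
        plasma=np.interp(ts, session.inputs.t, session.inputs.total_plasma),
    )
    trials = pd.DataFrame([dataclasses.asdict(tr) for tr in session.trials])
    return SessionInputs(
        frames=session.frames,
        tacs=dict(session.tacs),
        blood=blood,
        motion=session.motion,
        trials=trials,
        f_bolus=(session.inputs.t, session.f_bolus),
    )


def performance_weights(trials: pd.DataFrame, task: TaskSchedule) -> np.ndarray:
    """Per-block task-performance weights from the trial log.

    Gain blocks: actual gain / possible gain; loss blocks: amount avoided /
    maximum avoidable.
    """
    weights = np.zeros(task.n_blocks)
    for j in range(task.n_blocks):
        rows = trials[trials["block"] == j]
        if rows.empty:
            raise ValueError(f"trial log has no trials for block {j}")
        possible = rows["amount"].abs().sum()
        if possible <= 0:
            raise ValueError(f"block {j} has zero possible amount")
        if task.conditions[j] == "gain":
            actual = rows["balance_delta"].sum()
        else:
            actual = rows.loc[rows["hit"].astype(bool), "amount"].abs().sum()
        weights[j] = actual / possible
    return np.clip(weights, 0.0, 1.0)


@dataclass
class RegionResult:
    name: str
    condition_ki: ConditionKi
    patlak_baseline: PatlakResult
    task_ki_blocks: np.ndarray
    task_ki_patlak: np.ndarray
    glm: GlmFit


@dataclass
class QuantResults:
    regions: dict[str, RegionResult]
    ref_fit: OneTissueFit
    inputs: InputFunctionSet
    metabolite_auc_reduction: float
    qc: dict
    provenance: dict


def run_quantification(inputs: SessionInputs, config: RunConfig | None = None) -> QuantResults:
    config = config or RunConfig()
    frames = inputs.frames
    task = config.task.build()
    quant = config.quant
    schedule = config.administration.build()

    # --- input functions --------------------------------------------------
    grid = np.arange(0.0, frames.duration + quant.grid_dt / 2, quant.grid_dt)
    ratio = fit_plasma_ratio(inputs.blood)
    fb_t, fb_v = inputs.f_bolus
    f_bolus = lambda t: np.interp(t, fb_t, fb_v)  # noqa: E731
    blood_model = config.blood_model.build()
    f_bi, auc_reduction = adapt_metabolite_fraction(
        f_bolus, schedule, grid, total_bolus_response=blood_model.total_bolus
    )
    ifs = assemble_input_functions(
        inputs.blood, ratio, f_bi, grid, extrapolation_margin=quant.extrapolation_margin
    )

    # --- nuisance regressors ---------------------------------------------
    def F(a: np.ndarray) -> np.ndarray:
        return lowpass_filter(a, frames.frame_length, quant.cutoff_period)

    motion_pc = motion_regressor(inputs.motion)
    ramps = np.column_stack(
        [task_ramp(frames, task.block_interval(j)[0], task.duration) for j in range(task.n_blocks)]
    )

    # --- reference fit and metabolite correction --------------------------
    ref_name = config.reference_name
    if ref_name not in inputs.tacs:
        raise ValueError(f"reference region {ref_name!r} missing from TAC table")
    nuisance = np.column_stack([ramps, motion_pc[:, None]])
    ref_model = ReferenceOneTissueModel(vB=quant.vB)
    ref_model.fit(F(inputs.tacs[ref_name]), frames, ifs, nuisance=F(nuisance))
    ref_fit = ref_model.result()
    omfd = estimate_omfd_tissue(ref_fit, ifs, frames)

    wb_frames = frames.average(grid, ifs.whole_blood)
    brain = {name: tac for name, tac in inputs.tacs.items() if name != ref_name}
    corrected = correct_tacs(brain, omfd, quant.vB)
    n_neg = sum(int(np.sum(v < 0)) for v in corrected.values())
    tissue = {name: tissue_fraction(v, wb_frames, quant.vB) for name, v in corrected.items()}

    # --- GLM and Patlak per target region ----------------------------------
    gray = {n: tissue[n] for n in config.gray_names if n in tissue}
    baseline = build_baseline_regressor(gray, exclude=set(config.exclusion))
    weights = performance_weights(inputs.trials, task)

    regions: dict[str, RegionResult] = {}
    qc_regions = {}
    for name in config.target_names:
        if name not in tissue:
            raise ValueError(f"target region {name!r} missing from TAC table")
        design = GlmDesign.build(frames, task, baseline, motion_pc)
        designF = dataclasses.replace(design, matrix=F(design.matrix))
        fit = fit_glm(F(tissue[name]), designF)
        ki_blocks = task_ki(fit, ifs, task)
        ki_patlak = task_ki_patlak_difference(fit, ifs, t_star=quant.t_star)
        x, y = patlak_transform(fit.component("baseline"), frames, ifs)
        pat = fit_ki(x, y, frames.mid, t_star=quant.t_star)
        cond = weight_and_average(ki_blocks, task.conditions, weights, pat.ki)
        regions[name] = RegionResult(
            name=name,
            condition_ki=cond,
            patlak_baseline=pat,
            task_ki_blocks=ki_blocks,
            task_ki_patlak=ki_patlak,
            glm=fit,
        )
        qc_regions[name] = {
            "betas": dict(zip(fit.design.names, fit.beta)),
            "condition_number": designF.condition_number,
            "residual_variance": fit.residual_variance,
            "patlak_r_squared": pat.r_squared,
        }

    qc = {
        "reference_fit": {
            "K1": ref_fit.K1,
            "k2": ref_fit.k2,
            "residual_rms": ref_fit.residual_rms,
            "converged": ref_fit.converged,
        },
        "plasma_ratio": {"intercept": ratio.intercept, "slope": ratio.slope},
        "metabolite_auc_reduction_pct": auc_reduction,
        "negative_corrected_values": n_neg,
        "performance_weights": weights.tolist(),
        "regions": qc_regions,
    }
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "fpetki_version": _pkg_version,
        "numpy_version": np.__version__,
    }
    return QuantResults(
        regions=regions,
        ref_fit=ref_fit,
        inputs=ifs,
        metabolite_auc_reduction=auc_reduction,
        qc=qc,
        provenance=provenance,
    )


def results_table(results: QuantResults) -> pd.DataFrame:
    rows = []
    for name, rr in results.regions.items():
        c = rr.condition_ki
        row = {
            "region": name,
            "Ki_baseline": c.ki_baseline,
            "Ki_gain": c.ki_gain,
            "Ki_loss": c.ki_loss,
            "Ki_gain_unweighted": c.ki_gain_unweighted,
            "Ki_loss_unweighted": c.ki_loss_unweighted,
            "PSC_gain": c.psc_gain,
            "PSC_loss": c.psc_loss,
            "PSC_diff": c.psc_diff,
        }
        for j, (ki, w) in enumerate(zip(c.ki_blocks, c.weights)):
            row[f"Ki_block{j + 1}"] = ki
            row[f"weight_block{j + 1}"] = w
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(results: QuantResults, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = results_table(results)
    with open(out / "results.tsv", "w") as fh:
        fh.write(f"# Ki in 1/min, PSC in percent; config {results.provenance['config_hash']}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    io.write_json(out / "qc.json", results.qc)
    io.write_json(out / "provenance.json", results.provenance)
    return out
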