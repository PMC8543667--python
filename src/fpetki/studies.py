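"""Canned parameter-recovery studies on synthetic sessions.

These functions assemble study conditions (kinetic ground truth, group
structure, behavioral generating models), run the full pipeline or the
behavioral analysis, and return the recovered quantities next to the
generative truth. They back both the validation test suite and the
reproduction script.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import stepwise_polyfit
from .config import RunConfig, default_regions
from .pipeline import run_quantification, session_inputs_from_synthetic
from .synthetic import simulate_rt_amount_data, simulate_session

#: behavioral RT-versus-amount models as printed for the two groups
#: (intercept, linear, quadratic), mean-centered RT in ms per EUR
MEN_RT_MODEL = (-0.18, -2.36, 0.0)
WOMEN_RT_MODEL = (4.31, -0.95, -1.16)


@dataclass(frozen=True)
class RecoveryResult:
    """Recovered vs generative values for one simulated session."""

    ki_baseline_true: float
    ki_baseline_recovered: float
    ki_blocks_true: tuple[float, ...]
    ki_blocks_recovered: tuple[float, ...]
    ki_gain: float
    ki_loss: float
    psc_gain: float
    psc_loss: float
    conditions: tuple[str, ...]


def run_recovery_session(
    ki_baseline: float,
    task_ki: dict[str, float],
    seed: int,
    noise_sd: float = 0.0,
) -> RecoveryResult:
    """Simulate one noise-free session at the given generative influx values
    and quantify it with the full pipeline (blood -> metabolite correction
    -> GLM -> Patlak)."""
    cfg = RunConfig(
        regions=default_regions(ki_baseline=ki_baseline, task_ki=task_ki),
        noise_sd=noise_sd,
        seed=seed,
    )
    session = simulate_session(cfg)
    results = run_quantification(session_inputs_from_synthetic(session), cfg)
    rr = results.regions["vstr"]
    truth = session.truths["vstr"]
    c = rr.condition_ki
    return RecoveryResult(
        ki_baseline_true=truth.ki_baseline,
        ki_baseline_recovered=rr.patlak_baseline.ki,
        ki_blocks_true=truth.ki_blocks,
        ki_blocks_recovered=tuple(rr.task_ki_blocks),
        ki_gain=c.ki_gain,
        ki_loss=c.ki_loss,
        psc_gain=c.psc_gain,
        psc_loss=c.psc_loss,
        conditions=c.conditions,
    )


def womens_group_difference_study(
    n_subjects: int = 7,
    diff: float = -0.006,
    seed: int = 0,
) -> dict:
    """Simulate a group of women whose generative gain-loss difference is
    ``diff`` and recover the group-mean difference with the pipeline.

    Baseline and gain-condition influx vary across subjects around the
    group's values; every subject's loss influx is gain - diff.
    """
    rng = np.random.default_rng(seed)
    baselines = 0.012 + rng.uniform(-0.002, 0.002, n_subjects)
    gains = 0.012 + rng.uniform(-0.002, 0.002, n_subjects)
    diffs = []
    for i in range(n_subjects):
        res = run_recovery_session(
            ki_baseline=float(baselines[i]),
            task_ki={"gain": float(gains[i]), "loss": float(gains[i] - diff)},
            seed=seed + 1000 + i,
        )
        diffs.append(res.ki_gain - res.ki_loss)
    diffs = np.asarray(diffs)
    return {
        "generative_diff": diff,
        "recovered_diffs": diffs,
        "mean_diff": float(diffs.mean()),
        "sd_diff": float(diffs.std(ddof=1)),
    }


def behavior_recovery_study(
    model: tuple[float, float, float],
    seed: int = 0,
    n_subjects: int = 18,
    trials_per_amount: int = 10,
    noise_sd: float = 10.0,
) -> dict:
    """Recover a generating RT-versus-amount model by stepwise regression
    on pooled trial-level data."""
    intercept, linear, quadratic = model
    df = simulate_rt_amount_data(
        intercept, linear, quadratic,
        n_subjects=n_subjects, trials_per_amount=trials_per_amount,
        noise_sd=noise_sd, seed=seed,
    )
    fit = stepwise_polyfit(df["amount"].to_numpy(), df["rt"].to_numpy())
    return {
        "terms": fit.terms_,
        "coef": dict(fit.coef_),
        "se": dict(fit.bse_),
        "generative": {"linear": linear, "quadratic": quadratic},
        "n": len(df),
    }


def stepwise_selection_rates(
    seed: int = 0,
    n_replicates: int = 200,
    noise_sd: float = 10.0,
) -> dict:
    """Fraction of replicates in which stepwise selection includes the
    linear term for the men's generating model and the quadratic term for
    the women's."""
    men_hits = 0
    women_hits = 0
    for r in range(n_replicates):
        men = behavior_recovery_study(MEN_RT_MODEL, seed=seed + 2 * r, noise_sd=noise_sd)
        women = behavior_recovery_study(WOMEN_RT_MODEL, seed=seed + 2 * r + 1, noise_sd=noise_sd)
        men_hits += 1 in men["terms"]
        women_hits += 2 in women["terms"]
    return {
        "n_replicates": n_replicates,
        "men_linear_rate": men_hits / n_replicates,
        "women_quadratic_rate": women_hits / n_replicates,
    }
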