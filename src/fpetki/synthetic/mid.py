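"""Monetary incentive delay (MID) behavior with an adaptive staircase.

Each trial presents a cued amount; the subject must respond before the
current time limit. The limit tracks the subject: a hit shortens it by one
staircase step, a miss lengthens it, holding the hit probability near 0.5.
To separate gain from loss within one session, the limit receives a
one-time additive manipulation at the beginning and at the middle of every
block (eased in gain blocks, tightened in loss blocks), biasing gain blocks
toward net wins and loss blocks toward net losses while the staircase
slowly erodes the bias.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np


@dataclass(frozen=True)
class MidTrial:
    trial_index: int
    block: int
    condition: str  # gain | loss
    amount: float  # signed currency units (negative in loss blocks)
    time_limit: float  # ms, effective limit for this trial
    reaction_time: float  # ms
    hit: bool
    balance_delta: float  # currency units

    def __post_init__(self) -> None:
        if self.hit != (self.reaction_time <= self.time_limit):
            raise ValueError("hit must equal reaction_time <= time_limit")


def simulate_mid_session(
    rt_model: Callable[[float], float] | None = None,
    n_blocks: int = 4,
    trials_per_block: int = 20,
    staircase_step: float = 20.0,
    initial_limit: float = 500.0,
    manipulation_bias: float = 150.0,
    conditions: Sequence[str] = ("gain", "loss", "gain", "loss"),
    amounts: Sequence[float] = (1.0, 2.0, 3.0),
    rt_noise_sd: float = 100.0,
    seed: int | None = None,
) -> list[MidTrial]:
    """Simulate one MID session; fully replayable from ``seed``.

    rt_model maps the signed amount to the mean reaction time (ms); default
    is amount-independent at the initial limit so the unmanipulated hit
    rate sits near 0.5.
    """
    if trials_per_block % 2 != 0:
        raise ValueError("trials_per_block must be even (manipulation switches mid-block)")
    if len(conditions) != n_blocks:
        raise ValueError("one condition label per block required")
    if staircase_step < 0 or manipulation_bias < 0 or rt_noise_sd < 0:
        raise ValueError("step, bias and noise must be non-negative")
    if rt_model is None:
        rt_model = lambda amount: float(initial_limit)  # noqa: E731

    rng = np.random.default_rng(seed)
    amounts = np.asarray(amounts, dtype=float)
    if np.any(amounts <= 0):
        raise ValueError("amounts are magnitudes; signs follow the block condition")

    limit = float(initial_limit)
    trials: list[MidTrial] = []
    idx = 0
    half = trials_per_block // 2
    for b in range(n_blocks):
        cond = conditions[b]
        if cond not in ("gain", "loss"):
            raise ValueError(f"unknown block condition {cond!r}")
        sign = 1.0 if cond == "gain" else -1.0
        for k in range(trials_per_block):
            if k == 0 or k == half:
                # manipulation: ease gain blocks, tighten loss blocks
                limit += sign * manipulation_bias
            magnitude = float(rng.choice(amounts))
            amount = sign * magnitude
            rt = float(rng.normal(rt_model(amount), rt_noise_sd))
            rt = max(rt, 1.0)
            hit = rt <= limit
            if cond == "gain":
                delta = magnitude if hit else 0.0
            else:
                delta = 0.0 if hit else -magnitude
            trials.append(
                MidTrial(
                    trial_index=idx,
                    block=b,
                    condition=cond,
                    amount=amount,
                    time_limit=limit,
                    reaction_time=rt,
                    hit=bool(hit),
                    balance_delta=delta,
                )
            )
            limit += -staircase_step if hit else staircase_step
            idx += 1
    return trials


def simulate_rt_amount_data(
    intercept: float,
    linear: float,
    quadratic: float,
    n_subjects: int = 18,
    trials_per_amount: int = 10,
    amounts: Sequence[float] = (-3.0, -2.0, -1.0, 1.0, 2.0, 3.0),
    noise_sd: float = 10.0,
    seed: int | None = None,
):
    """Trial-level mean-centered RT data from a polynomial RT-amount model.

    Each simulated subject contributes ``trials_per_amount`` trials at every
    amount level with RT = intercept + linear*a + quadratic*a^2 + Gaussian
    noise (ms); RTs are then mean-centered within subject, mirroring the
    block-wise normalization applied to real staircase data. Returns a
    DataFrame with columns subject, amount, rt.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    amounts = np.asarray(amounts, dtype=float)
    rows = []
    for s in range(n_subjects):
        a = np.repeat(amounts, trials_per_amount)
        rt = intercept + linear * a + quadratic * a**2 + rng.normal(0.0, noise_sd, a.size)
        rt = rt - rt.mean()
        rows.append(pd.DataFrame({"subject": s, "amount": a, "rt": rt}))
    return pd.concat(rows, ignore_index=True)


def accumulated_balance(trials: Sequence[MidTrial], condition: str | None = None) -> float:
    """Total money gained (or lost) over the session or one condition."""
    return float(
        sum(tr.balance_delta for tr in trials if condition is None or tr.condition == condition)
    )


def block_performance_weight(trials: Sequence[MidTrial], block: int) -> float:
    """Task-performance weight of one block.

    Gain blocks: actual gain / possible gain. Loss blocks: amount avoided /
    maximum avoidable. Both lie in [0, 1].
    """
    rows = [tr for tr in trials if tr.block == block]
    if not rows:
        raise ValueError(f"no trials for block {block}")
    cond = rows[0].condition
    possible = sum(abs(tr.amount) for tr in rows)
    if possible == 0:
        raise ValueError("block has zero possible amount")
    if cond == "gain":
        actual = sum(tr.balance_delta for tr in rows)
    else:
        actual = sum(abs(tr.amount) for tr in rows if tr.hit)
    return float(actual / possible)
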