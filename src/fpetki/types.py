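"""Domain containers shared across the quantification pipeline.

Conventions: time in minutes from start of tracer administration, activity
concentration in kBq/mL, rate constants in 1/min (K1 in mL/cm3/min).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AdministrationSchedule",
    "KineticParams",
    "TaskSchedule",
    "InputFunctionSet",
    "k3_for_ki",
    "task_delta_for_ki",
]


@dataclass(frozen=True)
class AdministrationSchedule:
    """Bolus + constant-infusion tracer administration.

    The default 20:80 bolus:infusion split with the infusion running over
    the whole 50 min acquisition keeps the late parent-plasma curve close
    to a plateau, which is what makes within-scan task regressors and the
    graphical analysis well conditioned.
    """

    bolus_fraction: float = 0.20
    infusion_duration: float = 50.0  # minutes
    total_activity: float = 1.0  # arbitrary activity units
    scan_duration: float = 50.0  # minutes

    def __post_init__(self) -> None:
        if not 0.0 <= self.bolus_fraction <= 1.0:
            raise ValueError("bolus_fraction must lie in [0, 1]")
        if self.infusion_duration < 0 or self.infusion_duration > self.scan_duration + 1e-9:
            raise ValueError("infusion_duration must lie within the scan")
        if self.total_activity < 0:
            raise ValueError("total_activity must be non-negative")
        if self.scan_duration <= 0:
            raise ValueError("scan_duration must be positive")

    @property
    def infusion_fraction(self) -> float:
        return 1.0 - self.bolus_fraction


def k3_for_ki(K1: float, k2: float, ki: float) -> float:
    """Trapping rate k3 that yields net influx ``ki`` given K1 and k2.

    Inverts Ki = K1*k3/(k2+k3); requires ki < K1.
    """
    if not 0.0 <= ki < K1:
        raise ValueError("need 0 <= ki < K1 for an irreversible 2TC model")
    return k2 * ki / (K1 - ki)


@dataclass(frozen=True)
class KineticParams:
    """Irreversible two-tissue-compartment rate constants.

    k3 models trapping via decarboxylation (AADC) and is the parameter the
    task is allowed to modulate: ``task_k3_delta`` maps a block index to an
    additive change of k3 inside that block.
    """

    K1: float  # mL/cm3/min
    k2: float  # 1/min
    k3: float = 0.0  # 1/min
    vB: float = 0.05  # blood volume fraction
    task_k3_delta: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.K1 < 0 or self.k2 < 0 or self.k3 < 0:
            raise ValueError("rate constants must be non-negative")
        if not 0.0 <= self.vB <= 1.0:
            raise ValueError("vB must lie in [0, 1]")
        deltas = tuple((int(b), float(d)) for b, d in self.task_k3_delta)
        object.__setattr__(self, "task_k3_delta", deltas)
        for _, d in deltas:
            if self.k3 + d < 0:
                raise ValueError("task_k3_delta would make k3 negative")

    @property
    def ki(self) -> float:
        """Noise-free net influx constant K1*k3/(k2+k3)."""
        if self.k3 == 0.0:
            return 0.0
        return self.K1 * self.k3 / (self.k2 + self.k3)

    def ki_with_delta(self, delta: float) -> float:
        k3 = self.k3 + delta
        if k3 == 0.0:
            return 0.0
        return self.K1 * k3 / (self.k2 + k3)

    def block_task_ki(self) -> dict[int, float]:
        """Task-specific net influx increment per modulated block."""
        return {b: self.ki_with_delta(d) - self.ki for b, d in self.task_k3_delta}

    def with_task_ki(self, block_task_ki: dict[int, float]) -> "KineticParams":
        """Return params whose per-block influx increments equal the given values."""
        deltas = []
        for b, dki in block_task_ki.items():
            k3_task = k3_for_ki(self.K1, self.k2, self.ki + dki)
            deltas.append((b, k3_task - self.k3))
        return replace(self, task_k3_delta=tuple(deltas))


@dataclass(frozen=True)
class TaskSchedule:
    """Timing and condition labels of the task blocks within the scan."""

    onsets: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0)
    duration: float = 5.0  # minutes per block
    conditions: tuple[str, ...] = ("gain", "loss", "gain", "loss")

    def __post_init__(self) -> None:
        onsets = tuple(float(o) for o in self.onsets)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if self.duration <= 0:
            raise ValueError("block duration must be positive")
        if len(self.conditions) != len(onsets):
            raise ValueError("one condition label per block required")
        for c in self.conditions:
            if c not in ("gain", "loss", "mixed"):
                raise ValueError(f"unknown block condition {c!r}")
        for a, b in zip(onsets[:-1], onsets[1:]):
            if b < a + self.duration - 1e-12:
                raise ValueError("task blocks must not overlap")

    @property
    def n_blocks(self) -> int:
        return len(self.onsets)

    def block_interval(self, j: int) -> tuple[float, float]:
        return self.onsets[j], self.onsets[j] + self.duration

    def validate_within(self, scan_duration: float) -> None:
        if self.onsets and self.onsets[-1] + self.duration > scan_duration + 1e-9:
            raise ValueError("task blocks extend beyond the scan")

    def k3_series(self, t: np.ndarray, k3: float, deltas: tuple[tuple[int, float], ...]) -> np.ndarray:
        """Piecewise-constant k3(t): baseline plus the block deltas."""
        out = np.full(np.asarray(t).shape, float(k3))
        delta_map = dict(deltas)
        for j, onset in enumerate(self.onsets):
            d = delta_map.get(j, 0.0)
            if d:
                inside = (t >= onset) & (t < onset + self.duration)
                out[inside] += d
        return out

    def blocks_of(self, condition: str) -> list[int]:
        return [j for j, c in enumerate(self.conditions) if c == condition]


@dataclass(frozen=True)
class InputFunctionSet:
    """Whole-blood, parent (6-FDOPA) and metabolite (3-OMFD) concentration
    curves on a common time grid (minutes)."""

    t: np.ndarray
    whole_blood: np.ndarray
    parent: np.ndarray
    metabolite: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "t", t)
        for name in ("whole_blood", "parent", "metabolite"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != t.shape:
                raise ValueError(f"{name} must match the time grid")
            if np.any(arr < -1e-9):
                raise ValueError(f"{name} must be non-negative")
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if t[0] < -1e-12:
            raise ValueError("time grid must start at or after 0")

    @property
    def total_plasma(self) -> np.ndarray:
        return self.parent + self.metabolite

    @property
    def parent_fraction(self) -> np.ndarray:
        total = self.total_plasma
        out = np.ones_like(total)
        nz = total > 0
        out[nz] = self.parent[nz] / total[nz]
        return out

    def resample(self, t_new: np.ndarray) -> "InputFunctionSet":
        t_new = np.asarray(t_new, dtype=float)
        return InputFunctionSet(
            t=t_new,
            whole_blood=np.interp(t_new, self.t, self.whole_blood),
            parent=np.interp(t_new, self.t, self.parent),
            metabolite=np.interp(t_new, self.t, self.metabolite),
        )


def task_delta_for_ki(params: KineticParams, dki: float) -> float:
    """Additive k3 change producing a net-influx increment ``dki``."""
    k3_task = k3_for_ki(params.K1, params.k2, params.ki + dki)
    return k3_task - params.k3
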