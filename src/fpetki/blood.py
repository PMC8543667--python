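"""Arterial input functions from blood sample tables.

The parent (6-FDOPA) and metabolite (3-OMFD) plasma curves are assembled
as whole blood x plasma/whole-blood ratio x parent (metabolite) fraction.
The ratio is a linear fit to the per-sample plasma/whole-blood ratios; the
metabolite fraction starts from a literature-style pure-bolus fraction
curve and is adapted to the bolus+infusion protocol by treating the
administration as a superposition of boluses.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .types import AdministrationSchedule, InputFunctionSet

__all__ = [
    "BloodSamples",
    "PlasmaRatio",
    "fit_plasma_ratio",
    "adapt_metabolite_fraction",
    "assemble_input_functions",
]


@dataclass(frozen=True)
class BloodSamples:
    """Arterial samples: time (minutes), whole-blood and plasma activity."""

    time: np.ndarray
    whole_blood: np.ndarray
    plasma: np.ndarray

    def __post_init__(self) -> None:
        for name in ("time", "whole_blood", "plasma"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.time.shape == self.whole_blood.shape == self.plasma.shape):
            raise ValueError("sample columns must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.whole_blood < 0) or np.any(self.plasma < 0):
            raise ValueError("activities must be non-negative")


@dataclass(frozen=True)
class PlasmaRatio:
    """Linear plasma/whole-blood ratio r(t) = a + b*t, clamped to >= 0."""

    intercept: float
    slope: float  # per minute

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return np.maximum(self.intercept + self.slope * np.asarray(t, dtype=float), 0.0)


def fit_plasma_ratio(samples: BloodSamples) -> PlasmaRatio:
    """Ordinary least squares on the per-sample plasma/whole-blood ratios."""
    usable = samples.whole_blood > 0
    if int(usable.sum()) < 2:
        raise ValueError("need at least 2 samples with whole_blood > 0")
    t = samples.time[usable]
    r = samples.plasma[usable] / samples.whole_blood[usable]
    A = np.column_stack([np.ones_like(t), t])
    (a, b), *_ = np.linalg.lstsq(A, r, rcond=None)
    return PlasmaRatio(intercept=float(a), slope=float(b))


def _as_curve(f, t: np.ndarray) -> np.ndarray:
    if callable(f):
        return np.asarray(f(t), dtype=float)
    arr = np.asarray(f, dtype=float)
    if arr.shape != t.shape:
        raise ValueError("tabulated curve must match the time grid")
    return arr


def _default_total_bolus_response(t: np.ndarray) -> np.ndarray:
    from .synthetic.blood_model import BloodModelParams

    return BloodModelParams().total_bolus(t)


def adapt_metabolite_fraction(
    f_bolus: Callable[[np.ndarray], np.ndarray] | np.ndarray,
    schedule: AdministrationSchedule,
    t: np.ndarray,
    total_bolus_response: Callable[[np.ndarray], np.ndarray] | np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Adapt a pure-bolus 3-OMFD fraction curve to bolus+infusion.

    The B+I administration is treated as a superposition of boluses: the
    total and metabolite plasma responses are the administration-rate
    convolutions of the bolus responses (metabolite bolus response =
    f_bolus x total bolus response); the adapted fraction is their ratio.
    Returns ``(f_BI on t, percent AUC reduction vs the bolus fraction)``.

    ``total_bolus_response`` supplies the total (parent+metabolite) plasma
    unit-bolus curve shape; the default is the package's parametric blood
    model with default parameters. The result is invariant to its overall
    scale.
    """
    t = np.asarray(t, dtype=float)
    if np.any(np.diff(t) <= 0) or abs(t[0]) > 1e-12:
        raise ValueError("time grid must be strictly increasing and start at 0")
    fb = _as_curve(f_bolus, t)
    if np.any((fb < -1e-12) | (fb > 1 + 1e-12)):
        raise ValueError("bolus metabolite fraction must lie in [0, 1]")
    fb = np.clip(fb, 0.0, 1.0)
    if total_bolus_response is None:
        total_bolus_response = _default_total_bolus_response
    h_tot = _as_curve(total_bolus_response, t)
    if np.any(h_tot < 0):
        raise ValueError("total bolus response must be non-negative")
    h_met = fb * h_tot

    def superpose(h: np.ndarray) -> np.ndarray:
        out = schedule.bolus_fraction * h.copy()
        if schedule.infusion_fraction > 0 and schedule.infusion_duration > 0:
            rate = schedule.infusion_fraction / schedule.infusion_duration
            H = np.concatenate(([0.0], cumulative_trapezoid(h, t)))
            tail = np.clip(t - schedule.infusion_duration, 0.0, None)
            out = out + rate * (H - np.interp(tail, t, H))
        return out

    tot_bi = superpose(h_tot)
    met_bi = superpose(h_met)
    f_bi = np.zeros_like(tot_bi)
    nz = tot_bi > 0
    f_bi[nz] = met_bi[nz] / tot_bi[nz]

    horizon = t <= schedule.scan_duration + 1e-9
    auc_bolus = np.trapezoid(fb[horizon], t[horizon])
    auc_bi = np.trapezoid(f_bi[horizon], t[horizon])
    reduction = 100.0 * (1.0 - auc_bi / auc_bolus) if auc_bolus > 0 else 0.0
    return f_bi, float(reduction)


def assemble_input_functions(
    samples: BloodSamples,
    ratio: PlasmaRatio | Callable[[np.ndarray], np.ndarray],
    f_bi: Callable[[np.ndarray], np.ndarray] | np.ndarray,
    t: np.ndarray,
    extrapolation_margin: float = 5.0,
) -> InputFunctionSet:
    """Build the input-function set on ``t`` (minutes).

    Whole blood is linearly interpolated between samples with constant
    extrapolation after the last sample (an error if the grid runs more
    than ``extrapolation_margin`` minutes past it). Parent input = whole
    blood x ratio x (1 - f_BI); metabolite input = whole blood x ratio x
    f_BI, so parent + metabolite reproduces total plasma exactly.
    """
    t = np.asarray(t, dtype=float)
    if t[-1] > samples.time[-1] + extrapolation_margin:
        raise ValueError(
            f"grid extends {t[-1] - samples.time[-1]:.1f} min past the last blood sample "
            f"(allowed margin {extrapolation_margin:.1f} min)"
        )
    wb = np.interp(t, samples.time, samples.whole_blood)
    r = ratio(t) if callable(ratio) else np.asarray(ratio, dtype=float)
    total_plasma = np.maximum(wb * r, 0.0)
    frac = np.clip(_as_curve(f_bi, t), 0.0, 1.0)
    metabolite = total_plasma * frac
    parent = total_plasma - metabolite
    return InputFunctionSet(t=t, whole_blood=wb, parent=parent, metabolite=metabolite)
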