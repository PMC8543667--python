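"""Parametric arterial blood model and its bolus+infusion superposition.

The unit-bolus parent plasma response is a sum of exponentials; the
metabolite (3-OMFD) plasma response follows by first-order conversion from
parent with its own clearance. Both have closed forms, as do their running
integrals, so any bolus + constant-infusion administration is obtained by
exact superposition rather than numeric convolution.

The default parent clearance is dominated by a 0.08/min component, which
under the default 20:80 split over 50 min makes the late parent plasma
near-flat (a pure mono-exponential at rate (1-f_b)/(T_inf*f_b) would be
exactly flat).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..types import AdministrationSchedule, InputFunctionSet


@dataclass(frozen=True)
class BloodModelParams:
    """Unit-bolus plasma responses and the plasma/whole-blood ratio line.

    Amplitudes are kBq/mL in plasma per unit administered activity.
    """

    parent_amps: tuple[float, ...] = (40.0, 10.0)
    parent_rates: tuple[float, ...] = (0.08, 0.6)  # 1/min
    k_met: float = 0.012  # parent -> 3-OMFD conversion, 1/min
    lam_met: float = 0.02  # 3-OMFD plasma clearance, 1/min
    ratio_intercept: float = 1.10  # plasma / whole blood at t=0
    ratio_slope: float = 0.0015  # per minute

    def __post_init__(self) -> None:
        if len(self.parent_amps) != len(self.parent_rates):
            raise ValueError("parent_amps and parent_rates must align")
        if any(a < 0 for a in self.parent_amps) or any(r <= 0 for r in self.parent_rates):
            raise ValueError("non-physical parent response parameters")
        if self.k_met < 0 or self.lam_met < 0:
            raise ValueError("non-physical metabolite parameters")
        if self.ratio_intercept <= 0:
            raise ValueError("plasma/whole-blood ratio must be positive")

    # ---- closed-form unit-bolus responses -------------------------------
    def parent_bolus(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for A, lam in zip(self.parent_amps, self.parent_rates):
            out += A * np.exp(-lam * t)
        return out

    def parent_bolus_integral(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for A, lam in zip(self.parent_amps, self.parent_rates):
            out += A * (1.0 - np.exp(-lam * t)) / lam
        return out

    def metabolite_bolus(self, t: np.ndarray) -> np.ndarray:
        """Solution of m' = k_met * p(t) - lam_met * m for a unit bolus."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for A, lam in zip(self.parent_amps, self.parent_rates):
            if abs(lam - self.lam_met) < 1e-12:
                out += self.k_met * A * t * np.exp(-lam * t)
            else:
                out += (
                    self.k_met
                    * A
                    * (np.exp(-self.lam_met * t) - np.exp(-lam * t))
                    / (lam - self.lam_met)
                )
        return out

    def metabolite_bolus_integral(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        lm = self.lam_met
        for A, lam in zip(self.parent_amps, self.parent_rates):
            if abs(lam - lm) < 1e-12:
                out += self.k_met * A * (1.0 - (1.0 + lam * t) * np.exp(-lam * t)) / lam**2
            else:
                out += (
                    self.k_met
                    * A
                    / (lam - lm)
                    * ((1.0 - np.exp(-lm * t)) / lm - (1.0 - np.exp(-lam * t)) / lam)
                )
        return out

    def total_bolus(self, t: np.ndarray) -> np.ndarray:
        return self.parent_bolus(t) + self.metabolite_bolus(t)

    def ratio(self, t: np.ndarray) -> np.ndarray:
        return np.maximum(self.ratio_intercept + self.ratio_slope * np.asarray(t, float), 0.0)


def _superpose(
    schedule: AdministrationSchedule,
    response,
    response_integral,
    t: np.ndarray,
) -> np.ndarray:
    """Plasma curve of a bolus+infusion administration of a unit response.

    bolus part:    f_b * A * h(t)
    infusion part: (1-f_b) * A / T_inf * (H(t) - H(t - T_inf))
    """
    t = np.asarray(t, dtype=float)
    out = schedule.bolus_fraction * schedule.total_activity * response(t)
    inf_frac = schedule.infusion_fraction
    if inf_frac > 0 and schedule.infusion_duration > 0:
        rate = inf_frac * schedule.total_activity / schedule.infusion_duration
        tail = np.clip(t - schedule.infusion_duration, 0.0, None)
        out += rate * (response_integral(t) - response_integral(tail))
    return out


def make_input_functions(
    schedule: AdministrationSchedule,
    params: BloodModelParams | None = None,
    t: np.ndarray | None = None,
) -> InputFunctionSet:
    """Whole-blood, parent and metabolite plasma curves for a B+I protocol.

    The curves are the exact superposition (administration-rate convolution)
    of the closed-form unit-bolus responses; whole blood is total plasma
    divided by the linear plasma/whole-blood ratio.
    """
    params = params or BloodModelParams()
    if t is None:
        from ..kinetics import internal_grid

        t = internal_grid(schedule.scan_duration)
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if abs(t[0]) > 1e-12:
        raise ValueError("time grid must start at 0")
    parent = _superpose(schedule, params.parent_bolus, params.parent_bolus_integral, t)
    metabolite = _superpose(
        schedule, params.metabolite_bolus, params.metabolite_bolus_integral, t
    )
    whole_blood = (parent + metabolite) / params.ratio(t)
    return InputFunctionSet(t=t, whole_blood=whole_blood, parent=parent, metabolite=metabolite)


def metabolite_bolus_fraction(params: BloodModelParams, t: np.ndarray) -> np.ndarray:
    """3-OMFD fraction of total plasma after a pure bolus.

    This is the generator's analogue of a literature bolus parent-fraction
    curve and is what the blood module adapts to bolus+infusion.
    """
    p = params.parent_bolus(t)
    m = params.metabolite_bolus(t)
    total = p + m
    out = np.zeros_like(total)
    nz = total > 0
    out[nz] = m[nz] / total[nz]
    return out
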