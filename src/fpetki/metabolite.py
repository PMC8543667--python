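"""Removal of the 3-OMFD metabolite signal from brain TACs.

3-OMFD crosses the blood-brain barrier and adds a non-specific, spatially
uniform component to every brain TAC. The correction fits a one-tissue
model to a reference region devoid of trapping (occipital cortex), under
the assumptions that (i) the reference region has no specific binding,
(ii) the distribution volumes of 3-OMFD and 6-FDOPA are equal there and
(iii) the 3-OMFD distribution volume is uniform across the brain. With
equal distribution volumes the reference tissue responds to parent and
metabolite plasma with the same impulse response, so the reference fit is
driven by total plasma; the brain-wide metabolite component is then the
fitted impulse response convolved with the 3-OMFD input function, and is
subtracted from every TAC.

The fixed 5% whole-blood component is modelled explicitly throughout:
measured = (1 - vB) * tissue + vB * whole blood.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .frames import FrameSchedule
from .kinetics import conv_1tc
from .types import InputFunctionSet

__all__ = [
    "OneTissueFit",
    "ReferenceOneTissueModel",
    "fit_reference_1tc",
    "estimate_omfd_tissue",
    "correct_tacs",
    "tissue_fraction",
]


@dataclass(frozen=True)
class OneTissueFit:
    """Fitted reference-region one-tissue parameters."""

    K1: float  # mL/cm3/min
    k2: float  # 1/min
    residual_rms: float  # kBq/mL
    covariance: np.ndarray  # 2x2, (K1, k2)
    vB: float
    converged: bool
    n_starts: int


class ReferenceOneTissueModel:
    """Nonlinear least-squares fit of the reference TAC.

    Model: (1-vB) * [K1 exp(-k2 t) (*) (Cp + Cm)] + vB * C_wb, frame
    averaged. Parameters are optimized in log space over a multi-start
    grid (log-uniform over the parameter box) with the lowest-residual
    converged solution retained.

    Attributes set by :meth:`fit`: ``K1_``, ``k2_``, ``residual_rms_``,
    ``covariance_``, ``converged_``.
    """

    def __init__(
        self,
        vB: float = 0.05,
        bounds: tuple[tuple[float, float], tuple[float, float]] = ((1e-4, 2.0), (1e-4, 2.0)),
        n_starts: int = 10,
        tol: float = 1e-8,
    ) -> None:
        self.vB = vB
        self.bounds = bounds
        self.n_starts = n_starts
        self.tol = tol

    def _start_grid(self) -> np.ndarray:
        (k1lo, k1hi), (k2lo, k2hi) = self.bounds
        n = max(int(np.ceil(np.sqrt(self.n_starts))), 1)
        g1 = np.exp(np.linspace(np.log(k1lo * 10), np.log(k1hi / 10), n))
        g2 = np.exp(np.linspace(np.log(k2lo * 10), np.log(k2hi / 10), n))
        grid = np.array([(a, b) for a in g1 for b in g2])
        return grid[: self.n_starts]

    def fit(
        self,
        ref_tac: np.ndarray,
        frames: FrameSchedule,
        inputs: InputFunctionSet,
        nuisance: np.ndarray | None = None,
    ) -> "ReferenceOneTissueModel":
        """Fit the reference TAC, optionally adjusting for nuisance signal.

        ``nuisance`` columns (task ramps, motion) enter the model linearly;
        for each candidate (K1, k2) their coefficients are profiled out by
        least squares, so the reference is adjusted for task and movement
        with the same regressors as the uptake GLM while its baseline is
        represented by the one-tissue model itself.
        """
        y = np.asarray(ref_tac, dtype=float)
        if y.shape != (frames.n_frames,):
            raise ValueError("reference TAC must match the frame schedule")
        driving = inputs.total_plasma
        if np.max(driving) <= 0:
            raise ValueError("degenerate input: total plasma is identically zero")
        t = inputs.t
        wb_frames = frames.average(t, inputs.whole_blood)
        vB = self.vB
        N = None
        if nuisance is not None:
            N = np.atleast_2d(np.asarray(nuisance, dtype=float))
            if N.shape[0] != y.size:
                N = N.T
            if N.shape[0] != y.size:
                raise ValueError("nuisance regressors must match the frame schedule")
            # drop all-zero columns (e.g. zero-motion sessions)
            N = N[:, np.ptp(N, axis=0) > 0]
            if N.shape[1] == 0:
                N = None

        def model(theta: np.ndarray) -> np.ndarray:
            K1, k2 = np.exp(theta)
            tissue = conv_1tc(t, driving, K1, k2)
            return (1.0 - vB) * frames.average(t, tissue) + vB * wb_frames

        def resid(theta: np.ndarray) -> np.ndarray:
            r = model(theta) - y
            if N is not None:
                coef, *_ = np.linalg.lstsq(N, -r, rcond=None)
                r = r + N @ coef
            return r

        (k1lo, k1hi), (k2lo, k2hi) = self.bounds
        lb = np.log([k1lo, k2lo])
        ub = np.log([k1hi, k2hi])
        best = None
        for start in self._start_grid():
            theta0 = np.log(start)
            try:
                sol = least_squares(
                    resid, theta0, bounds=(lb, ub), xtol=self.tol, ftol=self.tol, gtol=self.tol
                )
            except Exception:  # pragma: no cover - optimizer failure path
                continue
            if not sol.success:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("reference 1TC fit failed to converge from any start")
        K1, k2 = np.exp(best.x)
        # delta-method covariance in (K1, k2) from the log-space Jacobian
        J = best.jac * np.exp(best.x)  # d(resid)/d(K1,k2)
        dof = max(y.size - 2, 1)
        rss = float(2.0 * best.cost)
        try:
            cov = np.linalg.inv(J.T @ J) * rss / dof
        except np.linalg.LinAlgError:  # pragma: no cover
            cov = np.full((2, 2), np.nan)
        self.K1_ = float(K1)
        self.k2_ = float(k2)
        self.residual_rms_ = float(np.sqrt(rss / y.size))
        self.covariance_ = cov
        self.converged_ = True
        if N is not None:
            coef, *_ = np.linalg.lstsq(N, y - model(best.x), rcond=None)
            self.nuisance_coef_ = coef
            self.adjusted_tac_ = y - N @ coef
        else:
            self.nuisance_coef_ = np.zeros(0)
            self.adjusted_tac_ = y.copy()
        return self

    def result(self) -> OneTissueFit:
        return OneTissueFit(
            K1=self.K1_,
            k2=self.k2_,
            residual_rms=self.residual_rms_,
            covariance=self.covariance_,
            vB=self.vB,
            converged=self.converged_,
            n_starts=self.n_starts,
        )


def fit_reference_1tc(
    ref_tac: np.ndarray,
    frames: FrameSchedule,
    inputs: InputFunctionSet,
    vB: float = 0.05,
    nuisance: np.ndarray | None = None,
    **kwargs,
) -> OneTissueFit:
    """Fit the (task/motion-adjusted) reference TAC; see
    :class:`ReferenceOneTissueModel`."""
    model = ReferenceOneTissueModel(vB=vB, **kwargs)
    return model.fit(ref_tac, frames, inputs, nuisance=nuisance).result()


def estimate_omfd_tissue(
    fit: OneTissueFit,
    inputs: InputFunctionSet,
    frames: FrameSchedule,
) -> np.ndarray:
    """Brain 3-OMFD tissue component: K1 exp(-k2 t) convolved with the
    metabolite input function, frame-averaged."""
    if not fit.converged:
        raise ValueError("reference fit did not converge")
    tissue = conv_1tc(inputs.t, inputs.metabolite, fit.K1, fit.k2)
    return frames.average(inputs.t, tissue)


def correct_tacs(
    tacs: dict[str, np.ndarray] | np.ndarray,
    omfd_tac: np.ndarray,
    vB: float = 0.05,
) -> dict[str, np.ndarray] | np.ndarray:
    """Subtract the (1-vB)-scaled metabolite tissue curve from brain TACs.

    Negative residual values are permitted (and surfaced by the pipeline's
    QC report rather than clipped).
    """
    omfd_tac = np.asarray(omfd_tac, dtype=float)

    def one(tac: np.ndarray) -> np.ndarray:
        tac = np.asarray(tac, dtype=float)
        if tac.shape != omfd_tac.shape:
            raise ValueError("TAC and metabolite curve must share the frame schedule")
        return tac - (1.0 - vB) * omfd_tac

    if isinstance(tacs, dict):
        return {name: one(tac) for name, tac in tacs.items()}
    return one(tacs)


def tissue_fraction(
    tac: np.ndarray,
    wb_frames: np.ndarray,
    vB: float = 0.05,
) -> np.ndarray:
    """Invert the measurement equation for the blood component:
    tissue = (measured - vB * whole_blood) / (1 - vB)."""
    tac = np.asarray(tac, dtype=float)
    wb_frames = np.asarray(wb_frames, dtype=float)
    if tac.shape != wb_frames.shape:
        raise ValueError("TAC and whole-blood curve must share the frame schedule")
    return (tac - vB * wb_frames) / (1.0 - vB)
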