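"""Compartment-model solvers on a fine internal grid.

The tissue systems are linear ODEs driven by plasma input curves. We solve
them by exact exponential stepping of piecewise-constant inputs on a 1 s
internal grid (input value per step = trapezoid mean of the sampled curve),
which avoids stiff-solver dependence and doubles as a reusable convolution
oracle for the metabolite-correction module.
"""
from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

#: internal step, minutes (1 second)
INTERNAL_DT = 1.0 / 60.0


def internal_grid(duration: float, dt: float = INTERNAL_DT) -> np.ndarray:
    n = int(round(duration / dt))
    return np.arange(n + 1) * dt


def _segment_means(c: np.ndarray) -> np.ndarray:
    return 0.5 * (c[:-1] + c[1:])


def conv_1tc(t: np.ndarray, cin: np.ndarray, K1: float, k2: float) -> np.ndarray:
    """One-tissue response: c(t) = K1 * exp(-k2 t) convolved with ``cin``.

    Exact for an input that is piecewise constant at the segment-mean
    values; implemented as a first-order IIR recursion.
    """
    t = np.asarray(t, dtype=float)
    cin = np.asarray(cin, dtype=float)
    dt = np.diff(t)
    if np.ptp(dt) > 1e-9 * dt[0]:
        raise ValueError("conv_1tc requires a uniform time grid")
    h = float(dt[0])
    u = _segment_means(cin)
    out = np.zeros_like(cin)
    if k2 * h < 1e-12:
        out[1:] = K1 * np.cumsum(u) * h
        return out
    E = np.exp(-k2 * h)
    gain = K1 * (1.0 - E) / k2
    out[1:] = lfilter([gain], [1.0, -E], u)
    return out


def solve_2tc_irreversible(
    t: np.ndarray,
    cp: np.ndarray,
    K1: float,
    k2: float,
    k3: float | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Free and trapped tissue concentrations of the irreversible 2TC model.

    dC1/dt = K1*Cp - (k2 + k3(t))*C1 ;  dC2/dt = k3(t)*C1

    ``k3`` may be a scalar or a per-segment/per-sample array (piecewise
    constant within each step), enabling task modulation of trapping.
    Returns (C1, C2) sampled on ``t``.
    """
    t = np.asarray(t, dtype=float)
    cp = np.asarray(cp, dtype=float)
    dt = np.diff(t)
    if np.ptp(dt) > 1e-9 * dt[0]:
        raise ValueError("solver requires a uniform time grid")
    h = float(dt[0])
    n_seg = t.size - 1
    u = _segment_means(cp)

    k3_arr = np.asarray(k3, dtype=float)
    if k3_arr.ndim == 0:
        k3_seg = np.full(n_seg, float(k3_arr))
    elif k3_arr.size == n_seg:
        k3_seg = k3_arr
    elif k3_arr.size == t.size:
        k3_seg = k3_arr[:-1]
    else:
        raise ValueError("k3 must be scalar, per-segment or per-sample")
    if np.any(k3_seg < 0):
        raise ValueError("k3 must stay non-negative over the whole scan")

    a = k2 + k3_seg
    c1 = np.zeros(t.size)
    # exact update over segments of constant a; vectorize over runs
    runs = np.flatnonzero(np.diff(a) != 0.0)
    bounds = np.concatenate(([0], runs + 1, [n_seg]))
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi <= lo:
            continue
        a_run = a[lo]
        u_run = u[lo:hi]
        c0 = c1[lo]
        if a_run * h < 1e-12:
            c1[lo + 1 : hi + 1] = c0 + K1 * np.cumsum(u_run) * h
        else:
            E = np.exp(-a_run * h)
            gain = K1 * (1.0 - E) / a_run
            free = lfilter([gain], [1.0, -E], u_run)
            n = np.arange(1, hi - lo + 1)
            c1[lo + 1 : hi + 1] = free + c0 * E**n

    # trapped increment over one segment of constant a with c1(start)=c1_n:
    #   dC2 = k3 * [ c1_n*(1-E)/a + (K1*u/a)*(h - (1-E)/a) ]
    with np.errstate(divide="ignore", invalid="ignore"):
        E_seg = np.exp(-a * h)
        w1 = np.where(a * h < 1e-12, h, (1.0 - E_seg) / np.where(a == 0, 1.0, a))
        w2 = np.where(a * h < 1e-12, 0.5 * h * h, (h - w1) / np.where(a == 0, 1.0, a))
    inc = k3_seg * (c1[:-1] * w1 + K1 * u * w2)
    c2 = np.concatenate(([0.0], np.cumsum(inc)))
    return c1, c2
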