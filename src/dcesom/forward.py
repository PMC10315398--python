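"""Forward nested observation models for tissue contrast-agent concentration.

Three physiologically nested models describe the tissue DeltaR1 trace given a
plasma input Cp(t):

* model 1 — intact barrier:      C(t) = [vp Cp(t)] / (1 - Hct)
* model 2 — leakage, no backflux: C(t) = [vp Cp(t) + Ktrans Int_0^t Cp] / (1 - Hct)
* model 3 — leakage + backflux:   C(t) = [vp Cp(t) + Ktrans Int_0^t Cp(l) e^(-kep (t-l)) dl] / (1 - Hct)

Rates are supplied in 1/min (the reporting unit) and converted to 1/s
internally; ``times`` is in seconds.  The convolution integral is evaluated by
trapezoidal quadrature on the supplied grid, via an O(n) exponential-kernel
recursion.
"""

from __future__ import annotations

import numpy as np

MODELS = (1, 2, 3)
SEC_PER_MIN = 60.0


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or (np.diff(times) <= 0).any():
        raise ValueError("times must be a strictly increasing 1-D grid")
    return times


def cumtrapz_grid(values: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Cumulative trapezoidal integral with a leading zero, on ``times``."""
    dt = np.diff(times)
    out = np.zeros_like(values, dtype=float)
    out[1:] = np.cumsum(0.5 * dt * (values[1:] + values[:-1]))
    return out


def exp_convolution(cp: np.ndarray, times: np.ndarray, kep_per_s: float) -> np.ndarray:
    """Int_0^t cp(l) exp(-kep (t - l)) dl by trapezoid on the grid, O(n)."""
    if kep_per_s == 0.0:
        return cumtrapz_grid(cp, times)
    dt = np.diff(times)
    decay = np.exp(-kep_per_s * dt)
    out = np.zeros_like(cp, dtype=float)
    for i in range(1, cp.size):
        out[i] = out[i - 1] * decay[i - 1] + 0.5 * dt[i - 1] * (
            cp[i] + cp[i - 1] * decay[i - 1]
        )
    return out


def exp_convolution_matrix(cp: np.ndarray, times: np.ndarray, keps_per_s: np.ndarray) -> np.ndarray:
    """Vectorized :func:`exp_convolution` for many kep values: (nk, nt) output."""
    keps = np.atleast_1d(np.asarray(keps_per_s, dtype=float))
    dt = np.diff(times)
    decay = np.exp(-np.outer(keps, dt))  # (nk, nt-1)
    out = np.zeros((keps.size, cp.size))
    for i in range(1, cp.size):
        out[:, i] = out[:, i - 1] * decay[:, i - 1] + 0.5 * dt[i - 1] * (
            cp[i] + cp[i - 1] * decay[:, i - 1]
        )
    return out


def forward_tissue_curve(
    times: np.ndarray,
    cp: np.ndarray,
    model_id: int,
    vp: float,
    ktrans: float = 0.0,
    kep: float = 0.0,
    hct: float = 0.0,
) -> np.ndarray:
    """Evaluate the selected nested observation model.

    ``ktrans`` and ``kep`` are in 1/min; ``times`` in seconds.
    """
    times = _check_times(times)
    cp = np.asarray(cp, dtype=float)
    if cp.shape != times.shape:
        raise ValueError("cp and times must share a grid")
    if model_id not in MODELS:
        raise ValueError(f"model_id must be one of {MODELS}")
    if ktrans < 0 or kep < 0:
        raise ValueError("Ktrans and kep must be non-negative")
    if model_id == 1 and (ktrans != 0 or kep != 0):
        raise ValueError("model 1 has no leakage parameters")
    if model_id == 2 and kep != 0:
        raise ValueError("model 2 has no backflux parameter")

    scale = 1.0 / (1.0 - hct)
    curve = vp * cp
    if model_id >= 2:
        kt_s = ktrans / SEC_PER_MIN
        kep_s = kep / SEC_PER_MIN
        if model_id == 2 or kep_s == 0.0:
            curve = curve + kt_s * cumtrapz_grid(cp, times)
        else:
            curve = curve + kt_s * exp_convolution(cp, times, kep_s)
    return scale * curve
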