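"""Dual-gradient-echo signal synthesis.

Each acquisition yields two spoiled-gradient-echo readouts sharing the same
T1-weighted steady state but different T2* decay:

    F(t) = M0 sin(theta) (1 - E(t)) exp(-TE1/T2*(t)) / (1 - cos(theta) E(t))
    S(t) = M0 sin(theta) (1 - E(t)) exp(-TE2/T2*(t)) / (1 - cos(theta) E(t))

with E(t) = exp(-TR/T1(t)).  Because TE2 = mu TE1, the combination
F^(mu/(mu-1)) / S^(1/(mu-1)) cancels the T2* factor exactly — the property the
relaxometry stage inverts.  Contrast agent shortens both relaxation times:
R1(t) = 1/T1pre + DeltaR1(t) and 1/T2*(t) = 1/T2*pre + kappa DeltaR1(t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import TissueTruth
from .protocol import AcquisitionProtocol


@dataclass
class DualEchoSeries:
    """First/second-echo 4-D intensity arrays, shaped (x, y, slice, time)."""

    echo1: np.ndarray
    echo2: np.ndarray
    protocol: AcquisitionProtocol

    @property
    def shape(self):
        return self.echo1.shape


def spgre_signal(
    m0: np.ndarray,
    theta_deg: float | np.ndarray,
    tr: float,
    t1: np.ndarray,
    te: float,
    t2star: np.ndarray,
) -> np.ndarray:
    """Spoiled-gradient-echo steady-state magnitude at echo time ``te``."""
    theta = np.deg2rad(theta_deg)
    e = np.exp(-tr / t1)
    return m0 * np.sin(theta) * (1.0 - e) * np.exp(-te / t2star) / (1.0 - np.cos(theta) * e)


def synthesize_dge(
    delta_r1: np.ndarray,
    truth: TissueTruth,
    protocol: AcquisitionProtocol,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DualEchoSeries:
    """Form noisy dual-echo series from a DeltaR1 volume-series.

    ``delta_r1`` is shaped (x, y, slice, time) in 1/s.  Additive zero-mean
    Gaussian noise of standard deviation ``noise_sd`` is applied independently
    to each echo; the draw is deterministic for a fixed ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if (truth.m0 <= 0).any():
        raise ValueError("M0 must be positive everywhere")
    if (truth.t1pre <= 0).any():
        raise ValueError("T1pre must be positive everywhere")
    delta_r1 = np.asarray(delta_r1, dtype=float)
    r1 = 1.0 / truth.t1pre[..., None] + delta_r1
    if (r1 <= 0).any():
        raise ValueError("DeltaR1 must satisfy R1(t) = 1/T1pre + DeltaR1(t) > 0")
    t1 = 1.0 / r1
    r2star = 1.0 / truth.t2star_pre[..., None] + truth.kappa * delta_r1
    t2star = 1.0 / r2star

    m0 = truth.m0[..., None]
    echo1 = spgre_signal(m0, protocol.theta_nominal, protocol.TR, t1, protocol.TE1, t2star)
    echo2 = spgre_signal(m0, protocol.theta_nominal, protocol.TR, t1, protocol.TE2, t2star)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        echo1 = echo1 + rng.normal(0.0, noise_sd, size=echo1.shape)
        echo2 = echo2 + rng.normal(0.0, noise_sd, size=echo2.shape)
    return DualEchoSeries(echo1=echo1, echo2=echo2, protocol=protocol)


def baseline_noise_sd_for_snr(truth: TissueTruth, protocol: AcquisitionProtocol, snr: float) -> float:
    """Noise sd giving the requested first-echo baseline SNR over the brain."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    mask = truth.brain_mask
    f0 = spgre_signal(
        truth.m0[mask],
        protocol.theta_nominal,
        protocol.TR,
        truth.t1pre[mask],
        protocol.TE1,
        truth.t2star_pre[mask],
    )
    return float(f0.mean() / snr)
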