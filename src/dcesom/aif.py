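"""Parametric arterial input function (AIF) models.

The plasma contrast-agent concentration trace Cp(t) is described by a
gamma-variate first-pass bolus plus an optional recirculation bump and a slow
mono-exponential washout tail.  Units are DeltaR1-equivalent (1/s); absolute
amplitude is irrelevant downstream because the trace is re-normalized against
a reference tissue region with known plasma volume fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class AIFModel:
    """Gamma-variate bolus with washout tail.

    Cp(t) = amplitude * g(t - onset) + tail_frac * amplitude * w(t - onset)
    with g the unit-peak gamma variate ((t/tp)^alpha) * exp(alpha (1 - t/tp))
    peaking at ``time_to_peak`` seconds after onset, and w a delayed
    mono-exponential washout plateau.
    """

    onset: float = 21.7  # s; bolus arrival (default: acquisition 15 at 1.55 s)
    amplitude: float = 5.0  # peak Cp in 1/s before normalization
    time_to_peak: float = 10.0  # s after onset
    shape: float = 3.0  # gamma-variate alpha (dimensionless)
    recirc_frac: float = 0.15  # relative amplitude of the recirculation bump
    recirc_delay: float = 25.0  # s after onset
    tail_frac: float = 0.25  # washout plateau relative to peak
    tail_rate: float = 1.0 / 600.0  # 1/s; plasma washout ~10 min half-life scale

    def __call__(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float) - self.onset
        cp = np.zeros_like(t)
        pos = t > 0
        tp = t[pos]
        rel = tp / self.time_to_peak
        cp_pos = self.amplitude * rel**self.shape * np.exp(self.shape * (1.0 - rel))
        # recirculation: smaller, delayed gamma variate with the same shape
        rel2 = np.clip(tp - self.recirc_delay, 0.0, None) / (2.0 * self.time_to_peak)
        cp_pos += (
            self.recirc_frac
            * self.amplitude
            * rel2**self.shape
            * np.exp(self.shape * (1.0 - rel2))
        )
        # washout tail: rises with the bolus, decays slowly
        cp_pos += (
            self.tail_frac
            * self.amplitude
            * (1.0 - np.exp(-tp / self.time_to_peak))
            * np.exp(-self.tail_rate * tp)
        )
        cp[pos] = cp_pos
        return cp

    def sample(self, protocol) -> np.ndarray:
        return self(protocol.times)
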