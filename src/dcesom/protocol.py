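"""Acquisition protocol and baseline-window definitions shared by synthesis and relaxometry."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Dual-gradient-echo DCE acquisition parameters.

    Times are in seconds.  ``mu`` is the echo-time ratio TE2/TE1, the exponent
    base of the dual-echo T2*-cancellation trick.  ``injection_acq`` is the
    1-based acquisition index at which the contrast bolus is pushed.
    """

    TR: float = 0.024
    TE1: float = 0.002
    TE2: float = 0.004
    theta_nominal: float = 18.0  # degrees
    dt: float = 1.55
    n_acq: int = 400
    injection_acq: int = 15
    Hct: float = 0.45

    def __post_init__(self) -> None:
        if not (0 < self.TE1 < self.TE2):
            raise ValueError("require TE2 > TE1 > 0")
        if self.TR <= self.TE2:
            raise ValueError("require TR > TE2")
        if not (1 <= self.injection_acq < self.n_acq):
            raise ValueError("require 1 <= injection_acq < n_acq")
        if not (0 <= self.Hct < 1):
            raise ValueError("require 0 <= Hct < 1")
        if not (0 < self.theta_nominal <= 90):
            raise ValueError("require 0 < theta_nominal <= 90 degrees")

    @property
    def mu(self) -> float:
        return self.TE2 / self.TE1

    @property
    def times(self):
        """Acquisition time grid in seconds, t=0 at the first acquisition."""
        import numpy as np

        return np.arange(self.n_acq) * self.dt

    @property
    def injection_time(self) -> float:
        """Time of the bolus push in seconds (start of the injection acquisition)."""
        return (self.injection_acq - 1) * self.dt

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class BaselineWindows:
    """Pre-injection (m..n) and saturated late (o..p) averaging windows.

    Bounds are 1-based, inclusive acquisition indices.  The two windows must
    have equal length (p - o = n - m).
    """

    m: int = 5
    n: int = 14
    o: int = 391
    p: int = 400

    def __post_init__(self) -> None:
        if not (1 <= self.m <= self.n < self.o <= self.p):
            raise ValueError("require 1 <= m <= n < o <= p")
        if self.p - self.o != self.n - self.m:
            raise ValueError("windows must have equal length (p - o = n - m)")

    @classmethod
    def default_for(cls, protocol: AcquisitionProtocol, length: int = 10) -> "BaselineWindows":
        """Last ``length`` pre-injection acquisitions and last ``length`` acquisitions."""
        n = protocol.injection_acq - 1
        m = n - length + 1
        if m < 1:
            raise ValueError("not enough pre-injection acquisitions for the requested window")
        return cls(m=m, n=n, o=protocol.n_acq - length + 1, p=protocol.n_acq)

    def validate_against(self, protocol: AcquisitionProtocol) -> None:
        if self.n >= protocol.injection_acq:
            raise ValueError("pre-injection window overlaps the injection transient")
        if self.p != protocol.n_acq:
            raise ValueError("saturated window must end at the last acquisition")

    @property
    def length(self) -> int:
        return self.n - self.m + 1

    def pre_slice(self) -> slice:
        """0-based slice of the pre-injection window on the acquisition axis."""
        return slice(self.m - 1, self.n)

    def sat_slice(self) -> slice:
        return slice(self.o - 1, self.p)
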