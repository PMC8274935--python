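"""Voltage waveforms driving the channel model.

A waveform maps time (ms) to voltage (mV) and exposes its discontinuity
structure through :meth:`segments` so the integrator can restart cleanly at
each boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator, Sequence

import numpy as np

__all__ = [
    "ConstantWaveform",
    "StepWaveform",
    "SquareWaveform",
    "TrapezoidWaveform",
    "SampledWaveform",
]

Segment = tuple[float, float, Callable[[float], float]]


class _WaveformBase:
    def voltage(self, t: float) -> float:
        raise NotImplementedError

    def __call__(self, t):
        return self.voltage(t)

    def segments(self, t0: float, t1: float) -> Iterator[Segment]:
        """Yield (start, end, V(t)) pieces covering [t0, t1]."""
        raise NotImplementedError

    def _split(self, t0: float, t1: float, boundaries: Sequence[float]) -> list[float]:
        pts = [t0] + [b for b in boundaries if t0 < b < t1] + [t1]
        return sorted(set(pts))


@dataclass(frozen=True)
class ConstantWaveform(_WaveformBase):
    V: float

    def voltage(self, t: float) -> float:
        return self.V

    def segments(self, t0, t1):
        V = self.V
        yield (t0, t1, lambda t: V)


@dataclass(frozen=True)
class StepWaveform(_WaveformBase):
    """Ordered (voltage, duration) steps starting at t = 0, then a final hold.

    ``steps`` is a sequence of (V_mV, duration_ms); after the last step the
    voltage stays at ``V_after`` (defaults to the last step's voltage).
    """

    steps: tuple[tuple[float, float], ...]
    V_after: float | None = None

    def __post_init__(self):
        if not self.steps:
            raise ValueError("StepWaveform needs at least one step")
        for V, dur in self.steps:
            if dur <= 0:
                raise ValueError("step durations must be > 0")

    @property
    def boundaries(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum([d for _, d in self.steps])])

    def voltage(self, t: float) -> float:
        edges = self.boundaries
        if t < edges[0]:
            return self.steps[0][0]
        if t >= edges[-1]:
            return self.V_after if self.V_after is not None else self.steps[-1][0]
        i = int(np.searchsorted(edges, t, side="right")) - 1
        return self.steps[i][0]

    def segments(self, t0, t1):
        for a, b in zip(self._split(t0, t1, self.boundaries.tolist())[:-1],
                        self._split(t0, t1, self.boundaries.tolist())[1:]):
            V = self.voltage(0.5 * (a + b))
            yield (a, b, lambda t, V=V: V)


@dataclass(frozen=True)
class SquareWaveform(_WaveformBase):
    """Periodic square wave: V_high for ``apd`` ms then V_low for ``di`` ms.

    Upstrokes occur at t = k * (apd + di), k = 0, 1, 2, ...
    """

    V_high: float
    V_low: float
    apd: float
    di: float

    def __post_init__(self):
        if self.apd <= 0 or self.di <= 0:
            raise ValueError("apd and di must be > 0")

    @property
    def period(self) -> float:
        return self.apd + self.di

    def voltage(self, t: float) -> float:
        return self.V_high if (t % self.period) < self.apd else self.V_low

    def segments(self, t0, t1):
        bcl = self.period
        k0 = int(np.floor(t0 / bcl))
        k1 = int(np.ceil(t1 / bcl)) + 1
        bounds: list[float] = []
        for k in range(k0, k1):
            bounds.extend([k * bcl, k * bcl + self.apd])
        for a, b in zip(self._split(t0, t1, bounds)[:-1],
                        self._split(t0, t1, bounds)[1:]):
            V = self.voltage(0.5 * (a + b))
            yield (a, b, lambda t, V=V: V)


@dataclass(frozen=True)
class TrapezoidWaveform(_WaveformBase):
    """Periodic trapezoid: linear ramps of ``ramp`` ms flank each plateau.

    The plateau-level interval (including both ramps) spans ``apd`` ms; with
    ramp = 0 this reduces exactly to :class:`SquareWaveform`.
    """

    V_high: float
    V_low: float
    apd: float
    di: float
    ramp: float = 0.0

    def __post_init__(self):
        if self.apd <= 0 or self.di <= 0:
            raise ValueError("apd and di must be > 0")
        if self.ramp < 0 or self.ramp >= self.apd / 2:
            raise ValueError("need 0 <= ramp < apd/2")

    @property
    def period(self) -> float:
        return self.apd + self.di

    def _phase_voltage(self, tau: float) -> float:
        r, apd = self.ramp, self.apd
        if r > 0 and tau < r:
            return self.V_low + (self.V_high - self.V_low) * tau / r
        if r > 0 and apd - r <= tau < apd:
            return self.V_high - (self.V_high - self.V_low) * (tau - (apd - r)) / r
        if tau < apd:
            return self.V_high
        return self.V_low

    def voltage(self, t: float) -> float:
        return self._phase_voltage(t % self.period)

    def segments(self, t0, t1):
        bcl = self.period
        k0 = int(np.floor(t0 / bcl))
        k1 = int(np.ceil(t1 / bcl)) + 1
        bounds: list[float] = []
        for k in range(k0, k1):
            base = k * bcl
            if self.ramp > 0:
                bounds.extend(
                    [base, base + self.ramp, base + self.apd - self.ramp,
                     base + self.apd]
                )
            else:
                bounds.extend([base, base + self.apd])
        for a, b in zip(self._split(t0, t1, bounds)[:-1],
                        self._split(t0, t1, bounds)[1:]):
            yield (a, b, self.voltage)


@dataclass(frozen=True)
class SampledWaveform(_WaveformBase):
    """Sampled trace with linear interpolation between samples."""

    t_samples: tuple[float, ...]
    V_samples: tuple[float, ...]

    def __post_init__(self):
        if len(self.t_samples) != len(self.V_samples) or len(self.t_samples) < 2:
            raise ValueError("need >= 2 samples with matching lengths")
        if np.any(np.diff(self.t_samples) <= 0):
            raise ValueError("sample times must be strictly increasing")

    def voltage(self, t: float) -> float:
        return float(np.interp(t, self.t_samples, self.V_samples))

    def segments(self, t0, t1):
        if t0 < self.t_samples[0] or t1 > self.t_samples[-1]:
            raise ValueError("span outside sampled domain")
        yield (t0, t1, self.voltage)
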