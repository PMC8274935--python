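"""Voltage-clamp protocol simulation and summary measurements.

Implements the standard Na+-channel characterization protocols: steady-state
availability and activation, time to half inactivation (two branches),
activation time constant, tonic block, use-dependent block (dose and
frequency scans), and recovery from use-dependent block, plus the mean
squared error metric used for fitting.

On a constant-voltage segment m and h are uncoupled linear ODEs with exact
exponential solutions; only the drug-bound fraction b requires numerics (a
scalar ODE driven by the analytic h(t)).  The protocol engine exploits this,
so drug-free protocols are fully closed-form and fast enough to sit inside an
optimizer loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .gating import (
    ChannelParams,
    ChannelState,
    DrugParams,
    GatingRateParams,
    SimulationError,
    b_equilibrium,
    equilibrium,
    rates,
    relax,
    steady_state,
)

__all__ = [
    "ClampDataset",
    "EquilibrationWarning",
    "TrainConvergenceWarning",
    "steady_state_availability",
    "steady_state_activation",
    "time_to_half_inactivation",
    "activation_tau",
    "tonic_block",
    "use_dependent_block",
    "udb_dose_scan",
    "udb_frequency_scan",
    "recovery_from_udb",
    "sse",
    "model_curve",
    "FITTABLE_TAGS",
]

#: sampling interval (ms) for peak detection during test pulses
PEAK_SAMPLE_DT = 0.01


class EquilibrationWarning(UserWarning):
    """A hold was too short to equilibrate gating or drug binding."""


class TrainConvergenceWarning(UserWarning):
    """A pulse train ended before its peaks reached steady state."""


@dataclass
class ClampDataset:
    """An x-y curve produced by a protocol or consumed by the fitter.

    ``config`` stores the protocol keyword arguments needed to regenerate the
    model curve at arbitrary x (used by the fitter and by CSV sidecar files).
    """

    tag: str
    x: np.ndarray
    y: np.ndarray
    weights: np.ndarray | None = None
    config: dict = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.x.shape:
                raise ValueError("weights must match x length")

    def __len__(self):
        return self.x.size


# ---------------------------------------------------------------------------
# segment engine: analytic m/h, scalar-numeric b
# ---------------------------------------------------------------------------

def _hold_traces(state: ChannelState, V: float, t: np.ndarray,
                 p: GatingRateParams, d: DrugParams):
    """(m, h, b) arrays on time grid ``t`` (from 0) at constant voltage."""
    m_inf, h_inf, tau_m, tau_h = steady_state(V, p)
    m = relax(state.m, m_inf, tau_m, t)
    h = relax(state.h, h_inf, tau_h, t)
    conc = d.concentration
    if conc == 0.0:
        b = state.b * np.exp(-d.k_off * t)
    else:
        kon_c = d.k_on * conc

        def rhs(tt, y):
            h_t = h_inf + (state.h - h_inf) * np.exp(-tt / tau_h)
            return kon_c * (1.0 - h_t) * (1.0 - y[0]) - d.k_off * y[0]

        sol = solve_ivp(rhs, (0.0, float(t[-1])), [state.b], method="LSODA",
                        rtol=1e-8, atol=1e-12, t_eval=t)
        if not sol.success:
            raise SimulationError(f"b integration failed at V={V}: {sol.message}")
        b = np.clip(sol.y[0], 0.0, 1.0)
    return m, h, b


def _step(state: ChannelState, V: float, dur: float,
          p: GatingRateParams, d: DrugParams) -> ChannelState:
    """Propagate a state through ``dur`` ms at constant voltage (endpoint only)."""
    m, h, b = _hold_traces(state, V, np.array([0.0, dur]), p, d)
    return ChannelState(m=float(m[-1]), h=float(h[-1]), b=float(b[-1]))


def _pulse_grid(V: float, dur: float, p: GatingRateParams) -> np.ndarray:
    """Sampling grid for peak detection within a test pulse.

    Uniform PEAK_SAMPLE_DT spacing, refined geometrically near the pulse
    onset (relative to tau_m at the pulse potential) so that peaks earlier
    than the uniform spacing are still resolved.
    """
    n = max(int(np.ceil(dur / PEAK_SAMPLE_DT)), 2)
    coarse = np.linspace(0.0, dur, n + 1)
    tau_m = float(steady_state(V, p)[2])
    dt0 = min(max(tau_m / 50.0, 1e-9), dur / 10.0)
    fine = np.geomspace(dt0, dur, 400)
    return np.unique(np.concatenate([[0.0], fine, coarse]))


def _pulse_peak(state: ChannelState, V: float, dur: float,
                p: GatingRateParams, d: DrugParams,
                channel: ChannelParams, measure: str):
    """(peak, t_peak, trace t, trace g) for one test pulse."""
    t = _pulse_grid(V, dur, p)
    m, h, b = _hold_traces(state, V, t, p, d)
    g = channel.g_max * m**3 * h * (1.0 - b)
    if measure == "current":
        y = np.abs(g * (V - channel.E_Na))
    elif measure == "conductance":
        y = g
    else:
        raise ValueError("measure must be 'conductance' or 'current'")
    i = int(np.argmax(y))
    end_state = ChannelState(m=float(m[-1]), h=float(h[-1]), b=float(b[-1]))
    return float(y[i]), float(t[i]), end_state, t, y


def _peaks_drug_free(m0, h0, V: float, dur: float, p: GatingRateParams,
                     channel: ChannelParams, measure: str) -> np.ndarray:
    """Vectorized drug-free test-pulse peaks for arrays of initial states."""
    m0 = np.atleast_1d(np.asarray(m0, dtype=float))
    h0 = np.atleast_1d(np.asarray(h0, dtype=float))
    t = _pulse_grid(V, dur, p)
    m_inf, h_inf, tau_m, tau_h = steady_state(V, p)
    decay_m = np.exp(-t / tau_m)
    decay_h = np.exp(-t / tau_h)
    m = m_inf + (m0[:, None] - m_inf) * decay_m[None, :]
    h = h_inf + (h0[:, None] - h_inf) * decay_h[None, :]
    g = channel.g_max * m**3 * h
    if measure == "current":
        g = np.abs(g * (V - channel.E_Na))
    elif measure != "conductance":
        raise ValueError("measure must be 'conductance' or 'current'")
    return g.max(axis=1)


def _resolve_drug(d: DrugParams | None) -> DrugParams:
    return d if d is not None else DrugParams()


def _initial_state(V_hold: float, hold_ms: float | None, analytic: bool,
                   p: GatingRateParams, d: DrugParams,
                   start: ChannelState | None = None) -> ChannelState:
    """Equilibrate at a holding potential, analytically or by simulation."""
    if analytic or hold_ms is None:
        return equilibrium(V_hold, p, d)
    _, _, _, tau_h = steady_state(V_hold, p)
    need = 5.0 * float(tau_h)
    if d.concentration > 0:
        m_inf, h_inf, _, _ = steady_state(V_hold, p)
        tau_b = 1.0 / ((1.0 - h_inf) * d.concentration * d.k_on + d.k_off)
        need = max(need, 5.0 * float(tau_b))
    if hold_ms < need:
        warnings.warn(
            f"hold of {hold_ms:g} ms at {V_hold:g} mV is shorter than 5x the "
            f"slowest relevant time constant ({need:.1f} ms)",
            EquilibrationWarning, stacklevel=3,
        )
    s = start if start is not None else equilibrium(V_hold, p, DrugParams())
    return _step(s, V_hold, hold_ms, p, d)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def steady_state_availability(
    p: GatingRateParams,
    d: DrugParams | None = None,
    prepulse_range: Sequence[float] | None = None,
    prepulse_ms: float = 1000.0,
    test_V: float = -20.0,
    test_ms: float = 20.0,
    *,
    holding_V: float = -100.0,
    analytic_equilibration: bool = True,
    measure: str = "conductance",
    channel: ChannelParams | None = None,
) -> ClampDataset:
    """Steady-state availability: prepulse to each V, test-pulse peak, max-normalized.

    With ``analytic_equilibration`` each sweep starts from the exact fixed
    point at its prepulse potential (exact for constant holds and much faster
    than simulating multi-second holds).
    """
    d = _resolve_drug(d)
    channel = channel or ChannelParams()
    if prepulse_range is None:
        prepulse_range = np.arange(-120.0, -35.0, 5.0)
    prepulse_range = np.asarray(prepulse_range, dtype=float)
    if d.concentration == 0.0 and analytic_equilibration:
        ss = [steady_state(V_pre, p) for V_pre in prepulse_range]
        peaks = _peaks_drug_free(
            np.array([s[0] for s in ss]), np.array([s[1] for s in ss]),
            test_V, test_ms, p, channel, measure)
    else:
        peaks = np.empty_like(prepulse_range)
        for i, V_pre in enumerate(prepulse_range):
            s0 = _initial_state(V_pre, prepulse_ms, analytic_equilibration, p, d)
            peaks[i], _, _, _, _ = _pulse_peak(s0, test_V, test_ms, p, d,
                                               channel, measure)
    flagged = [int(i) for i in np.nonzero(peaks <= 1e-12)[0]]
    y = peaks / peaks.max()
    return ClampDataset(
        tag="availability", x=prepulse_range, y=y,
        config=dict(prepulse_ms=prepulse_ms, test_V=test_V, test_ms=test_ms,
                    holding_V=holding_V, drug_conc_uM=d.concentration * 1e6,
                    analytic_equilibration=analytic_equilibration,
                    measure=measure, flagged_sweeps=flagged),
    )


def steady_state_activation(
    p: GatingRateParams,
    test_range: Sequence[float] | None = None,
    holding_V: float = -120.0,
    test_ms: float = 20.0,
    *,
    d: DrugParams | None = None,
    measure: str = "conductance",
    channel: ChannelParams | None = None,
) -> ClampDataset:
    """Steady-state activation: test-pulse peak at each potential, max-normalized."""
    d = _resolve_drug(d)
    channel = channel or ChannelParams()
    if test_range is None:
        test_range = np.arange(-60.0, 25.0, 5.0)
    test_range = np.asarray(test_range, dtype=float)
    s0 = equilibrium(holding_V, p, d)
    peaks = np.empty_like(test_range)
    for i, V in enumerate(test_range):
        if d.concentration == 0.0:
            peaks[i] = _peaks_drug_free(s0.m, s0.h, V, test_ms, p, channel,
                                        measure)[0]
        else:
            peaks[i], _, _, _, _ = _pulse_peak(s0, V, test_ms, p, d, channel,
                                               measure)
    flagged = [int(i) for i in np.nonzero(peaks <= 1e-12)[0]]
    y = peaks / peaks.max()
    return ClampDataset(
        tag="activation", x=test_range, y=y,
        config=dict(holding_V=holding_V, test_ms=test_ms,
                    measure=measure, flagged_sweeps=flagged),
    )


def time_to_half_inactivation(
    p: GatingRateParams,
    V: float,
    *,
    branch_threshold: float = -60.0,
    holding_V: float = -120.0,
    conditioning_V: float = -20.0,
    test_V: float = -20.0,
    test_ms: float = 20.0,
    channel: ChannelParams | None = None,
) -> float:
    """Time to half inactivation (ms), drug-free.

    Depolarized branch (V above ``branch_threshold``): time from the peak of
    the test-pulse conductance to 50% of peak within the pulse.  Hyperpolarized
    branch: time for the recovery-time-course availability to reach halfway
    from its post-conditioning value toward the recovered steady state.
    """
    channel = channel or ChannelParams()
    d = DrugParams()
    if V > branch_threshold:
        s0 = equilibrium(holding_V, p, d)
        _, _, tau_m, tau_h = steady_state(V, p)
        span = max(20.0 * float(tau_m + tau_h), 2.0)
        for _ in range(3):
            n = min(max(int(span / PEAK_SAMPLE_DT), 200), 400_000)
            t = np.linspace(0.0, span, n + 1)
            m, h, b = _hold_traces(s0, V, t, p, d)
            g = m**3 * h
            i_pk = int(np.argmax(g))
            tail = g[i_pk:]
            below = np.nonzero(tail <= 0.5 * g[i_pk])[0]
            if below.size:
                j = below[0]
                # linear interpolation of the crossing
                if j == 0:
                    return 0.0
                t_hi, t_lo = t[i_pk + j - 1], t[i_pk + j]
                g_hi, g_lo = tail[j - 1], tail[j]
                frac = (g_hi - 0.5 * g[i_pk]) / (g_hi - g_lo)
                return float(t_hi + frac * (t_lo - t_hi) - t[i_pk])
            span *= 5.0
        raise SimulationError(
            f"conductance did not decay to half within {span:.0f} ms at {V} mV"
        )
    # hyperpolarized branch: recovery time course
    s_cond = equilibrium(conditioning_V, p, d)
    m_inf, h_inf, tau_m, tau_h = steady_state(V, p)
    intervals = np.concatenate([[0.0], np.geomspace(tau_h / 50.0, 12.0 * tau_h, 40)])
    m_rec = relax(s_cond.m, m_inf, tau_m, intervals)
    h_rec = relax(s_cond.h, h_inf, tau_h, intervals)
    peaks = _peaks_drug_free(m_rec, h_rec, test_V, test_ms, p, channel,
                             "conductance")
    peak_inf = _peaks_drug_free(m_inf, h_inf, test_V, test_ms, p, channel,
                                "conductance")[0]
    target = 0.5 * (peaks[0] + peak_inf)
    curve = PchipInterpolator(intervals, peaks - target)
    if curve(intervals[-1]) < 0:
        raise SimulationError(
            f"recovery did not reach half within {intervals[-1]:.0f} ms at {V} mV"
        )
    return float(brentq(curve, intervals[0], intervals[-1]))


def activation_tau(p: GatingRateParams, V) -> float | np.ndarray:
    """Activation time constant tau_m = 1 / (alpha_m + beta_m) in ms."""
    am, bm, _, _ = rates(V, p)
    out = 1.0 / (am + bm)
    return out if np.ndim(out) else float(out)


def tonic_block(
    p: GatingRateParams,
    d: DrugParams,
    holding_V: float = -100.0,
    equilibration_ms: float | None = None,
    test_V: float = -20.0,
    test_ms: float = 20.0,
    *,
    analytic_equilibration: bool = True,
    channel: ChannelParams | None = None,
) -> float:
    """Fraction blocked at rest: 1 - (peak with drug) / (peak drug-free)."""
    channel = channel or ChannelParams()
    d0 = DrugParams(k_on=d.k_on, k_off=d.k_off, concentration=0.0)
    s_drug = _initial_state(holding_V, equilibration_ms, analytic_equilibration, p, d)
    s_free = _initial_state(holding_V, equilibration_ms, analytic_equilibration, p, d0)
    pk_drug, _, _, _, _ = _pulse_peak(s_drug, test_V, test_ms, p, d, channel,
                                      "conductance")
    pk_free, _, _, _, _ = _pulse_peak(s_free, test_V, test_ms, p, d0, channel,
                                      "conductance")
    return 1.0 - pk_drug / pk_free


def use_dependent_block(
    p: GatingRateParams,
    d: DrugParams,
    freq_Hz: float = 10.0,
    pulse_V: float = -20.0,
    pulse_ms: float = 25.0,
    holding_V: float = -100.0,
    n_pulses: int = 25,
    *,
    channel: ChannelParams | None = None,
) -> tuple[np.ndarray, float]:
    """Pulse-train block: per-pulse peaks normalized to pulse 1, and the UDB level.

    UDB = 1 - (steady-state peak) / (first peak).  The train starts from the
    tonic equilibrium at the holding potential, so UDB measures block
    accumulated in excess of tonic block.
    """
    channel = channel or ChannelParams()
    period = 1000.0 / freq_Hz
    if period <= pulse_ms:
        raise ValueError("pacing period must exceed pulse duration")
    state = equilibrium(holding_V, p, d)
    peaks = np.empty(n_pulses)
    for k in range(n_pulses):
        peaks[k], _, state, _, _ = _pulse_peak(state, pulse_V, pulse_ms, p, d,
                                               channel, "conductance")
        state = _step(state, holding_V, period - pulse_ms, p, d)
    if n_pulses >= 2 and abs(peaks[-1] - peaks[-2]) / peaks[0] > 1e-4:
        warnings.warn(
            f"train of {n_pulses} pulses has not converged "
            f"(last step {abs(peaks[-1] - peaks[-2]) / peaks[0]:.2e})",
            TrainConvergenceWarning, stacklevel=2,
        )
    normalized = peaks / peaks[0]
    return normalized, float(1.0 - normalized[-1])


def udb_dose_scan(p, d, concentrations_uM, **kwargs) -> ClampDataset:
    """Use-dependent block level versus drug concentration (uM)."""
    concentrations_uM = np.asarray(concentrations_uM, dtype=float)
    y = np.array([
        use_dependent_block(p, d.with_concentration_uM(c), **kwargs)[1]
        for c in concentrations_uM
    ])
    return ClampDataset(tag="udb_dose", x=concentrations_uM, y=y,
                        config=dict(kwargs))


def udb_frequency_scan(p, d, freqs_Hz=(1.0, 2.0, 5.0, 10.0), **kwargs) -> ClampDataset:
    """Use-dependent block level versus pacing frequency at fixed concentration."""
    freqs_Hz = np.asarray(freqs_Hz, dtype=float)
    y = np.array([
        use_dependent_block(p, d, freq_Hz=f, **kwargs)[1] for f in freqs_Hz
    ])
    return ClampDataset(tag="udb_freq", x=freqs_Hz, y=y,
                        config=dict(kwargs, drug_conc_uM=d.concentration * 1e6))


def recovery_from_udb(
    p: GatingRateParams,
    d: DrugParams,
    intervals_ms: Sequence[float],
    recovery_V: float = -100.0,
    *,
    conditioning_freq_Hz: float = 10.0,
    conditioning_pulses: int = 30,
    pulse_V: float = -20.0,
    pulse_ms: float = 25.0,
    test_V: float = -20.0,
    test_ms: float = 20.0,
    channel: ChannelParams | None = None,
) -> ClampDataset:
    """Recovery of availability after a conditioning train.

    y = test-pulse peak after each recovery interval, normalized to the
    unconditioned drug-free peak at the recovery potential.
    """
    channel = channel or ChannelParams()
    period = 1000.0 / conditioning_freq_Hz
    state = equilibrium(recovery_V, p, d)
    for _ in range(conditioning_pulses):
        _, _, state, _, _ = _pulse_peak(state, pulse_V, pulse_ms, p, d,
                                        channel, "conductance")
        state = _step(state, recovery_V, period - pulse_ms, p, d)
    d0 = DrugParams(k_on=d.k_on, k_off=d.k_off, concentration=0.0)
    ref_peak, _, _, _, _ = _pulse_peak(equilibrium(recovery_V, p, d0), test_V,
                                       test_ms, p, d0, channel, "conductance")
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    y = np.empty_like(intervals_ms)
    for i, dt in enumerate(intervals_ms):
        s = state if dt == 0 else _step(state, recovery_V, dt, p, d)
        pk, _, _, _, _ = _pulse_peak(s, test_V, test_ms, p, d, channel,
                                     "conductance")
        y[i] = pk / ref_peak
    return ClampDataset(
        tag="recovery_udb", x=intervals_ms, y=y,
        config=dict(recovery_V=recovery_V, drug_conc_uM=d.concentration * 1e6,
                    conditioning_freq_Hz=conditioning_freq_Hz,
                    conditioning_pulses=conditioning_pulses,
                    pulse_V=pulse_V, pulse_ms=pulse_ms,
                    test_V=test_V, test_ms=test_ms),
    )


def sse(model_y, data_y) -> float:
    """Mean of squared model-data differences, (1/n) * sum((y_i - x_i)^2)."""
    model_y = np.asarray(model_y, dtype=float)
    data_y = np.asarray(data_y, dtype=float)
    if model_y.shape != data_y.shape:
        raise ValueError("length mismatch between model and data")
    return float(np.mean((model_y - data_y) ** 2))


# ---------------------------------------------------------------------------
# fitter dispatch
# ---------------------------------------------------------------------------

#: tags the drug-free fitter knows how to regenerate from a parameter set
FITTABLE_TAGS = ("availability", "activation", "t_half", "activation_tau")


def model_curve(tag: str, x, p: GatingRateParams,
                config: dict | None = None) -> np.ndarray:
    """Model prediction at the dataset's x values for a fittable protocol tag."""
    config = dict(config or {})
    config.pop("flagged_sweeps", None)
    config.pop("drug_conc_uM", None)
    x = np.asarray(x, dtype=float)
    if tag == "availability":
        config.pop("analytic_equilibration", None)
        return steady_state_availability(
            p, prepulse_range=x, analytic_equilibration=True, **config
        ).y
    if tag == "activation":
        return steady_state_activation(p, test_range=x, **config).y
    if tag == "t_half":
        return np.array([time_to_half_inactivation(p, V, **config) for V in x])
    if tag == "activation_tau":
        return np.asarray(activation_tau(p, x))
    raise KeyError(f"unknown protocol tag {tag!r}; fittable tags: {FITTABLE_TAGS}")
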