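"""Three-variable sodium-channel model: m^3*h Hodgkin-Huxley gating plus a
drug-bound fraction b.

The open, unblocked fraction is ``f_open = m**3 * h * (1 - b)`` and the
current is ``I = g_max * f_open * (V - E_Na)``.  Gating rates have the form
``c1 * exp(V / c2)``; the drug-bound fraction obeys

    db/dt = k_on * [D] * (1 - h) * (1 - b) - k_off * b

i.e. the drug binds only to inactivated channels and locks them inactivated
until it unbinds.  Internal units are mV, ms and molar throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "EXP_ARG_CAP",
    "GatingRateParams",
    "DrugParams",
    "ChannelParams",
    "ChannelState",
    "Trajectory",
    "OverflowGuardWarning",
    "SimulationError",
    "rates",
    "steady_state",
    "f_open",
    "current",
    "derivatives",
    "equilibrium",
    "integrate",
    "dissociation_constant",
    "charged_fraction",
    "relax",
]

#: Cap on |V / c2| inside the rate-constant exponentials.  Exceeding it is a
#: sign of optimizer excursions, not physiology; the argument is clipped and a
#: warning emitted so the evaluation stays finite.
EXP_ARG_CAP = 50.0


class OverflowGuardWarning(UserWarning):
    """A rate-constant exponential argument was clipped at ``EXP_ARG_CAP``."""


class SimulationError(RuntimeError):
    """Raised when an ODE integration fails or produces out-of-range states."""


def _capped_exp(arg: np.ndarray | float) -> np.ndarray | float:
    a = np.asarray(arg, dtype=float)
    if np.any(np.abs(a) > EXP_ARG_CAP):
        warnings.warn(
            f"rate exponent clipped at |arg| = {EXP_ARG_CAP}",
            OverflowGuardWarning,
            stacklevel=3,
        )
        a = np.clip(a, -EXP_ARG_CAP, EXP_ARG_CAP)
    out = np.exp(a)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GatingRateParams:
    """The eight drug-free gating coefficients.

    Each rate constant ``r(V) = c1_r * exp(V / c2_r)`` (c1 in 1/ms, c2 in mV).
    Sign convention: ``c2_alpha_m > 0``, ``c2_beta_m < 0`` (activation opens
    with depolarization) and ``c2_alpha_h < 0``, ``c2_beta_h > 0``
    (inactivation closes with depolarization), so that m_inf is increasing and
    h_inf decreasing in V.
    """

    c1_alpha_m: float
    c2_alpha_m: float
    c1_beta_m: float
    c2_beta_m: float
    c1_alpha_h: float
    c2_alpha_h: float
    c1_beta_h: float
    c2_beta_h: float

    def __post_init__(self) -> None:
        for name in ("c1_alpha_m", "c1_beta_m", "c1_alpha_h", "c1_beta_h"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        for name in ("c2_alpha_m", "c2_beta_m", "c2_alpha_h", "c2_beta_h"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v != 0):
                raise ValueError(f"{name} must be finite and nonzero, got {v}")
        if not (self.c2_alpha_m > 0 and self.c2_beta_m < 0):
            raise ValueError("sign convention: c2_alpha_m > 0 and c2_beta_m < 0")
        if not (self.c2_alpha_h < 0 and self.c2_beta_h > 0):
            raise ValueError("sign convention: c2_alpha_h < 0 and c2_beta_h > 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.c1_alpha_m, self.c2_alpha_m,
                self.c1_beta_m, self.c2_beta_m,
                self.c1_alpha_h, self.c2_alpha_h,
                self.c1_beta_h, self.c2_beta_h,
            ]
        )

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "GatingRateParams":
        a = np.asarray(a, dtype=float)
        if a.shape != (8,):
            raise ValueError("expected 8 coefficients")
        return cls(*a.tolist())

    FIELD_ORDER = (
        "c1_alpha_m", "c2_alpha_m", "c1_beta_m", "c2_beta_m",
        "c1_alpha_h", "c2_alpha_h", "c1_beta_h", "c2_beta_h",
    )


@dataclass(frozen=True)
class DrugParams:
    """Drug binding kinetics: k_on (1/(M*ms)), k_off (1/ms), concentration (M)."""

    k_on: float = 250.0
    k_off: float = 1.7e-3
    concentration: float = 0.0

    def __post_init__(self) -> None:
        if not self.k_on > 0:
            raise ValueError("k_on must be > 0")
        if not self.k_off > 0:
            raise ValueError("k_off must be > 0")
        if self.concentration < 0:
            raise ValueError(
                "concentration must be >= 0 (note: internal unit is molar; "
                "use with_concentration_uM for micromolar input)"
            )

    def with_concentration_uM(self, conc_uM: float) -> "DrugParams":
        return replace(self, concentration=conc_uM * 1e-6)

    def scaled(self, sigma: float) -> "DrugParams":
        """Scale both binding rates by a common factor (time rescaling)."""
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        return replace(self, k_on=self.k_on * sigma, k_off=self.k_off * sigma)


@dataclass(frozen=True)
class ChannelParams:
    """Maximal conductance (arbitrary units, default normalized) and reversal."""

    g_max: float = 1.0
    E_Na: float = 70.0

    def __post_init__(self) -> None:
        if not self.g_max > 0:
            raise ValueError("g_max must be > 0")


@dataclass(frozen=True)
class ChannelState:
    """Gating/block fractions (m, h, b), each in [0, 1]."""

    m: float
    h: float
    b: float = 0.0
    t: float | None = None

    def __post_init__(self) -> None:
        for name in ("m", "h", "b"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.m, self.h, self.b])


def rates(V, p: GatingRateParams):
    """Evaluate (alpha_m, beta_m, alpha_h, beta_h) at voltage ``V`` (mV).

    Accepts scalars or arrays.  Exponent arguments are clipped at
    ``EXP_ARG_CAP`` with an :class:`OverflowGuardWarning`.
    """
    am = p.c1_alpha_m * _capped_exp(np.asarray(V) / p.c2_alpha_m)
    bm = p.c1_beta_m * _capped_exp(np.asarray(V) / p.c2_beta_m)
    ah = p.c1_alpha_h * _capped_exp(np.asarray(V) / p.c2_alpha_h)
    bh = p.c1_beta_h * _capped_exp(np.asarray(V) / p.c2_beta_h)
    return am, bm, ah, bh


def steady_state(V, p: GatingRateParams):
    """Return (m_inf, h_inf, tau_m, tau_h) at ``V``; tau = 1/(alpha+beta)."""
    am, bm, ah, bh = rates(V, p)
    tau_m = 1.0 / (am + bm)
    tau_h = 1.0 / (ah + bh)
    return am * tau_m, ah * tau_h, tau_m, tau_h


def f_open(s: ChannelState) -> float:
    """Open, unblocked fraction m^3 * h * (1 - b)."""
    return s.m**3 * s.h * (1.0 - s.b)


def current(V: float, s: ChannelState, c: ChannelParams) -> float:
    """Macroscopic current g_max * f_open * (V - E_Na)."""
    return c.g_max * f_open(s) * (V - c.E_Na)


def derivatives(V: float, s: ChannelState, p: GatingRateParams, d: DrugParams):
    """(dm/dt, dh/dt, db/dt) in 1/ms at fixed voltage."""
    am, bm, ah, bh = rates(V, p)
    dm = am * (1.0 - s.m) - bm * s.m
    dh = ah * (1.0 - s.h) - bh * s.h
    db = d.k_on * d.concentration * (1.0 - s.h) * (1.0 - s.b) - d.k_off * s.b
    return dm, dh, db


def b_equilibrium(h_inf: float, d: DrugParams) -> float:
    """Steady drug-bound fraction given the non-inactivated fraction h_inf."""
    kon_eff = (1.0 - h_inf) * d.concentration * d.k_on
    return kon_eff / (kon_eff + d.k_off)


def equilibrium(V: float, p: GatingRateParams, d: DrugParams) -> ChannelState:
    """Fixed point (m_inf, h_inf, b_inf) of the model at constant voltage."""
    m_inf, h_inf, _, _ = steady_state(V, p)
    return ChannelState(m=float(m_inf), h=float(h_inf), b=b_equilibrium(float(h_inf), d))


def dissociation_constant(d: DrugParams) -> float:
    """Dissociation constant k_off / k_on in molar."""
    return d.k_off / d.k_on


def charged_fraction(pH: float, pKa: float = 7.6) -> float:
    """Henderson-Hasselbalch protonated (charged) fraction 1/(1+10^(pH-pKa))."""
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def relax(x0, x_inf, tau, t):
    """Closed-form scalar relaxation x_inf + (x0 - x_inf) * exp(-t/tau)."""
    return x_inf + (x0 - x_inf) * np.exp(-np.asarray(t, dtype=float) / tau)


# ---------------------------------------------------------------------------
# Trajectory integration
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-indexed model state produced by :func:`integrate`."""

    t: np.ndarray
    V: np.ndarray
    m: np.ndarray
    h: np.ndarray
    b: np.ndarray
    channel: ChannelParams = field(default_factory=ChannelParams)

    @property
    def f_open(self) -> np.ndarray:
        return self.m**3 * self.h * (1.0 - self.b)

    @property
    def conductance(self) -> np.ndarray:
        return self.channel.g_max * self.f_open

    @property
    def I_Na(self) -> np.ndarray:
        return self.channel.g_max * self.f_open * (self.V - self.channel.E_Na)

    def final_state(self) -> ChannelState:
        return ChannelState(
            m=float(self.m[-1]), h=float(self.h[-1]), b=float(self.b[-1]),
            t=float(self.t[-1]),
        )

    def concat(self, other: "Trajectory") -> "Trajectory":
        return Trajectory(
            t=np.concatenate([self.t, other.t]),
            V=np.concatenate([self.V, other.V]),
            m=np.concatenate([self.m, other.m]),
            h=np.concatenate([self.h, other.h]),
            b=np.concatenate([self.b, other.b]),
            channel=self.channel,
        )


def _clip_unit(y: np.ndarray, atol: float, t_ref: float) -> np.ndarray:
    """Clip round-off excursions out of [0,1]; large excursions are bugs."""
    excess = np.maximum(y - 1.0, 0.0) + np.maximum(-y, 0.0)
    worst = float(np.max(excess))
    if worst > 100.0 * atol:
        raise SimulationError(
            f"state left [0,1] by {worst:.3e} near t = {t_ref:.6g} ms "
            f"(> 100*atol = {100 * atol:.1e}); model or solver bug"
        )
    return np.clip(y, 0.0, 1.0)


def _integrate_segment(
    V_of_t: Callable[[float], float],
    t0: float,
    t1: float,
    y0: np.ndarray,
    p: GatingRateParams,
    d: DrugParams,
    rtol: float,
    atol: float,
    t_eval: np.ndarray | None,
    pin_h: bool,
) -> tuple[np.ndarray, np.ndarray]:
    def rhs(t, y):
        V = V_of_t(t0 + t)
        am, bm, ah, bh = rates(V, p)
        m, h, b = y
        if pin_h:
            h = ah / (ah + bh)
            dh = 0.0
        else:
            dh = ah * (1.0 - h) - bh * h
        dm = am * (1.0 - m) - bm * m
        db = d.k_on * d.concentration * (1.0 - h) * (1.0 - b) - d.k_off * b
        return (dm, dh, db)

    if pin_h:
        am, bm, ah, bh = rates(V_of_t(t0), p)
        y0 = np.array([y0[0], ah / (ah + bh), y0[2]])
    # BDF rather than LSODA: the model is stiff (tau_m is microseconds while
    # tau_b is hundreds of ms) and scipy's LSODA wrapper proved non-reentrant
    # across back-to-back segment solves (step size collapse after a ramp).
    # Each segment is solved in local time so the solver's minimum step bound
    # (proportional to |t|) does not tighten as absolute time grows.
    local_t_eval = None if t_eval is None else t_eval - t0
    sol = solve_ivp(
        rhs, (0.0, t1 - t0), y0, method="BDF", rtol=rtol, atol=atol,
        t_eval=local_t_eval, dense_output=False,
    )
    if not sol.success:
        raise SimulationError(f"solver failed in [{t0}, {t1}] ms: {sol.message}")
    return sol.t + t0, sol.y


def integrate(
    waveform,
    s0: ChannelState,
    span: tuple[float, float],
    p: GatingRateParams,
    d: DrugParams | None = None,
    *,
    channel: ChannelParams | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    sample_dt: float | None = None,
    pin_h_to_steady_state: bool = False,
) -> Trajectory:
    """Integrate the (m, h, b) ODEs under a voltage waveform.

    The waveform is split at its segment boundaries (see
    :mod:`nablock.waveforms`) and each segment integrated separately with a
    stiff-capable solver, so voltage discontinuities are handled exactly.

    Parameters
    ----------
    sample_dt
        If given, states are reported on a uniform grid of this spacing within
        each segment; otherwise the solver's own steps are reported.
    pin_h_to_steady_state
        Hold h at h_inf(V(t)) instead of integrating it (the square-wave
        approximation used by the rate-dependence analysis).
    """
    d = d or DrugParams()
    channel = channel or ChannelParams()
    t0, t1 = float(span[0]), float(span[1])
    if t1 <= t0:
        raise ValueError("span must have positive length")

    y = s0.as_array()
    ts: list[np.ndarray] = []
    Vs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for seg_t0, seg_t1, v_fun in waveform.segments(t0, t1):
        if seg_t1 <= seg_t0:
            continue
        if sample_dt is not None:
            n = max(int(np.ceil((seg_t1 - seg_t0) / sample_dt)), 1)
            t_eval = np.linspace(seg_t0, seg_t1, n + 1)
        else:
            t_eval = None
        seg_t, seg_y = _integrate_segment(
            v_fun, seg_t0, seg_t1, y, p, d, rtol, atol, t_eval,
            pin_h_to_steady_state,
        )
        seg_y = _clip_unit(seg_y, atol, seg_t[-1])
        y = seg_y[:, -1]
        ts.append(seg_t)
        Vs.append(np.array([v_fun(t) for t in seg_t]))
        ys.append(seg_y)
    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    return Trajectory(
        t=t_all, V=np.concatenate(Vs),
        m=y_all[0], h=y_all[1], b=y_all[2], channel=channel,
    )
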