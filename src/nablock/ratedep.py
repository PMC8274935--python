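"""Closed-form theory of rate-dependent block under periodic pacing.

The action potential is approximated by a square wave alternating between a
plateau potential V_AP (for APD ms) and a diastolic potential V_DI (for DI
ms), with h pinned at its steady state for the phase voltage.  The drug-bound
fraction then relaxes exponentially within each phase,

    b(t) = b_inf(V) - (b_inf(V) - b_start) * exp(-t / tau_b(V)),

with tau_b(V) = 1 / ((1 - h_inf(V)) [D] k_on + k_off) and
b_inf(V) = (1 - h_inf(V)) [D] k_on * tau_b(V).  Composing the two phases over
one cycle and imposing periodicity yields the upstroke-time fixed point

    b* = [(1 - D) / (1 - A D)] b_inf(V_DI)
       + [(1 - A) D / (1 - A D)] b_inf(V_AP),

with A = exp(-APD / tau_b(V_AP)) and D = exp(-DI / tau_b(V_DI)).  This module
provides that fixed point, its BCL-derivative when APD follows a restitution
curve APD = f(BCL), the critical restitution slope at which the derivative
changes sign, scans and sensitivities, and the independent numerical oracles
(iterated pacing map, ODE pacing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .gating import (
    ChannelState,
    DrugParams,
    GatingRateParams,
    b_equilibrium,
    integrate,
    steady_state,
)
from .waveforms import SquareWaveform, TrapezoidWaveform

__all__ = [
    "SquareWaveAP",
    "RestitutionCurve",
    "BindingEnv",
    "tau_b",
    "b_inf",
    "binding_env",
    "b_transient",
    "b_star",
    "b_star_from_env",
    "b_star_at_bcl",
    "iterate_pacing_map",
    "ode_pace",
    "db_star_dbcl",
    "eq6_bracket",
    "critical_slope",
    "critical_slope_from_env",
    "scan_b_star",
    "db_star_dV",
    "rate_scaling_pair",
]

DEFAULT_V_AP = 20.0
DEFAULT_V_DI = -85.0


@dataclass(frozen=True)
class SquareWaveAP:
    """Square-wave action potential descriptor; upstrokes at t_k = k * BCL."""

    V_AP: float = DEFAULT_V_AP
    V_DI: float = DEFAULT_V_DI
    APD: float = 300.0
    DI: float = 450.0

    def __post_init__(self):
        if self.APD <= 0 or self.DI <= 0:
            raise ValueError("APD and DI must be > 0")
        if not self.V_AP > self.V_DI:
            raise ValueError("V_AP must exceed V_DI")

    @property
    def BCL(self) -> float:
        return self.APD + self.DI

    def waveform(self) -> SquareWaveform:
        return SquareWaveform(V_high=self.V_AP, V_low=self.V_DI,
                              apd=self.APD, di=self.DI)


class RestitutionCurve:
    """APD = f(BCL) with derivative, from a parametric form or a table.

    Invariants on the stated domain: 0 < f(BCL) < BCL and f nondecreasing.
    """

    def __init__(self, f, dfdbcl, domain: tuple[float, float], label: str = ""):
        self._f = f
        self._df = dfdbcl
        self.domain = (float(domain[0]), float(domain[1]))
        self.label = label
        self._validate()

    def _validate(self, n: int = 101) -> None:
        g = np.linspace(*self.domain, n)
        apd = self(g)
        if np.any(apd <= 0) or np.any(apd >= g):
            raise ValueError("restitution must satisfy 0 < f(BCL) < BCL on its domain")
        if np.any(np.diff(apd) < -1e-9):
            raise ValueError("restitution must be nondecreasing")
        if np.any(self.derivative(g) < -1e-9):
            raise ValueError("restitution slope must be >= 0")

    def _check_domain(self, bcl) -> None:
        bcl = np.asarray(bcl, dtype=float)
        if np.any(bcl < self.domain[0] - 1e-9) or np.any(bcl > self.domain[1] + 1e-9):
            raise ValueError(
                f"BCL outside restitution domain {self.domain}"
            )

    def __call__(self, bcl):
        self._check_domain(bcl)
        return self._f(np.asarray(bcl, dtype=float))

    def derivative(self, bcl):
        self._check_domain(bcl)
        return self._df(np.asarray(bcl, dtype=float))

    @classmethod
    def exponential(cls, apd_max: float, a: float, tau: float,
                    domain: tuple[float, float], label: str = "exponential"
                    ) -> "RestitutionCurve":
        """f(BCL) = apd_max * (1 - a * exp(-BCL / tau))."""

        def f(bcl):
            return apd_max * (1.0 - a * np.exp(-bcl / tau))

        def df(bcl):
            return apd_max * a / tau * np.exp(-bcl / tau)

        return cls(f, df, domain, label)

    @classmethod
    def flat(cls, apd: float, domain: tuple[float, float]) -> "RestitutionCurve":
        return cls(lambda bcl: np.full_like(np.asarray(bcl, float), apd),
                   lambda bcl: np.zeros_like(np.asarray(bcl, float)),
                   domain, "flat")

    @classmethod
    def from_table(cls, bcl: Sequence[float], apd: Sequence[float],
                   label: str = "tabulated") -> "RestitutionCurve":
        """Monotone piecewise-cubic interpolation of tabulated (BCL, APD)."""
        bcl = np.asarray(bcl, dtype=float)
        apd = np.asarray(apd, dtype=float)
        order = np.argsort(bcl)
        interp = PchipInterpolator(bcl[order], apd[order])
        deriv = interp.derivative()
        return cls(interp, deriv, (bcl.min(), bcl.max()), label)

    def scaled(self, sigma: float) -> "RestitutionCurve":
        """The time-rescaled curve APD = f(sigma * BCL) / sigma."""
        return RestitutionCurve(
            lambda bcl: self._f(sigma * np.asarray(bcl, float)) / sigma,
            lambda bcl: self._df(sigma * np.asarray(bcl, float)),
            (self.domain[0] / sigma, self.domain[1] / sigma),
            f"{self.label} (sigma={sigma})",
        )


# ---------------------------------------------------------------------------
# binding environment
# ---------------------------------------------------------------------------

def tau_b(V, p: GatingRateParams, d: DrugParams):
    """Effective drug-binding time constant 1/((1-h_inf)[D]k_on + k_off) in ms."""
    _, h_inf, _, _ = steady_state(V, p)
    return 1.0 / ((1.0 - h_inf) * d.concentration * d.k_on + d.k_off)


def b_inf(V, p: GatingRateParams, d: DrugParams):
    """Steady drug-bound fraction at fixed voltage."""
    _, h_inf, _, _ = steady_state(V, p)
    kon_eff = (1.0 - h_inf) * d.concentration * d.k_on
    return kon_eff / (kon_eff + d.k_off)


@dataclass(frozen=True)
class BindingEnv:
    """Per-phase binding constants and the cycle weight factors A, D."""

    tau_ap: float
    tau_di: float
    binf_ap: float
    binf_di: float
    apd: float
    di: float

    def __post_init__(self):
        if self.tau_ap <= 0 or self.tau_di <= 0:
            raise ValueError("time constants must be > 0")
        if not (0 <= self.binf_ap < 1 and 0 <= self.binf_di < 1):
            raise ValueError("b_inf values must lie in [0, 1)")
        if self.apd <= 0 or self.di <= 0:
            raise ValueError("APD and DI must be > 0")

    @property
    def A(self) -> float:
        return float(np.exp(-self.apd / self.tau_ap))

    @property
    def D(self) -> float:
        return float(np.exp(-self.di / self.tau_di))


def binding_env(square: SquareWaveAP, p: GatingRateParams,
                d: DrugParams) -> BindingEnv:
    return BindingEnv(
        tau_ap=float(tau_b(square.V_AP, p, d)),
        tau_di=float(tau_b(square.V_DI, p, d)),
        binf_ap=float(b_inf(square.V_AP, p, d)),
        binf_di=float(b_inf(square.V_DI, p, d)),
        apd=square.APD, di=square.DI,
    )


def b_transient(t, phase: str, b_start: float, env: BindingEnv):
    """b at time ``t`` after the start of an 'AP' or 'DI' phase."""
    if phase == "AP":
        binf, tau = env.binf_ap, env.tau_ap
    elif phase == "DI":
        binf, tau = env.binf_di, env.tau_di
    else:
        raise ValueError("phase must be 'AP' or 'DI'")
    t = np.asarray(t, dtype=float)
    out = binf - (binf - b_start) * np.exp(-t / tau)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# fixed point and derivative
# ---------------------------------------------------------------------------

def b_star_from_env(env: BindingEnv) -> float:
    """Upstroke-time fixed point: convex combination of the phase asymptotes."""
    A, D = env.A, env.D
    w_di = (1.0 - D) / (1.0 - A * D)
    w_ap = (1.0 - A) * D / (1.0 - A * D)
    return w_di * env.binf_di + w_ap * env.binf_ap


def b_star(square: SquareWaveAP, p: GatingRateParams, d: DrugParams) -> float:
    """Closed-form fraction bound at the upstroke under periodic pacing."""
    return b_star_from_env(binding_env(square, p, d))


def _square_at_bcl(bcl: float, restitution: RestitutionCurve,
                   v_ap: float, v_di: float) -> SquareWaveAP:
    apd = float(restitution(bcl))
    di = bcl - apd
    if apd <= 0 or di <= 0:
        raise ValueError(f"degenerate APD ({apd:g}) or DI ({di:g}) at BCL {bcl:g}")
    return SquareWaveAP(V_AP=v_ap, V_DI=v_di, APD=apd, DI=di)


def b_star_at_bcl(bcl: float, restitution: RestitutionCurve,
                  p: GatingRateParams, d: DrugParams,
                  v_ap: float = DEFAULT_V_AP, v_di: float = DEFAULT_V_DI) -> float:
    """b* at a cycle length, with APD taken from the restitution curve."""
    return b_star(_square_at_bcl(bcl, restitution, v_ap, v_di), p, d)


def iterate_pacing_map(square: SquareWaveAP, p: GatingRateParams, d: DrugParams,
                       b0: float = 0.0, n_cycles: int = 100) -> np.ndarray:
    """Upstroke-time b over successive cycles of the exact one-cycle map.

    Composes the two phase exponentials; converges geometrically to ``b_star``
    with contraction factor A*D per cycle.  Serves as an independent oracle
    for the closed-form fixed point.
    """
    env = binding_env(square, p, d)
    out = np.empty(n_cycles + 1)
    out[0] = b = float(b0)
    for k in range(n_cycles):
        b_end_ap = b_transient(env.apd, "AP", b, env)
        b = float(b_transient(env.di, "DI", b_end_ap, env))
        out[k + 1] = b
    return out


def ode_pace(square: SquareWaveAP, p: GatingRateParams, d: DrugParams,
             b0: float = 0.0, n_cycles: int = 50, *, pin_h: bool = True,
             rtol: float = 1e-10, atol: float = 1e-12,
             waveform=None) -> np.ndarray:
    """Upstroke-time b from numerical integration of the binding ODE.

    With ``pin_h`` (default) h is held at h_inf(V(t)), matching the
    approximation behind the closed-form solution; with ``pin_h=False`` the
    full free-h model is integrated instead.  ``waveform`` may override the
    square wave (e.g. a trapezoid) while keeping the same period.
    """
    w = waveform if waveform is not None else square.waveform()
    bcl = square.BCL
    s0 = ChannelState(m=0.0, h=float(steady_state(square.V_DI, p)[1]), b=b0)
    traj = integrate(
        w, s0, (0.0, n_cycles * bcl), p, d,
        rtol=rtol, atol=atol, pin_h_to_steady_state=pin_h,
    )
    upstroke_b = np.empty(n_cycles + 1)
    for k in range(n_cycles + 1):
        idx = np.searchsorted(traj.t, k * bcl - 1e-9)
        upstroke_b[k] = traj.b[min(idx, traj.t.size - 1)]
    return upstroke_b


def eq6_bracket(env: BindingEnv, slope: float) -> float:
    """The slope-dependent bracket of the BCL-derivative of b*.

    ((1-D) A D / tau_AP) * f'(BCL) - ((1-A) D / tau_DI) * (1 - f'(BCL)).
    Its root in the slope defines the critical restitution slope.
    """
    A, D = env.A, env.D
    return ((1.0 - D) * A * D / env.tau_ap * slope
            - (1.0 - A) * D / env.tau_di * (1.0 - slope))


def db_star_dbcl(bcl: float, restitution: RestitutionCurve,
                 p: GatingRateParams, d: DrugParams,
                 v_ap: float = DEFAULT_V_AP, v_di: float = DEFAULT_V_DI) -> float:
    """d b*/d BCL with APD following the restitution curve (1/ms)."""
    square = _square_at_bcl(bcl, restitution, v_ap, v_di)
    env = binding_env(square, p, d)
    slope = float(restitution.derivative(bcl))
    A, D = env.A, env.D
    prefactor = (env.binf_ap - env.binf_di) / (1.0 - A * D) ** 2
    return prefactor * eq6_bracket(env, slope)


def critical_slope_from_env(env: BindingEnv) -> float:
    """Restitution slope at which the BCL-derivative of b* changes sign.

    Derived as the root of :func:`eq6_bracket` in the slope (the common
    factor D cancels): slope = 1 / (1 + (tau_DI/tau_AP) * (1-D) A / (1-A)).
    """
    A, D = env.A, env.D
    return 1.0 / (1.0 + (env.tau_di / env.tau_ap) * (1.0 - D) * A / (1.0 - A))


def critical_slope(bcl: float, restitution: RestitutionCurve,
                   p: GatingRateParams, d: DrugParams,
                   v_ap: float = DEFAULT_V_AP, v_di: float = DEFAULT_V_DI) -> float:
    """Critical restitution slope at a cycle length."""
    square = _square_at_bcl(bcl, restitution, v_ap, v_di)
    return critical_slope_from_env(binding_env(square, p, d))


def scan_b_star(bcl_grid, restitution: RestitutionCurve,
                p: GatingRateParams, d: DrugParams,
                v_ap: float = DEFAULT_V_AP, v_di: float = DEFAULT_V_DI) -> dict:
    """b*, its BCL-derivative and the critical slope over a BCL grid.

    Per-point domain errors are collected into ``errors`` rather than raised.
    """
    bcl_grid = np.asarray(bcl_grid, dtype=float)
    out = {
        "bcl": bcl_grid,
        "apd": np.full_like(bcl_grid, np.nan),
        "di": np.full_like(bcl_grid, np.nan),
        "b_star": np.full_like(bcl_grid, np.nan),
        "db_star_dbcl": np.full_like(bcl_grid, np.nan),
        "critical_slope": np.full_like(bcl_grid, np.nan),
        "errors": {},
    }
    for i, bcl in enumerate(bcl_grid):
        try:
            square = _square_at_bcl(float(bcl), restitution, v_ap, v_di)
            out["apd"][i] = square.APD
            out["di"][i] = square.DI
            out["b_star"][i] = b_star(square, p, d)
            out["db_star_dbcl"][i] = db_star_dbcl(float(bcl), restitution, p, d,
                                                  v_ap, v_di)
            out["critical_slope"][i] = critical_slope(float(bcl), restitution,
                                                      p, d, v_ap, v_di)
        except ValueError as exc:
            out["errors"][i] = str(exc)
    return out


def db_star_dV(bcl: float, restitution: RestitutionCurve,
               p: GatingRateParams, d: DrugParams,
               which: str = "V_DI",
               v_ap: float = DEFAULT_V_AP, v_di: float = DEFAULT_V_DI,
               step: float = 0.5) -> float:
    """Sensitivity of b* to the plateau or diastolic potential (central diff)."""
    def eval_at(vap, vdi):
        return b_star_at_bcl(bcl, restitution, p, d, vap, vdi)

    if which == "V_AP":
        return (eval_at(v_ap + step, v_di) - eval_at(v_ap - step, v_di)) / (2 * step)
    if which == "V_DI":
        return (eval_at(v_ap, v_di + step) - eval_at(v_ap, v_di - step)) / (2 * step)
    raise ValueError("which must be 'V_AP' or 'V_DI'")


def rate_scaling_pair(sigma: float, square: SquareWaveAP,
                      p: GatingRateParams, d: DrugParams) -> tuple[float, float]:
    """(b* with binding rates scaled by sigma, b* with APD and DI scaled by sigma).

    The two are algebraically identical: scaling k_on and k_off by sigma is
    equivalent to scaling APD and DI by sigma.
    """
    lhs = b_star(square, p, d.scaled(sigma))
    stretched = SquareWaveAP(V_AP=square.V_AP, V_DI=square.V_DI,
                             APD=sigma * square.APD, DI=sigma * square.DI)
    rhs = b_star(stretched, p, d)
    return lhs, rhs
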