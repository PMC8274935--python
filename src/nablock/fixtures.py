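"""Synthetic test inputs with known ground truth.

Everything a test or the fitter consumes can be regenerated here
bit-identically from a seed: a ground-truth gating parameter preset, noiseless
or noisy clamp datasets, parametric restitution curves, and periodic AP
waveforms (square and trapezoid).

The dataset shapes emulate published Na+-channel clamp curves qualitatively
(half-points, slopes, time scales); they are not digitized experimental data
and carry provenance strings saying so.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import protocols
from .gating import DrugParams, GatingRateParams, steady_state
from .ratedep import RestitutionCurve
from .waveforms import SquareWaveform, TrapezoidWaveform

__all__ = [
    "FixtureSpec",
    "default_truth",
    "gen_clamp_fixture",
    "gen_restitution",
    "gen_ap_waveform",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20210614


def default_truth() -> GatingRateParams:
    """Ground-truth gating coefficients for synthetic data.

    Constructed so that the inactivation curve has its half-point at -75 mV
    with slope factor 5 mV (so h_inf(-85) ~= 0.88, rounding to 0.9, and
    h_inf(+20) ~= 0) and m_inf^3 saturates above roughly -20 mV.
    """
    return GatingRateParams(
        c1_alpha_m=3000.0, c2_alpha_m=8.0,
        c1_beta_m=3.9e-2, c2_beta_m=-8.0,
        c1_alpha_h=1.1e-6, c2_alpha_h=-8.0,
        c1_beta_h=1.1e-6 * np.exp(15.0), c2_beta_h=40.0 / 3.0,
    )


@dataclass
class FixtureSpec:
    """Recipe for a reproducible set of synthetic clamp datasets.

    ``noise_sd`` maps protocol tag -> additive Gaussian standard deviation
    (fraction units for fraction-valued protocols, relative units applied on
    the log scale for ms-valued protocols).
    """

    truth: GatingRateParams = field(default_factory=default_truth)
    protocols: tuple[str, ...] = ("availability", "activation", "t_half",
                                  "activation_tau")
    seed: int = DEFAULT_SEED
    noise_sd: dict = field(default_factory=dict)
    availability_grid: np.ndarray = field(
        default_factory=lambda: np.arange(-120.0, -35.0, 5.0))
    activation_grid: np.ndarray = field(
        default_factory=lambda: np.arange(-60.0, 25.0, 5.0))
    t_half_grid: np.ndarray = field(
        default_factory=lambda: np.concatenate([
            np.arange(-110.0, -65.0, 10.0),   # hyperpolarized (recovery) branch
            np.arange(-50.0, 25.0, 10.0),     # depolarized (decay) branch
        ]))
    activation_tau_grid: np.ndarray = field(
        default_factory=lambda: np.arange(-50.0, 25.0, 5.0))


def gen_clamp_fixture(spec: FixtureSpec | None = None) -> list[protocols.ClampDataset]:
    """Generate clamp datasets from the truth parameters, optionally noisy.

    Fraction-valued noise is clipped to [0, 1]; ms-valued noise is applied
    multiplicatively (log-normal) so values stay positive.  Reproducible from
    ``spec.seed``.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    provenance = f"synthetic fixture, seed={spec.seed}"
    out: list[protocols.ClampDataset] = []
    for tag in spec.protocols:
        if tag == "availability":
            ds = protocols.steady_state_availability(
                spec.truth, prepulse_range=spec.availability_grid)
        elif tag == "activation":
            ds = protocols.steady_state_activation(
                spec.truth, test_range=spec.activation_grid)
        elif tag == "t_half":
            x = spec.t_half_grid
            y = np.array([protocols.time_to_half_inactivation(spec.truth, V)
                          for V in x])
            ds = protocols.ClampDataset(tag="t_half", x=x, y=y)
        elif tag == "activation_tau":
            x = spec.activation_tau_grid
            ds = protocols.ClampDataset(
                tag="activation_tau", x=x,
                y=np.asarray(protocols.activation_tau(spec.truth, x)))
        else:
            raise KeyError(f"unsupported fixture protocol {tag!r}")
        sd = float(spec.noise_sd.get(tag, 0.0))
        if sd > 0:
            noise = rng.normal(0.0, sd, size=ds.y.shape)
            if tag in ("availability", "activation"):
                ds.y = np.clip(ds.y + noise, 0.0, 1.0)
            else:
                ds.y = ds.y * np.exp(noise)
        ds.provenance = provenance + (f", noise_sd={sd}" if sd > 0 else ", noiseless")
        out.append(ds)
    return out


_RESTITUTION_PRESETS = {
    # f(BCL) = apd_max * (1 - a * exp(-BCL / tau)), domain in ms
    "default": dict(apd_max=310.0, a=0.60, tau=350.0, domain=(300.0, 1000.0)),
    "steep": dict(apd_max=310.0, a=0.95, tau=280.0, domain=(300.0, 1000.0)),
}


def gen_restitution(form: str = "default", **params) -> RestitutionCurve:
    """Restitution curve presets and parametric/tabulated constructors.

    ``form`` is one of 'default', 'steep' (saturating-exponential presets),
    'flat' (requires ``apd``, ``domain``), 'exponential' (requires
    ``apd_max``, ``a``, ``tau``, ``domain``) or 'tabulated' (requires
    ``bcl``, ``apd`` arrays).
    """
    if form in _RESTITUTION_PRESETS:
        kw = dict(_RESTITUTION_PRESETS[form], **params)
        return RestitutionCurve.exponential(
            kw["apd_max"], kw["a"], kw["tau"], kw["domain"], label=form)
    if form == "exponential":
        return RestitutionCurve.exponential(
            params["apd_max"], params["a"], params["tau"], params["domain"])
    if form == "flat":
        return RestitutionCurve.flat(params["apd"], params["domain"])
    if form == "tabulated":
        return RestitutionCurve.from_table(params["bcl"], params["apd"])
    raise KeyError(f"unknown restitution form {form!r}")


def gen_ap_waveform(kind: str, V_AP: float = 20.0, V_DI: float = -85.0,
                    APD: float = 300.0, DI: float = 450.0,
                    ramp_ms: float = 0.0):
    """Periodic AP-clamp waveform: 'square' or 'trapezoid' (with ramps)."""
    if kind == "square":
        return SquareWaveform(V_high=V_AP, V_low=V_DI, apd=APD, di=DI)
    if kind == "trapezoid":
        return TrapezoidWaveform(V_high=V_AP, V_low=V_DI, apd=APD, di=DI,
                                 ramp=ramp_ms)
    raise KeyError(f"unknown waveform kind {kind!r}")
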