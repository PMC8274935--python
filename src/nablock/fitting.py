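"""Least-squares fitting of the 8 drug-free gating coefficients.

Only the gating coefficients are fitted; drug binding rates are literature
constants and are deliberately absent from the fit vector.  The objective is
a weighted sum over datasets of the mean squared model-data difference, with
ms-valued observables (time to half inactivation, activation time constant)
compared on a log scale so they do not swamp the fraction-valued curves.

Optimization is bounded local least-squares (scipy ``least_squares``, trust
region reflective) from multiple start points: one data-driven heuristic
start plus random starts drawn log-uniformly in c1 and uniformly in c2.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .gating import GatingRateParams, SimulationError
from .protocols import FITTABLE_TAGS, ClampDataset, model_curve, sse

__all__ = ["FitConfig", "FitResult", "objective", "fit_drug_free"]

#: protocol tags whose y-values are in ms and are fitted on a log scale
LOG_SCALE_TAGS = ("t_half", "activation_tau")

#: sign of c2 for each coefficient slot, fixed by the gating convention
_C2_SIGNS = (+1, -1, -1, +1)  # alpha_m, beta_m, alpha_h, beta_h
_PENALTY = 1e3


@dataclass
class FitConfig:
    """Multistart bounded least-squares settings."""

    n_starts: int = 20
    seed: int = 0
    log10_c1_bounds: tuple[float, float] = (-8.0, 4.0)
    abs_c2_bounds: tuple[float, float] = (3.0, 100.0)
    dataset_weights: dict = field(default_factory=dict)
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12
    max_nfev: int | None = None
    use_heuristic_start: bool = True

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.abs_c2_bounds[0] <= 0:
            raise ValueError("c2 magnitude bounds must be positive")


@dataclass
class FitResult:
    params: GatingRateParams
    per_dataset_sse: dict
    objective: float
    converged: bool
    start_index: int
    start_objectives: list
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "params": {k: getattr(self.params, k)
                       for k in GatingRateParams.FIELD_ORDER},
            "per_dataset_sse": self.per_dataset_sse,
            "objective": self.objective,
            "converged": self.converged,
            "start_index": self.start_index,
            "start_objectives": self.start_objectives,
            "provenance": self.provenance,
        }


# ---------------------------------------------------------------------------
# encoding: x = [log10(c1), c2] per rate, c2 sign folded into bounds
# ---------------------------------------------------------------------------

def _encode(p: GatingRateParams) -> np.ndarray:
    a = p.as_array()
    x = np.empty(8)
    x[0::2] = np.log10(a[0::2])
    x[1::2] = a[1::2]
    return x


def _decode(x: np.ndarray) -> GatingRateParams:
    a = np.empty(8)
    a[0::2] = 10.0 ** x[0::2]
    a[1::2] = x[1::2]
    return GatingRateParams.from_array(a)


def _bounds(config: FitConfig) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = np.empty(8), np.empty(8)
    lo[0::2], hi[0::2] = config.log10_c1_bounds
    c2lo, c2hi = config.abs_c2_bounds
    for i, sign in enumerate(_C2_SIGNS):
        j = 2 * i + 1
        if sign > 0:
            lo[j], hi[j] = c2lo, c2hi
        else:
            lo[j], hi[j] = -c2hi, -c2lo
    return lo, hi


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def _transform(tag: str, y: np.ndarray) -> np.ndarray:
    if tag in LOG_SCALE_TAGS:
        return np.log(np.maximum(y, 1e-300))
    return y


def _check_datasets(datasets: Sequence[ClampDataset]) -> None:
    for ds in datasets:
        if ds.tag not in FITTABLE_TAGS:
            raise KeyError(f"unknown protocol tag {ds.tag!r}")


def objective(p: GatingRateParams, datasets: Sequence[ClampDataset],
              weights: dict | None = None) -> float:
    """Weighted sum over datasets of sse(model curve, data)."""
    _check_datasets(datasets)
    weights = weights or {}
    total = 0.0
    for ds in datasets:
        yhat = model_curve(ds.tag, ds.x, p, ds.config)
        w = float(weights.get(ds.tag, 1.0))
        total += w * sse(_transform(ds.tag, yhat), _transform(ds.tag, ds.y))
    return total


def _residuals(x: np.ndarray, datasets: Sequence[ClampDataset],
               weights: dict, n_total: int) -> np.ndarray:
    try:
        p = _decode(x)
    except ValueError:
        return np.full(n_total, _PENALTY)
    parts = []
    for ds in datasets:
        w = float(weights.get(ds.tag, 1.0))
        scale = np.sqrt(w / len(ds))
        if ds.weights is not None:
            scale = scale * np.sqrt(ds.weights)
        try:
            yhat = model_curve(ds.tag, ds.x, p, ds.config)
            r = scale * (_transform(ds.tag, yhat) - _transform(ds.tag, ds.y))
        except (SimulationError, FloatingPointError, ValueError):
            r = np.full(len(ds), _PENALTY)
        parts.append(np.where(np.isfinite(r), r, _PENALTY))
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# start points
# ---------------------------------------------------------------------------

def _boltzmann_estimate(x: np.ndarray, y: np.ndarray, increasing: bool):
    """(V_half, slope_mV) from the 0.25/0.5/0.75 crossings of a sigmoid curve."""
    xs, ys = (x, y) if increasing else (x, 1.0 - y)
    ys = np.clip(ys, 0.0, 1.0)
    levels = []
    for q in (0.25, 0.5, 0.75):
        idx = np.nonzero(ys >= q)[0]
        if idx.size == 0 or idx[0] == 0:
            return None
        i = idx[0]
        frac = (q - ys[i - 1]) / (ys[i] - ys[i - 1])
        levels.append(xs[i - 1] + frac * (xs[i] - xs[i - 1]))
    v_half = levels[1]
    slope = max((levels[2] - levels[0]) / (2.0 * np.log(3.0)), 1.0)
    return float(v_half), float(slope)


def _loglinear_rate_fit(V: np.ndarray, r: np.ndarray, sign: int,
                        config: FitConfig):
    """Fit ln r = ln c1 + V/c2 by least squares, projected into bounds."""
    mask = r > 0
    if mask.sum() < 2:
        return None
    coef = np.polyfit(V[mask], np.log(r[mask]), 1)
    slope, intercept = coef[0], coef[1]
    if abs(slope) < 1e-12:
        slope = np.sign(sign) * 1e-12
    c2 = 1.0 / slope
    if np.sign(c2) != np.sign(sign):
        c2 = sign * config.abs_c2_bounds[1]
    c2 = np.sign(c2) * np.clip(abs(c2), *config.abs_c2_bounds)
    log10_c1 = np.clip(intercept / np.log(10.0), *config.log10_c1_bounds)
    return float(log10_c1), float(c2)


def heuristic_start(datasets: Sequence[ClampDataset],
                    config: FitConfig) -> np.ndarray | None:
    """Data-driven start: Boltzmann half-points + log-linear rate regressions.

    Estimates h_inf from the availability curve and tau_h from the
    time-to-half data (tau ~= t_half / ln 2 on both branches), giving
    pointwise alpha_h = h_inf/tau_h and beta_h = (1-h_inf)/tau_h which are
    regressed log-linearly in V; the m coefficients are estimated the same way
    from the activation curve (m_inf ~= y^(1/3)) and the activation-tau data.
    Returns None if the needed datasets are missing or degenerate.
    """
    by_tag = {ds.tag: ds for ds in datasets}
    need = {"availability", "t_half", "activation", "activation_tau"}
    if not need.issubset(by_tag):
        return None
    av, th = by_tag["availability"], by_tag["t_half"]
    act, atau = by_tag["activation"], by_tag["activation_tau"]

    est_h = _boltzmann_estimate(av.x, av.y, increasing=False)
    est_m = _boltzmann_estimate(act.x, np.cbrt(np.clip(act.y, 0, 1)),
                                increasing=True)
    if est_h is None or est_m is None:
        return None
    vh_h, k_h = est_h
    vh_m, k_m = est_m

    def h_inf(V):
        return 1.0 / (1.0 + np.exp((V - vh_h) / k_h))

    def m_inf(V):
        return 1.0 / (1.0 + np.exp(-(V - vh_m) / k_m))

    tau_h = np.maximum(th.y, 1e-6) / np.log(2.0)
    ah = _loglinear_rate_fit(th.x, h_inf(th.x) / tau_h, -1, config)
    bh = _loglinear_rate_fit(th.x, (1.0 - h_inf(th.x)) / tau_h, +1, config)
    tau_m = np.maximum(atau.y, 1e-9)
    am = _loglinear_rate_fit(atau.x, m_inf(atau.x) / tau_m, +1, config)
    bm = _loglinear_rate_fit(atau.x, (1.0 - m_inf(atau.x)) / tau_m, -1, config)
    if any(v is None for v in (ah, bh, am, bm)):
        return None
    return np.array([am[0], am[1], bm[0], bm[1], ah[0], ah[1], bh[0], bh[1]])


def _random_start(rng: np.random.Generator, lo: np.ndarray,
                  hi: np.ndarray) -> np.ndarray:
    return rng.uniform(lo, hi)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _config_hash(datasets: Sequence[ClampDataset], config: FitConfig) -> str:
    payload = {
        "datasets": [
            {"tag": ds.tag, "x": ds.x.tolist(), "y": ds.y.tolist(),
             "config": {k: v for k, v in sorted(ds.config.items())
                        if not isinstance(v, (list, np.ndarray))}}
            for ds in datasets
        ],
        "config": {
            "n_starts": config.n_starts, "seed": config.seed,
            "log10_c1_bounds": list(config.log10_c1_bounds),
            "abs_c2_bounds": list(config.abs_c2_bounds),
            "dataset_weights": dict(sorted(config.dataset_weights.items())),
        },
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def fit_drug_free(datasets: Sequence[ClampDataset],
                  config: FitConfig | None = None) -> FitResult:
    """Fit the 8 gating coefficients to clamp datasets by multistart least squares."""
    config = config or FitConfig()
    _check_datasets(datasets)
    tags = {ds.tag for ds in datasets}
    has_act = bool(tags & {"activation", "activation_tau"})
    has_inact = bool(tags & {"availability", "t_half"})
    if not (len(datasets) >= 2 and has_act and has_inact):
        import warnings
        warnings.warn(
            "fit is under-determined: supply at least one activation-type and "
            "one inactivation-type dataset", UserWarning, stacklevel=2)

    lo, hi = _bounds(config)
    n_total = sum(len(ds) for ds in datasets)
    weights = config.dataset_weights
    rng = np.random.default_rng(config.seed)

    starts: list[np.ndarray] = []
    if config.use_heuristic_start:
        x0 = heuristic_start(datasets, config)
        if x0 is not None:
            starts.append(np.clip(x0, lo, hi))
    while len(starts) < config.n_starts:
        starts.append(_random_start(rng, lo, hi))

    best = None
    start_objectives: list[float] = []
    any_converged = False
    for i, x0 in enumerate(starts):
        res = least_squares(
            _residuals, x0, bounds=(lo, hi), args=(datasets, weights, n_total),
            method="trf", x_scale="jac",
            xtol=config.xtol, ftol=config.ftol, gtol=config.gtol,
            max_nfev=config.max_nfev,
        )
        start_objectives.append(float(2.0 * res.cost))  # cost = 0.5 * sum r^2
        if res.status > 0:
            any_converged = True
        if best is None or res.cost < best[1].cost:
            best = (i, res)
    if best is None or not any_converged:
        raise RuntimeError("all optimization starts failed to converge")

    idx, res = best
    p_fit = _decode(res.x)
    per_sse = {}
    for ds in datasets:
        yhat = model_curve(ds.tag, ds.x, p_fit, ds.config)
        per_sse[ds.tag] = sse(_transform(ds.tag, yhat), _transform(ds.tag, ds.y))
    return FitResult(
        params=p_fit,
        per_dataset_sse=per_sse,
        objective=objective(p_fit, datasets, weights),
        converged=any_converged,
        start_index=idx,
        start_objectives=start_objectives,
        provenance={
            "seed": config.seed,
            "n_starts": config.n_starts,
            "config_hash": _config_hash(datasets, config),
            "dataset_provenance": [ds.provenance for ds in datasets],
        },
    )
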