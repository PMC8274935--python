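"""Readers and writers for the package's file formats.

Formats: flat key-value YAML parameter files, dataset CSV (columns x, y,
optional weight) with a JSON sidecar carrying the protocol tag / units /
config, trajectory CSV, restitution CSV (BCL_ms, APD_ms), and fit-result
JSON.  All writes are atomic (temp file + rename) and numeric CSV output is
full double precision.  Concentrations in parameter files are micromolar and
converted to molar at this boundary.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gating import ChannelParams, DrugParams, GatingRateParams, Trajectory
from .protocols import ClampDataset
from .ratedep import RestitutionCurve

__all__ = [
    "MalformedInputError",
    "load_params",
    "save_params",
    "read_dataset_csv",
    "write_dataset_csv",
    "write_trajectory_csv",
    "read_restitution_csv",
    "write_fit_result",
    "atomic_write_text",
]

PARAM_KEYS = list(GatingRateParams.FIELD_ORDER) + [
    "k_on", "k_off", "drug_conc_uM", "g_max", "E_Na_mV",
]


class MalformedInputError(ValueError):
    """An input file could not be parsed into the expected structure."""


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def load_params(path: str | Path) -> tuple[GatingRateParams, DrugParams, ChannelParams]:
    """Load a flat key-value YAML parameter file.

    Recognized keys: the eight gating coefficients (c1_alpha_m, ...), k_on
    (1/(M*ms)), k_off (1/ms), drug_conc_uM (micromolar), g_max, E_Na_mV.
    Missing drug/channel keys fall back to defaults; missing gating keys are
    an error.
    """
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise MalformedInputError(f"cannot parse parameter file {path}: {exc}")
    if not isinstance(raw, dict):
        raise MalformedInputError(f"parameter file {path} is not a key-value map")
    unknown = set(raw) - set(PARAM_KEYS)
    if unknown:
        raise MalformedInputError(
            f"unknown parameter keys in {path}: {sorted(unknown)}")
    missing = [k for k in GatingRateParams.FIELD_ORDER if k not in raw]
    if missing:
        raise MalformedInputError(f"missing gating keys in {path}: {missing}")
    gating = GatingRateParams(**{k: float(raw[k])
                                 for k in GatingRateParams.FIELD_ORDER})
    drug = DrugParams(
        k_on=float(raw.get("k_on", 250.0)),
        k_off=float(raw.get("k_off", 1.7e-3)),
        concentration=float(raw.get("drug_conc_uM", 0.0)) * 1e-6,
    )
    channel = ChannelParams(g_max=float(raw.get("g_max", 1.0)),
                            E_Na=float(raw.get("E_Na_mV", 70.0)))
    return gating, drug, channel


def save_params(path: str | Path, gating: GatingRateParams,
                drug: DrugParams | None = None,
                channel: ChannelParams | None = None) -> None:
    drug = drug or DrugParams()
    channel = channel or ChannelParams()
    data = {k: float(getattr(gating, k)) for k in GatingRateParams.FIELD_ORDER}
    data.update(k_on=float(drug.k_on), k_off=float(drug.k_off),
                drug_conc_uM=float(drug.concentration * 1e6),
                g_max=float(channel.g_max), E_Na_mV=float(channel.E_Na))
    atomic_write_text(path, yaml.safe_dump(data, sort_keys=False))


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_dataset_csv(path: str | Path, ds: ClampDataset) -> None:
    """Dataset CSV (x, y[, weight]) plus a JSON sidecar with tag and config."""
    path = Path(path)
    cols = {"x": ds.x, "y": ds.y}
    if ds.weights is not None:
        cols["weight"] = ds.weights
    df = pd.DataFrame(cols)
    atomic_write_text(path, df.to_csv(index=False, float_format="%.17e"))
    meta = {"tag": ds.tag, "config": _jsonable(ds.config),
            "provenance": ds.provenance}
    atomic_write_text(_sidecar(path), json.dumps(meta, indent=2))


def read_dataset_csv(path: str | Path, tag: str | None = None) -> ClampDataset:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise MalformedInputError(f"cannot parse dataset CSV {path}: {exc}")
    if "x" not in df.columns or "y" not in df.columns:
        raise MalformedInputError(
            f"dataset CSV {path} must have columns 'x' and 'y' "
            f"(got {list(df.columns)})")
    meta: dict = {}
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
    resolved_tag = tag or meta.get("tag")
    if resolved_tag is None:
        raise MalformedInputError(
            f"no protocol tag for {path}: pass one or provide a sidecar")
    return ClampDataset(
        tag=resolved_tag,
        x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        weights=(df["weight"].to_numpy(dtype=float)
                 if "weight" in df.columns else None),
        config=meta.get("config", {}),
        provenance=meta.get("provenance", ""),
    )


def write_trajectory_csv(path: str | Path, traj: Trajectory) -> None:
    df = pd.DataFrame({
        "t_ms": traj.t, "V_mV": traj.V, "m": traj.m, "h": traj.h,
        "b": traj.b, "f_open": traj.f_open, "I_Na": traj.I_Na,
    })
    atomic_write_text(path, df.to_csv(index=False, float_format="%.17e"))


def read_restitution_csv(path: str | Path) -> RestitutionCurve:
    """Tabulated restitution curve from a CSV with columns BCL_ms, APD_ms."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise MalformedInputError(f"cannot parse restitution CSV {path}: {exc}")
    if not {"BCL_ms", "APD_ms"}.issubset(df.columns):
        raise MalformedInputError(
            f"restitution CSV {path} must have columns BCL_ms and APD_ms")
    return RestitutionCurve.from_table(df["BCL_ms"].to_numpy(dtype=float),
                                       df["APD_ms"].to_numpy(dtype=float))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_fit_result(path: str | Path, result) -> None:
    atomic_write_text(path, json.dumps(_jsonable(result.to_dict()), indent=2))
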