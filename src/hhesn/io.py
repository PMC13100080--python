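"""File formats: columnar text traces, npz binary containers, trained systems.

Text traces are plain delimited columns with a fixed header (lossy only at
float-formatting precision); the npz containers are lossless and carry a
JSON provenance block (schema, seeds, tolerances, package version).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import __version__
from .hybrid import HybridLayout, HybridSystem, HybridVariant
from .neuron import GateParams, NeuronParams, NeuronState
from .reservoir import Readout, ReservoirConfig, ReservoirSystem, Scaler
from .timeseries import CurrentProtocol, Trajectory

__all__ = [
    "SchemaError",
    "write_protocol_text",
    "read_protocol_text",
    "write_trajectory_text",
    "read_trajectory_text",
    "save_protocol",
    "load_protocol",
    "save_trajectory",
    "load_trajectory",
    "save_system",
    "load_system",
]

PROTOCOL_COLUMNS = ["time_ms", "I_uA"]
TRAJECTORY_COLUMNS = ["time_ms", "V_mV", "m", "h", "n"]
FLOAT_FMT = "%.10g"


class SchemaError(ValueError):
    """File content does not match the requested schema."""


def _read_table(path, expected_columns) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != expected_columns:
        raise SchemaError(
            f"{path}: expected columns {expected_columns}, found {list(df.columns)}"
        )
    if df.isna().any().any():
        raise SchemaError(f"{path}: ragged or non-numeric rows")
    return df


def _infer_dt(times: np.ndarray) -> float:
    if times.size < 2:
        return float("nan")
    steps = np.diff(times)
    dt = float(np.median(steps))
    if not np.allclose(steps, dt, rtol=1e-6, atol=1e-9):
        raise SchemaError("non-uniform time grid")
    return dt


def write_protocol_text(protocol: CurrentProtocol, path) -> None:
    protocol.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_protocol_text(path) -> CurrentProtocol:
    df = _read_table(path, PROTOCOL_COLUMNS)
    t = df["time_ms"].to_numpy()
    return CurrentProtocol(df["I_uA"].to_numpy(), _infer_dt(t), float(t[0]))


def write_trajectory_text(traj: Trajectory, path) -> None:
    traj.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_trajectory_text(path) -> Trajectory:
    df = _read_table(path, TRAJECTORY_COLUMNS)
    t = df["time_ms"].to_numpy()
    data = df[["V_mV", "m", "h", "n"]].to_numpy()
    return Trajectory(data, _infer_dt(t), float(t[0]))


def _meta_block(kind: str, extra: dict | None) -> str:
    meta = {"schema": kind, "version": __version__}
    if extra:
        meta.update(extra)
    return json.dumps(meta)


def _check_kind(payload, path, kind: str) -> dict:
    meta = json.loads(str(payload["meta"]))
    if meta.get("schema") != kind:
        raise SchemaError(f"{path}: schema {meta.get('schema')!r}, expected {kind!r}")
    return meta


def save_protocol(protocol: CurrentProtocol, path, meta: dict | None = None) -> None:
    np.savez(
        path,
        current=protocol.current,
        dt=protocol.dt,
        t0=protocol.t0,
        meta=_meta_block("protocol", meta),
    )


def load_protocol(path) -> CurrentProtocol:
    with np.load(path, allow_pickle=False) as z:
        _check_kind(z, path, "protocol")
        return CurrentProtocol(z["current"], float(z["dt"]), float(z["t0"]))


def save_trajectory(traj: Trajectory, path, meta: dict | None = None) -> None:
    merged = dict(traj.meta)
    if meta:
        merged.update(meta)
    np.savez(
        path,
        data=traj.data,
        dt=traj.dt,
        t0=traj.t0,
        meta=_meta_block("trajectory", merged),
    )


def load_trajectory(path) -> Trajectory:
    with np.load(path, allow_pickle=False) as z:
        meta = _check_kind(z, path, "trajectory")
        extra = {k: v for k, v in meta.items() if k not in ("schema", "version")}
        return Trajectory(z["data"], float(z["dt"]), float(z["t0"]), extra)


def _params_dict(p: NeuronParams) -> dict:
    d = dataclasses.asdict(p)
    return d


def _params_from_dict(d: dict) -> NeuronParams:
    gates = {k: GateParams(**d.pop(k)) for k in ("m", "h", "n")}
    return NeuronParams(**d, **gates)


def save_system(system, path, meta: dict | None = None) -> None:
    """Serialize a trained ReservoirSystem or HybridSystem to npz."""
    if isinstance(system, HybridSystem):
        res = system.reservoir
        kind = "hybrid_system"
        extra = {
            "variant": system.variant.tag,
            "gamma": system.layout.gamma,
            "counts": list(system.layout.counts),
            "surrogate": _params_dict(system.surrogate_params),
            "rtol": system.rtol,
            "atol": system.atol,
            "scale_model_inputs": system.scale_model_inputs,
        }
        x_state = (
            system.surrogate_state.to_array()
            if system.surrogate_state is not None
            else np.full(4, np.nan)
        )
    elif isinstance(system, ReservoirSystem):
        res = system
        kind = "reservoir_system"
        extra = {}
        x_state = np.full(4, np.nan)
    else:
        raise TypeError(f"cannot serialize {type(system).__name__}")
    if not res.trained:
        raise ValueError("refusing to save an untrained system")
    a = sp.coo_matrix(res.A)
    payload = {
        "a_row": a.row,
        "a_col": a.col,
        "a_data": a.data,
        "n_nodes": res.config.n_nodes,
        "chan": res.chan,
        "config": json.dumps(dataclasses.asdict(res.config)),
        "scaler_i": np.array([res.scaler_i.center, res.scaler_i.spread, res.scaler_i.sigma]),
        "scaler_v": np.array([res.scaler_v.center, res.scaler_v.spread, res.scaler_v.sigma]),
        "weights": res.readout.weights,
        "bias": res.readout.bias,
        "r_state": res.r_state,
        "v_feedback": res.v_feedback,
        "v_rails": np.array([res.v_lo, res.v_hi], dtype=float),
        "x_state": x_state,
        "meta": _meta_block(kind, {**extra, **(meta or {})}),
    }
    np.savez(path, **payload)


def load_system(path):
    """Load a system saved by `save_system` (type inferred from the schema)."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        kind = meta.get("schema")
        if kind not in ("reservoir_system", "hybrid_system"):
            raise SchemaError(f"{path}: schema {kind!r} is not a trained system")
        n = int(z["n_nodes"])
        a = sp.csr_matrix(
            sp.coo_matrix((z["a_data"], (z["a_row"], z["a_col"])), shape=(n, n))
        )
        cfg = ReservoirConfig(**json.loads(str(z["config"])))
        res = ReservoirSystem(
            config=cfg,
            A=a,
            chan=z["chan"],
            scaler_i=Scaler(*z["scaler_i"]),
            scaler_v=Scaler(*z["scaler_v"]),
            readout=Readout(z["weights"], float(z["bias"])),
            r_state=z["r_state"],
            v_feedback=float(z["v_feedback"]),
            v_lo=float(z["v_rails"][0]),
            v_hi=float(z["v_rails"][1]),
        )
        if kind == "reservoir_system":
            return res
        variant = HybridVariant.parse(meta["variant"])
        layout = HybridLayout(float(meta["gamma"]), tuple(meta["counts"]))
        x = z["x_state"]
        state = None if np.isnan(x).any() else NeuronState.from_array(x)
        return HybridSystem(
            reservoir=res,
            surrogate_params=_params_from_dict(meta["surrogate"]),
            variant=variant,
            layout=layout,
            surrogate_state=state,
            rtol=float(meta["rtol"]),
            atol=float(meta["atol"]),
            scale_model_inputs=bool(meta.get("scale_model_inputs", False)),
        )
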