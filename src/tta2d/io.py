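"""File formats: decay-trace CSV and columnar trajectory text.

Trace CSV schema: header ``time_s,value,value_kind[,sigma]`` where
value_kind is ``depletion`` (dimensionless SHG trace) or
``concentration_mol_m2``.  Trajectory files are CSV
(``frame,particle_id,x_nm,y_nm``) preceded by ``# key=value`` metadata
lines (L_nm, dt_ns, wrapped, seed mandatory).  Files store nm/ns at the
boundary; in-memory objects are SI.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FitResult, SHGTrace
from .kinetics import KineticTrace
from .trajectories import Trajectory2D

__all__ = [
    "read_trace",
    "write_trace",
    "read_trajectory",
    "write_trajectory",
    "fit_result_to_json",
]

_TRACE_COLUMNS = {"time_s", "value", "value_kind"}
_KINDS = {"depletion", "concentration_mol_m2"}


class TraceParseError(ValueError):
    pass


def write_trace(trace, path) -> None:
    """Serialise a KineticTrace or SHGTrace to the trace CSV schema."""
    if isinstance(trace, KineticTrace):
        df = pd.DataFrame({
            "time_s": trace.times,
            "value": trace.conc,
            "value_kind": "concentration_mol_m2",
        })
    elif isinstance(trace, SHGTrace):
        df = pd.DataFrame({
            "time_s": trace.delays,
            "value": trace.depletion,
            "value_kind": "depletion",
        })
        if trace.sigma is not None:
            df["sigma"] = trace.sigma
    else:
        raise TypeError(f"cannot serialise {type(trace).__name__}")
    df.to_csv(path, index=False)


def read_trace(path):
    """Read a trace CSV; value_kind decides the returned type
    (SHGTrace for depletion, KineticTrace for concentration)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise TraceParseError(f"{path}: not parseable CSV: {exc}") from exc
    missing = _TRACE_COLUMNS - set(df.columns)
    if missing:
        raise TraceParseError(f"{path}: missing columns {sorted(missing)}")
    kinds = set(df["value_kind"].unique())
    if not kinds <= _KINDS:
        raise TraceParseError(f"{path}: unknown value_kind {kinds - _KINDS}")
    if len(kinds) != 1:
        raise TraceParseError(f"{path}: mixed value kinds {kinds}")
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        # +2: header line, then 1-based data rows; points at the second of the pair
        raise TraceParseError(
            f"{path}: time not strictly increasing at data line {bad[0] + 3} "
            f"(t = {t[bad[0] + 1]!r})"
        )
    v = df["value"].to_numpy(dtype=float)
    kind = kinds.pop()
    if kind == "concentration_mol_m2":
        return KineticTrace(times=t, conc=v)
    sigma = df["sigma"].to_numpy(dtype=float) if "sigma" in df.columns else None
    return SHGTrace(delays=t, depletion=v, sigma=sigma)


_REQUIRED_TRAJ_META = ("L_nm", "dt_ns", "wrapped", "seed")


def write_trajectory(traj: Trajectory2D, path) -> None:
    """Columnar trajectory text with a metadata header block.

    Every artifact embeds the parameters and seed needed to regenerate it.
    """
    path = Path(path)
    meta = dict(traj.meta)
    header = {
        "L_nm": traj.box[0] * 1e9,
        "Ly_nm": traj.box[1] * 1e9,
        "dt_ns": traj.dt * 1e9,
        "wrapped": traj.wrapped,
        "seed": meta.pop("seed", "unknown"),
    }
    n, f = traj.n_particles, traj.n_frames
    frame_idx = np.repeat(np.arange(f), n)
    pid = np.tile(np.arange(n), f)
    xy = np.transpose(traj.positions, (1, 0, 2)).reshape(-1, 2) * 1e9
    df = pd.DataFrame({"frame": frame_idx, "particle_id": pid,
                       "x_nm": xy[:, 0], "y_nm": xy[:, 1]})
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}={v}\n")
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False, float_format="%.9f")


def read_trajectory(path) -> Trajectory2D:
    """Read a columnar trajectory file written by :func:`write_trajectory`."""
    path = Path(path)
    meta = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    for key in _REQUIRED_TRAJ_META:
        if key not in meta:
            raise ValueError(f"{path}: missing required metadata {key!r}")
    df = pd.read_csv(path, skiprows=skip)
    Lx = float(meta["L_nm"]) * 1e-9
    Ly = float(meta.get("Ly_nm", meta["L_nm"])) * 1e-9
    dt = float(meta["dt_ns"]) * 1e-9
    wrapped = meta["wrapped"] in ("True", "true", "1")
    if df.empty:
        return Trajectory2D(times=np.zeros(0), positions=np.zeros((0, 0, 2)),
                            box=(Lx, Ly), wrapped=wrapped, meta=meta)
    n_frames = int(df["frame"].max()) + 1
    n_particles = int(df["particle_id"].max()) + 1
    if len(df) != n_frames * n_particles:
        raise ValueError(f"{path}: incomplete frames (ragged trajectory)")
    df = df.sort_values(["frame", "particle_id"])
    pos = df[["x_nm", "y_nm"]].to_numpy().reshape(n_frames, n_particles, 2)
    pos = np.transpose(pos, (1, 0, 2)) * 1e-9
    times = np.arange(n_frames) * dt
    if wrapped:
        pos = np.clip(pos, 0.0, np.nextafter([Lx, Ly], 0.0))
    return Trajectory2D(times=times, positions=pos, box=(Lx, Ly),
                        wrapped=wrapped, meta=meta)


def fit_result_to_json(result: FitResult, path=None) -> str:
    """FitResult as JSON (parameters, errors, residuals, diagnostics)."""
    payload = {
        "model": result.model,
        "params": result.params,
        "stderr": result.stderr,
        "residual_norm": result.residual_norm,
        "converged": result.converged,
        "message": result.message,
        "residuals": np.asarray(result.residuals).tolist(),
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
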