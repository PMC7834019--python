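"""Readers and writers for all on-disk formats.

Every format is plain text and round-trips exactly:

* trajectory CSV   ``track_id,time_s,x_mm,y_mm`` (1-Hz rows per track)
* counts JSON      ``{plate_id, n_A, n_B, n_O, n_total}``
* geometry JSON    the plate-geometry fields
* field text       header (origin, spacing, shape, timestamp) then rows
                   of mM values, ``nan`` marking off-plate cells
* trace CSV        ``time_s,ch1,ch2[,bg1,bg2]``
* velocity CSV     ``frame,velocity_um_s``
* protocol JSON    ``{frame_rate, epochs: [{t_start_s, conc_mM}]}``
* results JSON     free-form metric dictionaries

Schema violations raise ``SchemaError`` naming the offending column or
line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .plate import PlateGeometry
from .gradient import ConcentrationField
from .metrics import AssayCounts
from .trajectory import Trajectory
from .traces import StimulusProtocol, TwoChannelTrace


class SchemaError(ValueError):
    """A file does not conform to its documented schema."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


# -- trajectories -----------------------------------------------------------

def write_trajectories(tracks: list[Trajectory], path) -> None:
    frames = [pd.DataFrame({"track_id": tr.track_id, "time_s": tr.times,
                            "x_mm": tr.positions[:, 0],
                            "y_mm": tr.positions[:, 1]})
              for tr in tracks]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path) -> list[Trajectory]:
    df = pd.read_csv(path)
    _require_columns(df, ["track_id", "time_s", "x_mm", "y_mm"], path)
    if df[["time_s", "x_mm", "y_mm"]].isna().any().any():
        row = int(df[["time_s", "x_mm", "y_mm"]].isna().any(axis=1).idxmax())
        raise SchemaError(f"{path}: NaN value at data row {row}")
    tracks = []
    for tid, g in df.groupby("track_id", sort=False):
        try:
            tracks.append(Trajectory(str(tid), g["time_s"].to_numpy(),
                                     g[["x_mm", "y_mm"]].to_numpy()))
        except ValueError as e:
            raise SchemaError(f"{path}: track {tid}: {e}") from e
    return tracks


# -- counts -----------------------------------------------------------------

def write_counts(counts: AssayCounts, path, plate_id: str = "plate") -> None:
    Path(path).write_text(json.dumps(
        {"plate_id": plate_id, "n_A": counts.n_a, "n_B": counts.n_b,
         "n_O": counts.n_o, "n_total": counts.n_total}, indent=1) + "\n")


def read_counts(path) -> AssayCounts:
    d = json.loads(Path(path).read_text())
    try:
        return AssayCounts(n_a=int(d["n_A"]), n_b=int(d["n_B"]),
                           n_o=int(d["n_O"]), n_total=int(d["n_total"]))
    except KeyError as e:
        raise SchemaError(f"{path}: missing key {e}") from e


# -- geometry ---------------------------------------------------------------

def write_geometry(geometry: PlateGeometry, path) -> None:
    Path(path).write_text(json.dumps(geometry.to_dict(), indent=1) + "\n")


def read_geometry(path) -> PlateGeometry:
    try:
        return PlateGeometry.from_dict(json.loads(Path(path).read_text()))
    except (TypeError, ValueError) as e:
        raise SchemaError(f"{path}: {e}") from e


# -- concentration field ----------------------------------------------------

def write_field(field: ConcentrationField, path) -> None:
    lines = ["# saltnav concentration field (mM); nan = off plate",
             f"origin {float(field.origin[0])!r} {float(field.origin[1])!r}",
             f"spacing {float(field.grid_spacing)!r}",
             f"shape {field.values.shape[0]} {field.values.shape[1]}",
             f"timestamp {float(field.timestamp)!r}",
             "plate_radius " + ("None" if field.plate_radius is None
                                else repr(float(field.plate_radius)))]
    vals = np.where(field.mask, field.values, np.nan)
    for row in vals:
        lines.append(" ".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_field(path) -> ConcentrationField:
    lines = Path(path).read_text().splitlines()
    header = {}
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            continue
        key = line.split()[0]
        if key in ("origin", "spacing", "shape", "timestamp", "plate_radius"):
            header[key] = line.split()[1:]
        else:
            data_start = i
            break
    try:
        origin = (float(header["origin"][0]), float(header["origin"][1]))
        spacing = float(header["spacing"][0])
        ny, nx = int(header["shape"][0]), int(header["shape"][1])
        timestamp = float(header["timestamp"][0])
        pr = header["plate_radius"][0]
        plate_radius = None if pr == "None" else float(pr)
    except (KeyError, IndexError, ValueError) as e:
        raise SchemaError(f"{path}: malformed field header ({e})") from e
    rows = lines[data_start:data_start + ny]
    if len(rows) < ny:
        raise SchemaError(f"{path}: expected {ny} data rows, got {len(rows)}")
    values = np.array([[float(v) for v in row.split()] for row in rows])
    if values.shape != (ny, nx):
        raise SchemaError(f"{path}: data shape {values.shape} != header shape "
                          f"({ny}, {nx})")
    mask = ~np.isnan(values)
    return ConcentrationField(spacing, origin, np.nan_to_num(values), mask,
                              timestamp=timestamp, plate_radius=plate_radius)


# -- traces -----------------------------------------------------------------

def write_trace(trace: TwoChannelTrace, path) -> None:
    df = pd.DataFrame({"time_s": trace.times, "ch1": trace.channel_1,
                       "ch2": trace.channel_2})
    bg1, bg2 = np.broadcast_to(trace.background_1, trace.times.shape), \
        np.broadcast_to(trace.background_2, trace.times.shape)
    if np.any(bg1 != 0) or np.any(bg2 != 0):
        df["bg1"], df["bg2"] = bg1, bg2
    df.to_csv(path, index=False)


def read_trace(path) -> TwoChannelTrace:
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "ch1", "ch2"], path)
    kw = {}
    if "bg1" in df.columns or "bg2" in df.columns:
        _require_columns(df, ["bg1", "bg2"], path)
        kw = {"background_1": df["bg1"].to_numpy(),
              "background_2": df["bg2"].to_numpy()}
    try:
        return TwoChannelTrace(df["time_s"].to_numpy(), df["ch1"].to_numpy(),
                               df["ch2"].to_numpy(), **kw)
    except ValueError as e:
        raise SchemaError(f"{path}: {e}") from e


def write_velocity(velocity: np.ndarray, path) -> None:
    pd.DataFrame({"frame": np.arange(len(velocity)),
                  "velocity_um_s": velocity}).to_csv(path, index=False)


def read_velocity(path) -> np.ndarray:
    df = pd.read_csv(path)
    _require_columns(df, ["frame", "velocity_um_s"], path)
    if not np.array_equal(df["frame"].to_numpy(), np.arange(len(df))):
        raise SchemaError(f"{path}: frame numbers must be 0..n-1 without gaps")
    return df["velocity_um_s"].to_numpy(dtype=float)


# -- protocol ---------------------------------------------------------------

def write_protocol(protocol: StimulusProtocol, path) -> None:
    Path(path).write_text(json.dumps(
        {"frame_rate": protocol.frame_rate,
         "epochs": [{"t_start_s": t, "conc_mM": c} for t, c in protocol.epochs]},
        indent=1) + "\n")


def read_protocol(path) -> StimulusProtocol:
    d = json.loads(Path(path).read_text())
    try:
        return StimulusProtocol(
            frame_rate=float(d["frame_rate"]),
            epochs=tuple((e["t_start_s"], e["conc_mM"]) for e in d["epochs"]))
    except (KeyError, TypeError, ValueError) as e:
        raise SchemaError(f"{path}: {e}") from e


# -- results ----------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(results: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(results), indent=1,
                                     allow_nan=True) + "\n")


def read_results(path) -> dict:
    return json.loads(Path(path).read_text())
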