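"""File I/O: TIFF stacks with JSON sidecars, track tables, result tables.

Movies travel as multi-page grayscale TIFF with a ``<name>.tif.json``
sidecar holding the calibration metadata (pixel_size in um/px,
frame_interval in s, plus any generator parameters); reading refuses to
invent calibration silently.  Trajectories and per-adhesion property tables
are CSV with a header row.  Binary mask stacks are recognized by content.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .adhesions import FAMovie
from .migration import Trajectory
from .protrusion import EdgeMap

__all__ = [
    "write_tiff_stack",
    "read_tiff_stack",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_edge_map_csv",
    "read_edge_map_csv",
    "sidecar_path",
]

TRACK_COLUMNS = ["cell_id", "frame", "time_s", "x_um", "y_um", "egf_nM"]


def sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_tiff_stack(path, frames, pixel_size: float, frame_interval: float,
                     seed=None, params=None, intensity_scale: float = 1.0):
    """Write a (T, H, W) stack as multi-page TIFF plus a JSON sidecar.

    Boolean masks are stored as 8-bit 0/1; intensity movies keep their dtype
    (16-bit for generator output).
    """
    path = Path(path)
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("stack must be (T, H, W)")
    is_mask = frames.dtype == bool
    data = frames.astype(np.uint8) if is_mask else frames
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = dict(
        pixel_size=float(pixel_size),
        frame_interval=float(frame_interval),
        intensity_scale=float(intensity_scale),
        is_mask=bool(is_mask),
        seed=None if seed is None else int(seed),
        params=_jsonable(params) if params is not None else None,
    )
    sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_tiff_stack(path, pixel_size: float | None = None,
                    frame_interval: float | None = None,
                    intensity_scale: float | None = None):
    """Read a multi-page grayscale TIFF and its calibration.

    Returns ``FAMovie`` for intensity movies or ``(mask_stack, meta)`` for
    binary mask stacks (values only 0/1).  Calibration comes from the JSON
    sidecar; explicit keyword overrides are accepted, but missing
    calibration is an error, never a silent default.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(
            f"{path.name}: expected a grayscale multi-page TIFF (T, H, W); "
            f"got shape {frames.shape} (RGB/multichannel not supported)"
        )
    meta = {}
    sc = sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    if pixel_size is None:
        pixel_size = meta.get("pixel_size")
    if frame_interval is None:
        frame_interval = meta.get("frame_interval")
    if intensity_scale is None:
        intensity_scale = meta.get("intensity_scale", 1.0)
    if pixel_size is None or frame_interval is None:
        raise ValueError(
            f"{path.name}: missing calibration (pixel_size, frame_interval); "
            "provide a JSON sidecar or explicit values"
        )
    vals = np.unique(frames[: min(3, len(frames))])
    is_mask = meta.get("is_mask", bool(np.isin(vals, [0, 1]).all()))
    if is_mask:
        meta = dict(meta, pixel_size=float(pixel_size),
                    frame_interval=float(frame_interval))
        return frames.astype(bool), meta
    return FAMovie(frames=frames, pixel_size=float(pixel_size),
                   frame_interval=float(frame_interval),
                   intensity_scale=float(intensity_scale), metadata=meta)


def write_tracks_csv(trajectories, path):
    """Write trajectories as CSV (cell_id, frame, time_s, x_um, y_um, egf_nM)."""
    rows = []
    for traj in trajectories:
        for i in range(traj.times.size):
            rows.append(dict(
                cell_id=traj.cell_id,
                frame=i,
                time_s=traj.times[i] * 60.0,
                x_um=traj.positions[i, 0],
                y_um=traj.positions[i, 1],
                egf_nM="" if traj.egf_dose is None else traj.egf_dose,
            ))
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(
        path, index=False, float_format="%.10g")
    return Path(path)


def read_tracks_csv(path) -> list[Trajectory]:
    """Read a track table back into Trajectory objects (order-normalized).

    Raises with the column name when a required column is missing, and on
    non-monotone time within a cell.  Numeric parsing is strict: locale
    variants (decimal commas) are rejected.
    """
    df = pd.read_csv(path, dtype={"egf_nM": object})
    missing = [c for c in TRACK_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing required column(s) {missing}")
    for col in ("time_s", "x_um", "y_um"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(
                f"{Path(path).name}: column {col!r} is not parseable as numbers "
                f"(check for locale decimal commas): {exc}"
            ) from exc
    out = []
    for cell_id, g in df.groupby("cell_id", sort=True):
        g = g.sort_values("time_s")
        times = g["time_s"].to_numpy() / 60.0
        if np.any(np.diff(times) <= 0):
            raise ValueError(
                f"{Path(path).name}: non-monotone time for cell {cell_id!r}"
            )
        dose = None
        if "egf_nM" in g.columns:
            v = g["egf_nM"].iloc[0]
            if v not in (None, "") and not (isinstance(v, float) and np.isnan(v)):
                dose = float(v)
        out.append(Trajectory(
            cell_id=cell_id,
            times=times,
            positions=np.column_stack([g["x_um"].to_numpy(), g["y_um"].to_numpy()]),
            egf_dose=dose,
        ))
    return out


def write_edge_map_csv(edge_map: EdgeMap, path):
    """EdgeMap as a CSV matrix: rows = sectors, columns = frame intervals."""
    df = pd.DataFrame(
        edge_map.velocities,
        index=[f"sector_{i}" for i in range(edge_map.n_sectors)],
        columns=[f"interval_{j}" for j in range(edge_map.n_intervals)],
    )
    df.to_csv(path, float_format="%.8g")
    return Path(path)


def read_edge_map_csv(path, frame_interval: float) -> EdgeMap:
    df = pd.read_csv(path, index_col=0)
    v = df.to_numpy(dtype=float)
    return EdgeMap(velocities=v, frame_interval=frame_interval, n_sectors=v.shape[0])
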