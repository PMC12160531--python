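"""Plain-text readers/writers for the exchange formats the analysis consumes.

* velocity volumes: ASCII legacy-VTK STRUCTURED_POINTS files with a
  3-component ``VECTORS velocity`` point array, one file per time frame
  (the dialect 4D-flow post-processing pipelines commonly emit);
* WSS frames: one CSV per frame with columns
  ``face_index,tau_x,tau_y,tau_z``;
* free-edge polylines: CSV with ``x,y,z`` per row, one file per leaflet.

Out-of-lumen grid points are carried as NaN vectors in memory; in the VTK
files they are stored as the sentinel value 9.9e30 (legacy VTK ASCII has no
NaN convention that all readers accept).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .hemodynamic_metrics import VelocityVolume
from .valve_geometry import SurfaceMesh
from .wss_metrics import WSSFieldSeries

__all__ = [
    "write_velocity_vtk",
    "read_velocity_vtk",
    "write_velocity_volume",
    "read_velocity_volume",
    "write_wss_frames_csv",
    "read_wss_frames_csv",
    "write_polyline_csv",
    "read_polyline_csv",
]

_NAN_SENTINEL = 9.9e30


def write_velocity_vtk(path: str | Path, axes, frame: np.ndarray) -> None:
    """Write one velocity snapshot as ASCII legacy VTK STRUCTURED_POINTS."""
    x, y, z = (np.asarray(a, dtype=float) for a in axes)
    nx, ny, nz = x.size, y.size, z.size
    if frame.shape != (nx, ny, nz, 3):
        raise ValueError("frame shape does not match axes")
    spacing = (x[1] - x[0], y[1] - y[0], z[1] - z[0])
    # VTK orders points with x varying fastest
    data = np.transpose(frame, (2, 1, 0, 3)).reshape(-1, 3).copy()
    data[~np.isfinite(data)] = _NAN_SENTINEL
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nvelocity snapshot\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {x[0]:.9g} {y[0]:.9g} {z[0]:.9g}\n")
        fh.write(f"SPACING {spacing[0]:.9g} {spacing[1]:.9g} {spacing[2]:.9g}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write("VECTORS velocity float\n")
        np.savetxt(fh, data, fmt="%.9g")


def read_velocity_vtk(path: str | Path) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray], np.ndarray]:
    """Read one ASCII legacy VTK STRUCTURED_POINTS velocity snapshot."""
    lines = Path(path).read_text().splitlines()
    header = {}
    data_start = None
    for i, ln in enumerate(lines):
        parts = ln.split()
        if not parts:
            continue
        key = parts[0].upper()
        if key in ("DIMENSIONS", "ORIGIN", "SPACING"):
            header[key] = [float(p) for p in parts[1:4]]
        elif key == "VECTORS":
            data_start = i + 1
            break
    if data_start is None or "DIMENSIONS" not in header:
        raise ValueError(f"{path}: not a structured-points VECTORS file")
    nx, ny, nz = (int(d) for d in header["DIMENSIONS"])
    ox, oy, oz = header["ORIGIN"]
    sx, sy, sz = header["SPACING"]
    vals = np.loadtxt(lines[data_start:]).reshape(nz, ny, nx, 3)
    frame = np.transpose(vals, (2, 1, 0, 3)).astype(float)
    frame[frame >= _NAN_SENTINEL / 10] = np.nan
    axes = (ox + sx * np.arange(nx), oy + sy * np.arange(ny), oz + sz * np.arange(nz))
    return axes, frame


def write_velocity_volume(vol: VelocityVolume, directory: str | Path, stem: str = "frame") -> list[Path]:
    """Write all frames of a volume, one VTK file per time point, plus times.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(vol.n_frames):
        p = directory / f"{stem}_{i:04d}.vtk"
        write_velocity_vtk(p, vol.axes, vol.frames[i])
        paths.append(p)
    pd.DataFrame({"frame": range(vol.n_frames), "time_s": vol.times}).to_csv(
        directory / f"{stem}_times.csv", index=False)
    return paths


def read_velocity_volume(directory: str | Path, stem: str = "frame") -> VelocityVolume:
    directory = Path(directory)
    times = pd.read_csv(directory / f"{stem}_times.csv")["time_s"].to_numpy(float)
    frames = []
    axes = None
    for i in range(times.size):
        axes, frame = read_velocity_vtk(directory / f"{stem}_{i:04d}.vtk")
        frames.append(frame)
    return VelocityVolume(axes, np.stack(frames), times)


def write_wss_frames_csv(series: WSSFieldSeries, directory: str | Path, stem: str = "wss") -> list[Path]:
    """One ``face_index,tau_x,tau_y,tau_z`` CSV per frame, plus times.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(series.times.size):
        p = directory / f"{stem}_{i:04d}.csv"
        pd.DataFrame({
            "face_index": np.arange(series.tau.shape[1]),
            "tau_x": series.tau[i, :, 0],
            "tau_y": series.tau[i, :, 1],
            "tau_z": series.tau[i, :, 2],
        }).to_csv(p, index=False)
        paths.append(p)
    pd.DataFrame({"frame": range(series.times.size), "time_s": series.times}).to_csv(
        directory / f"{stem}_times.csv", index=False)
    return paths


def read_wss_frames_csv(directory: str | Path, mesh: SurfaceMesh, period: float,
                        stem: str = "wss", side_label: str | None = None) -> WSSFieldSeries:
    directory = Path(directory)
    times = pd.read_csv(directory / f"{stem}_times.csv")["time_s"].to_numpy(float)
    frames = []
    for i in range(times.size):
        df = pd.read_csv(directory / f"{stem}_{i:04d}.csv").sort_values("face_index")
        frames.append(df[["tau_x", "tau_y", "tau_z"]].to_numpy(float))
    return WSSFieldSeries(mesh, times, np.stack(frames), period, side_label)


def write_polyline_csv(points: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(points, dtype=float), columns=["x", "y", "z"]).to_csv(path, index=False)


def read_polyline_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path)[["x", "y", "z"]].to_numpy(float)
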