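"""Plain-text I/O: polyline CSV, legacy ASCII VTK, probe CSV, key-value files.

Field snapshots are written as legacy VTK structured points (cell-centred
values emitted as point data), geometry as VTK polydata polylines -- both
readable by ParaView and friends.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

__all__ = [
    "write_polyline_csv",
    "read_polyline_csv",
    "write_geometry_vtk",
    "write_snapshot_vtk",
    "write_probe_csv",
    "write_key_value",
    "config_hash",
]


def _polyline_items(geom) -> list[tuple[str, np.ndarray]]:
    items = [
        ("outer_wall_lower", geom.outer_wall_polylines[0]),
        ("outer_wall_upper", geom.outer_wall_polylines[1]),
        ("inner_wall_lower", geom.inner_wall_polylines[0]),
        ("inner_wall_upper", geom.inner_wall_polylines[1]),
    ]
    if geom.has_dissection:
        items.append(("flap", geom.flap_polyline))
    if geom.closure_polyline is not None:
        items.append(("closure", geom.closure_polyline))
    return items


def write_polyline_csv(geom, path) -> None:
    """Geometry as rows of (polyline_id, vertex_index, x_mm, y_mm)."""
    rows = []
    for name, poly in _polyline_items(geom):
        for k, (x, y) in enumerate(poly):
            rows.append((name, k, x, y))
    df = pd.DataFrame(rows, columns=["polyline_id", "vertex_index", "x_mm", "y_mm"])
    df.to_csv(path, index=False)


def read_polyline_csv(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    out = {}
    for name, g in df.groupby("polyline_id"):
        g = g.sort_values("vertex_index")
        out[str(name)] = g[["x_mm", "y_mm"]].to_numpy(dtype=float)
    return out


def write_geometry_vtk(geom, path) -> None:
    """Legacy ASCII VTK polydata with one polyline per boundary curve."""
    items = _polyline_items(geom)
    pts = np.vstack([poly for _, poly in items])
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("dissected vessel boundary polylines (mm)\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        for x, y in pts:
            fh.write(f"{x:.6f} {y:.6f} 0.0\n")
        nlines = len(items)
        size = sum(len(poly) + 1 for _, poly in items)
        fh.write(f"LINES {nlines} {size}\n")
        start = 0
        for _, poly in items:
            n = len(poly)
            fh.write(" ".join([str(n)] + [str(start + k) for k in range(n)]) + "\n")
            start += n


def write_snapshot_vtk(snap, path, extra_fields: dict[str, np.ndarray] | None = None
                       ) -> None:
    """Legacy ASCII VTK structured points of one field snapshot.

    Velocities are averaged to cell centres; spacing and origin are in mm.
    """
    nx, ny = snap.p.shape
    dx = snap.grid.spacing
    u_c = 0.5 * (snap.u[1:, :] + snap.u[:-1, :])
    v_c = 0.5 * (snap.v[:, 1:] + snap.v[:, :-1])
    fields = {"pressure_pa": snap.p, "velocity_x_m_s": u_c, "velocity_y_m_s": v_c}
    if extra_fields:
        fields.update(extra_fields)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"field snapshot t={snap.time:.6f}s\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} 1\n")
        fh.write(f"ORIGIN {dx/2:.6f} {dx/2:.6f} 0.0\n")
        fh.write(f"SPACING {dx:.6f} {dx:.6f} 1.0\n")
        fh.write(f"POINT_DATA {nx*ny}\n")
        for name, arr in fields.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            # VTK expects x fastest
            for j in range(ny):
                fh.write(" ".join(f"{arr[i, j]:.6g}" for i in range(nx)) + "\n")


def write_probe_csv(result, path) -> None:
    """Long-form probe series: time_s, value, site, quantity."""
    rows = []
    for site, d in result.probes.items():
        for q, v in d.items():
            rows.append(pd.DataFrame({
                "time_s": result.times, "value": v, "site": site, "quantity": q}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def write_key_value(data: dict, path) -> None:
    with open(path, "w") as fh:
        for k, v in data.items():
            fh.write(f"{k}\t{json.dumps(v, default=str)}\n")


def config_hash(config) -> str:
    """Stable short hash of a simulation config (for run-log provenance)."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_wall_series_csv(series_list, path, time_stride: int = 8) -> None:
    """Wall shear series as long-form CSV:
    face, station_mm, time_s, wss_pa, wssg_pa_per_mm."""
    frames = []
    for ser in series_list:
        tsel = np.arange(0, ser.times.size, max(time_stride, 1))
        for k in tsel:
            frames.append(pd.DataFrame({
                "face": ser.face,
                "station_mm": ser.arclength,
                "time_s": ser.times[k],
                "wss_pa": ser.wss[k],
                "wssg_pa_per_mm": (ser.wssg[k] if ser.wssg is not None
                                   else np.nan),
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
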