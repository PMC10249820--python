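"""Minimal legacy-ASCII VTK writers for field snapshots and vessel networks.

Image-data (STRUCTURED_POINTS) files hold scalar fields on the simulation
lattice; polyline (POLYDATA) files hold the vessel network with per-segment
radius, flow, shear and perfusion attributes.  Flat binary dumps with a JSON
sidecar are provided for programmatic re-loading.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np


def write_structured_points(path, arrays: dict[str, np.ndarray], spacing,
                            title: str = "tmesim fields") -> None:
    """Write named scalar fields (same shape) as one legacy VTK file."""
    first = next(iter(arrays.values()))
    nx, ny, nz = first.shape
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        "ORIGIN 0 0 0",
        f"SPACING {spacing[0]} {spacing[1]} {spacing[2]}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    for name, arr in arrays.items():
        if arr.shape != first.shape:
            raise ValueError(f"field {name!r} has mismatched shape")
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        # VTK expects x fastest: transpose to z,y,x then ravel
        flat = np.asarray(arr, dtype=float).transpose(2, 1, 0).ravel()
        lines.extend(" ".join(f"{v:.6g}" for v in chunk)
                     for chunk in np.array_split(flat, max(1, len(flat) // 9)))
    Path(path).write_text("\n".join(lines) + "\n")


def write_network(path, network, spacing) -> None:
    """Write the vessel graph as VTK polylines with per-segment attributes."""
    nodes = sorted(network.graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = list(network.graph.edges(data=True))
    lines = [
        "# vtk DataFile Version 3.0",
        "tmesim vessel network",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(nodes)} float",
    ]
    for n in nodes:
        lines.append(f"{n[0] * spacing[0]:.6g} {n[1] * spacing[1]:.6g} "
                     f"{n[2] * spacing[2]:.6g}")
    lines.append(f"LINES {len(edges)} {3 * len(edges)}")
    for a, b, _ in edges:
        lines.append(f"2 {index[a]} {index[b]}")
    lines.append(f"CELL_DATA {len(edges)}")
    for attr in ("radius", "flow", "shear"):
        lines.append(f"SCALARS {attr} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{attrs[attr]:.6g}" for _, _, attrs in edges)
    lines.append("SCALARS perfused int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(int(attrs["perfused"])) for _, _, attrs in edges)
    Path(path).write_text("\n".join(lines) + "\n")


def write_flat(path_base, arrays: dict[str, np.ndarray], spacing,
               time_days: float) -> None:
    """Flat float64 binary dump per field plus a JSON sidecar."""
    base = Path(path_base)
    meta = {"spacing_mm": list(spacing), "time_days": time_days, "fields": {}}
    for name, arr in arrays.items():
        fn = base.with_suffix(f".{name}.raw")
        np.asarray(arr, dtype="<f8").tofile(fn)
        meta["fields"][name] = {"file": fn.name, "shape": list(arr.shape),
                                "dtype": "<f8"}
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1))
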