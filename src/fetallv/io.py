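"""File formats: native mesh JSON, legacy-ASCII VTK export, configs, CSV.

The native mesh format is JSON and preserves every Hermite derivative DOF
exactly; VTK export subdivides the Hermite elements into hexahedra for
visualisation.  Configuration files are YAML (JSON accepted).  All CSV
outputs carry units in their headers and are re-readable by the package's
own readers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import GeometryParams, HermiteMesh

__all__ = [
    "RunConfig",
    "save_mesh",
    "load_mesh",
    "export_vtk",
    "save_config",
    "load_config",
    "trajectory_to_csv",
    "read_trajectory_csv",
]


@dataclass
class RunConfig:
    """Serializable description of a simulation run."""

    geometry: dict = field(default_factory=dict)
    material: dict = field(default_factory=dict)
    growth: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)
    output_dir: str = "."
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {k: d[k] for k in cls.__dataclass_fields__ if k in d}
        return cls(**known)


def save_config(config: RunConfig, path) -> None:
    path = Path(path)
    text = yaml.safe_dump(config.to_dict(), sort_keys=False)
    path.write_text(text)


def load_config(path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    return RunConfig.from_dict(data)


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def save_mesh(mesh: HermiteMesh, path) -> None:
    """Write the native JSON mesh format (derivative DOFs exact)."""
    doc = {
        "format": "fetallv-hermite-mesh",
        "version": 1,
        "units": {"length": "mm"},
        "focal_length": mesh.focal_length,
        "mu_base": mesh.mu_base,
        "endo_angle": mesh.endo_angle,
        "epi_angle": mesh.epi_angle,
        "dofs": mesh.dofs.tolist(),
    }
    if mesh.params is not None:
        doc["geometry_params"] = {
            "long_axis": mesh.params.long_axis,
            "short_axis": mesh.params.short_axis,
            "wall_thickness": mesh.params.wall_thickness,
            "base_truncation_mu": mesh.params.base_truncation_mu,
        }
    Path(path).write_text(json.dumps(doc))


def load_mesh(path) -> HermiteMesh:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "fetallv-hermite-mesh":
        raise ValueError(f"{path} is not a native mesh file")
    params = None
    if "geometry_params" in doc:
        params = GeometryParams(**doc["geometry_params"])
    return HermiteMesh(
        np.array(doc["dofs"]),
        doc["focal_length"],
        doc["mu_base"],
        params,
        doc.get("endo_angle", 83.0),
        doc.get("epi_angle", -37.0),
    )


def export_vtk(mesh: HermiteMesh, path, n_sub: int = 3, n_phi: int = 24) -> None:
    """Legacy-ASCII VTK unstructured grid of the swept, subdivided mesh.

    Each in-plane Hermite element is subdivided ``n_sub`` times per
    direction; the circumferential sweep uses ``n_phi`` segments of linear
    hexahedra.
    """
    from .geometry import N_LONG, N_TRANS

    n1 = N_LONG * n_sub + 1
    n2 = N_TRANS * n_sub + 1
    xs = np.linspace(0.0, 1.0, n1)
    ts = np.linspace(0.0, 1.0, n2)
    X1, X2 = np.meshgrid(xs, ts, indexing="ij")
    e1 = np.minimum((X1 * N_LONG).astype(int), N_LONG - 1)
    e2 = np.minimum((X2 * N_TRANS).astype(int), N_TRANS - 1)
    s = X1 * N_LONG - e1
    t = X2 * N_TRANS - e2
    op = mesh.grid.operator(e1.ravel(), e2.ravel(), s.ravel(), t.ravel())
    R = (op @ mesh.dofs_r).reshape(n1, n2)
    Z = (op @ mesh.dofs_z).reshape(n1, n2)

    phis = 2.0 * np.pi * np.arange(n_phi) / n_phi
    pts = []
    for k, ph in enumerate(phis):
        x = Z
        y = R * np.cos(ph)
        z = R * np.sin(ph)
        pts.append(np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1))
    points = np.concatenate(pts, axis=0)
    npl = n1 * n2  # points per phi layer

    def pid(i, j, k):
        return (k % n_phi) * npl + i * n2 + j

    cells = []
    for k in range(n_phi):
        for i in range(n1 - 1):
            for j in range(n2 - 1):
                cells.append(
                    [
                        pid(i, j, k), pid(i + 1, j, k),
                        pid(i + 1, j + 1, k), pid(i, j + 1, k),
                        pid(i, j, k + 1), pid(i + 1, j, k + 1),
                        pid(i + 1, j + 1, k + 1), pid(i, j + 1, k + 1),
                    ]
                )
    lines = [
        "# vtk DataFile Version 3.0",
        "fetallv LV mesh (swept axisymmetric Hermite elements)",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(points)} float",
    ]
    lines += [" ".join(f"{c:.6f}" for c in p) for p in points]
    lines.append(f"CELLS {len(cells)} {9 * len(cells)}")
    lines += ["8 " + " ".join(str(i) for i in c) for c in cells]
    lines.append(f"CELL_TYPES {len(cells)}")
    lines += ["12"] * len(cells)  # VTK_HEXAHEDRON
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

_TRAJ_UNITS = {
    "age": "weeks",
    "cavity_volume": "uL",
    "wall_volume": "uL",
    "long_axis": "mm",
    "short_axis": "mm",
    "wall_thickness": "mm",
    "unloaded_cavity_volume": "uL",
    "mean_fiber_stimulus": "strain",
    "mean_transverse_stimulus": "strain",
}


def trajectory_to_csv(data: pd.DataFrame, path) -> None:
    """Growth trajectory CSV with units embedded in the column headers."""
    out = data.rename(
        columns={c: f"{c} [{u}]" for c, u in _TRAJ_UNITS.items() if c in data}
    )
    out.to_csv(path, index=False)


def read_trajectory_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df.columns = [c.split(" [")[0] for c in df.columns]
    return df
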