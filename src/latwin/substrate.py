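"""Per-node electrophysiological substrate construction.

Builds the tissue description the solver consumes, following the clinical
mapping chain: a sparse electroanatomical (EAM-like) bipolar-voltage point
cloud is interpolated onto the dense node set by inverse-distance
weighting; each node's fibrosis state is drawn by comparing a
voltage-dependent fibrosis probability against a uniform random number;
fiber orientation and longitudinal/transverse conductivities are assigned
per node; and the non-lesion tissue is partitioned into the six-region
left-atrial scheme used for regional biomarker aggregation.

Coordinates are in mm; node indices are 0-based.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .myocyte import ModelError

#: Six-region left-atrial scheme (extra-PV area).
REGION_NAMES = (
    "septum",
    "anterior_wall",
    "left_atrial_appendage",
    "left_lateral_isthmus",
    "posterior_wall",
    "posterior_inferior_wall",
)

#: Default conductivity table (S/m): (fibrotic?, direction) -> sigma.
CONDUCTIVITY_TABLE = {
    "nonfibrotic_longitudinal": 0.1264,
    "fibrotic_longitudinal": 0.0546,
    "nonfibrotic_transverse": 0.0252,
    "fibrotic_transverse": 0.0068,
}


@dataclasses.dataclass
class SheetMesh:
    """Regular 2D sheet of nx x ny nodes at fixed spacing (mm), z = 0.

    Node i = iy * nx + ix.  Triangulated (two triangles per cell) so the
    surface can be exported in standard formats.
    """

    nx: int
    ny: int
    spacing_mm: float

    def __post_init__(self):
        if self.nx < 2 or self.ny < 2:
            raise ModelError("sheet needs at least 2x2 nodes")
        if not self.spacing_mm > 0:
            raise ModelError("spacing must be positive")

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    @property
    def points(self) -> np.ndarray:
        ix, iy = np.meshgrid(np.arange(self.nx), np.arange(self.ny))
        pts = np.zeros((self.n_nodes, 3))
        pts[:, 0] = ix.ravel() * self.spacing_mm
        pts[:, 1] = iy.ravel() * self.spacing_mm
        return pts

    @property
    def extent_mm(self) -> tuple[float, float]:
        return ((self.nx - 1) * self.spacing_mm, (self.ny - 1) * self.spacing_mm)

    @property
    def faces(self) -> np.ndarray:
        f = []
        for iy in range(self.ny - 1):
            for ix in range(self.nx - 1):
                a = iy * self.nx + ix
                b = a + 1
                c = a + self.nx
                d = c + 1
                f.append((a, b, d))
                f.append((a, d, c))
        return np.asarray(f, dtype=np.int64)

    def save_ply(self, path) -> None:
        import trimesh

        trimesh.Trimesh(vertices=self.points, faces=self.faces,
                        process=False).export(str(path))


@dataclasses.dataclass
class VoltagePointCloud:
    """Sparse bipolar-voltage samples: points (m, 3) in mm, values in mV."""

    points: np.ndarray
    values_mV: np.ndarray

    def __post_init__(self):
        p = np.atleast_2d(np.asarray(self.points, dtype=float))
        v = np.asarray(self.values_mV, dtype=float).ravel()
        if p.shape[0] == 0:
            raise ModelError("point cloud must contain at least one point")
        if p.shape[1] == 2:
            p = np.column_stack([p, np.zeros(p.shape[0])])
        if p.shape[0] != v.shape[0]:
            raise ModelError("points and values must have matching length")
        if np.any(v < 0):
            raise ModelError("bipolar voltages must be >= 0")
        self.points = p
        self.values_mV = v

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "x_mm": self.points[:, 0], "y_mm": self.points[:, 1],
            "z_mm": self.points[:, 2], "voltage_mV": self.values_mV,
        })

    @classmethod
    def from_frame(cls, df) -> "VoltagePointCloud":
        return cls(df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
                   df["voltage_mV"].to_numpy())


def idw_interpolate(cloud: VoltagePointCloud, nodes: np.ndarray,
                    radius_mm: float = 10.0, power: float = 2.0,
                    eps_mm: float = 1e-9):
    """Inverse-distance-weighted interpolation of sparse samples onto nodes.

    Node value = sum(w_i R_i) / sum(w_i) with w_i = d_i^-power over cloud
    points within ``radius_mm``.  A node coincident with a sample returns
    that sample's value exactly.  Nodes with no sample within the radius
    are filled from the nearest sample and flagged uncovered.

    Returns (values_mV, covered_mask).
    """
    if not radius_mm > 0:
        raise ModelError("radius must be positive")
    if not power > 0:
        raise ModelError("power must be positive")
    nodes = np.atleast_2d(np.asarray(nodes, dtype=float))
    if nodes.shape[1] == 2:
        nodes = np.column_stack([nodes, np.zeros(nodes.shape[0])])
    tree = cKDTree(cloud.points)
    neighbor_lists = tree.query_ball_point(nodes, r=radius_mm)
    values = np.empty(nodes.shape[0])
    covered = np.ones(nodes.shape[0], dtype=bool)
    # nearest-sample fallback for uncovered nodes
    d_near, i_near = tree.query(nodes, k=1)
    for k, idx in enumerate(neighbor_lists):
        if len(idx) == 0:
            covered[k] = False
            values[k] = cloud.values_mV[i_near[k]]
            continue
        d = np.linalg.norm(cloud.points[idx] - nodes[k], axis=1)
        if d.min() < eps_mm:
            values[k] = cloud.values_mV[idx[int(np.argmin(d))]]
            continue
        w = d ** (-power)
        values[k] = float(np.dot(w, cloud.values_mV[idx]) / w.sum())
    return values, covered


def fibrosis_probability(voltage_mV):
    """Probability of fibrosis at a node from its bipolar voltage (mV).

    Piecewise: 1 below 0 mV; a calibrated cubic
    (1/100)(-40 V^3 + 155 V^2 - 206 V + 99.8) on [0, 1.74] mV, clamped to
    [0, 1] (the raw cubic is slightly negative at the 1.74 mV boundary);
    0 above 1.74 mV.  Vectorized over arrays.
    """
    v = np.asarray(voltage_mV, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ModelError("voltage must be finite")
    p = np.where(
        v < 0.0, 1.0,
        np.where(v > 1.74, 0.0,
                 (-40.0 * v ** 3 + 155.0 * v ** 2 - 206.0 * v + 99.8) / 100.0),
    )
    p = np.clip(p, 0.0, 1.0)
    return p if p.ndim else float(p)


def assign_fibrosis(voltages_mV: np.ndarray, seed: int) -> np.ndarray:
    """Stochastic fibrosis mask: node fibrotic iff U(0,1) < P_fibrosis(V)."""
    rng = np.random.default_rng(seed)
    p = fibrosis_probability(voltages_mV)
    return rng.random(np.shape(voltages_mV)) < p


def build_fiber_field(mesh: SheetMesh, mode: str = "uniform",
                      params: Mapping | None = None) -> np.ndarray:
    """Per-node unit fiber directions (in-plane for sheets).

    Modes:
      - ``uniform``: constant angle (deg, param ``angle_deg``, default 0).
      - ``circular``: tangential around a center (param ``center_mm``,
        default sheet center), emulating circumferential bundles.
      - ``atlas_like``: smoothly rotating parametric field,
        angle = base + gain * (y / Ly) (params ``angle_deg``,
        ``twist_deg``), a stand-in for atlas-derived orientation.
    """
    params = dict(params or {})
    pts = mesh.points
    n = mesh.n_nodes
    if mode == "uniform":
        a = np.deg2rad(params.get("angle_deg", 0.0))
        vec = np.tile([np.cos(a), np.sin(a), 0.0], (n, 1))
    elif mode == "circular":
        lx, ly = mesh.extent_mm
        cx, cy = params.get("center_mm", (lx / 2.0, ly / 2.0))
        dx = pts[:, 0] - cx
        dy = pts[:, 1] - cy
        r = np.hypot(dx, dy)
        r[r < 1e-12] = 1.0
        vec = np.column_stack([-dy / r, dx / r, np.zeros(n)])
    elif mode == "atlas_like":
        lx, ly = mesh.extent_mm
        base = np.deg2rad(params.get("angle_deg", 0.0))
        twist = np.deg2rad(params.get("twist_deg", 60.0))
        a = base + twist * pts[:, 1] / max(ly, 1e-12)
        vec = np.column_stack([np.cos(a), np.sin(a), np.zeros(n)])
    else:
        raise ModelError(f"unknown fiber mode {mode!r}")
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    return vec


def assign_conductivity(fibrotic: np.ndarray,
                        table: Mapping[str, float] | None = None):
    """Per-node (sigma_l, sigma_t) in S/m from the 4-entry conductivity table."""
    table = dict(table if table is not None else CONDUCTIVITY_TABLE)
    for key in CONDUCTIVITY_TABLE:
        if key not in table:
            raise ModelError(f"conductivity table missing entry {key!r}")
    fib = np.asarray(fibrotic, dtype=bool)
    sigma_l = np.where(fib, table["fibrotic_longitudinal"],
                       table["nonfibrotic_longitudinal"])
    sigma_t = np.where(fib, table["fibrotic_transverse"],
                       table["nonfibrotic_transverse"])
    return sigma_l, sigma_t


def segment_regions(mesh: SheetMesh, lesion_mask: np.ndarray | None = None) -> np.ndarray:
    """Partition non-lesion sheet nodes into the six-region scheme.

    On synthetic sheets a fixed 2 x 3 block template stands in for
    anatomical segmentation: the sheet is split into three columns and two
    rows; the top row maps to (septum, anterior wall, left atrial
    appendage) and the bottom row to (left lateral isthmus, posterior
    wall, posterior inferior wall), left to right.  Lesion nodes get
    label -1.  Raises if any region would be empty.
    """
    n = mesh.n_nodes
    lesion = (np.zeros(n, dtype=bool) if lesion_mask is None
              else np.asarray(lesion_mask, dtype=bool))
    ix = np.arange(n) % mesh.nx
    iy = np.arange(n) // mesh.nx
    col = np.minimum(ix * 3 // mesh.nx, 2)
    row = np.minimum(iy * 2 // mesh.ny, 1)
    labels = (row * 3 + col).astype(np.int64)
    labels[lesion] = -1
    for r, name in enumerate(REGION_NAMES):
        if not np.any(labels == r):
            raise ModelError(f"region {name!r} would be empty on this geometry")
    return labels


@dataclasses.dataclass
class SubstrateMap:
    """Complete per-node substrate: everything the tissue solver needs."""

    mesh: SheetMesh
    voltage_mV: np.ndarray
    covered: np.ndarray
    fibrotic: np.ndarray
    fiber: np.ndarray
    sigma_l: np.ndarray
    sigma_t: np.ndarray
    region: np.ndarray
    lesion: np.ndarray

    def __post_init__(self):
        n = self.mesh.n_nodes
        for name in ("voltage_mV", "covered", "fibrotic", "sigma_l",
                     "sigma_t", "region", "lesion"):
            arr = getattr(self, name)
            if np.shape(arr)[0] != n:
                raise ModelError(f"substrate field {name!r} has wrong length")
        if self.fiber.shape != (n, 3):
            raise ModelError("fiber field must be (n_nodes, 3)")
        norms = np.linalg.norm(self.fiber, axis=1)
        if np.max(np.abs(norms - 1.0)) > 1e-9:
            raise ModelError("fiber vectors must be unit-norm")
        if np.any(self.sigma_t <= 0) or np.any(self.sigma_l < self.sigma_t):
            raise ModelError("conductivities must satisfy sigma_l >= sigma_t > 0")

    @property
    def fibrotic_fraction(self) -> float:
        return float(np.mean(self.fibrotic[~self.lesion]))

    def to_frame(self):
        import pandas as pd

        pts = self.mesh.points
        return pd.DataFrame({
            "node_id": np.arange(self.mesh.n_nodes),
            "x_mm": pts[:, 0], "y_mm": pts[:, 1], "z_mm": pts[:, 2],
            "voltage_mV": self.voltage_mV,
            "covered": self.covered.astype(int),
            "fibrotic": self.fibrotic.astype(int),
            "fiber_x": self.fiber[:, 0], "fiber_y": self.fiber[:, 1],
            "fiber_z": self.fiber[:, 2],
            "sigma_l_Spm": self.sigma_l, "sigma_t_Spm": self.sigma_t,
            "region": self.region, "lesion": self.lesion.astype(int),
        })


def build_substrate(mesh: SheetMesh, cloud: VoltagePointCloud, seed: int,
                    fiber_mode: str = "uniform",
                    fiber_params: Mapping | None = None,
                    lesion_mask: np.ndarray | None = None,
                    radius_mm: float = 10.0, power: float = 2.0,
                    conductivity_table: Mapping[str, float] | None = None) -> SubstrateMap:
    """Full substrate chain: IDW -> fibrosis draw -> fibers -> conductivity -> regions."""
    n = mesh.n_nodes
    lesion = (np.zeros(n, dtype=bool) if lesion_mask is None
              else np.asarray(lesion_mask, dtype=bool))
    voltage, covered = idw_interpolate(cloud, mesh.points, radius_mm, power)
    fibrotic = assign_fibrosis(voltage, seed)
    fibrotic[lesion] = False
    fiber = build_fiber_field(mesh, fiber_mode, fiber_params)
    sigma_l, sigma_t = assign_conductivity(fibrotic, conductivity_table)
    region = segment_regions(mesh, lesion)
    return SubstrateMap(mesh=mesh, voltage_mV=voltage, covered=covered,
                        fibrotic=fibrotic, fiber=fiber,
                        sigma_l=sigma_l, sigma_t=sigma_t,
                        region=region, lesion=lesion)
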