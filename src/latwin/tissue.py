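"""Monodomain reaction-diffusion solver on 2D sheets.

Membrane dynamics follow the atrial ionic model (``myocyte``); wave
propagation follows the monodomain equation

    dVm/dt = div( D grad Vm ) - (I_ion + I_stim) / Cm

with a per-node anisotropic diffusion tensor built from the fiber
direction f and the longitudinal/transverse conductivities:

    D = Dt * I + (Dl - Dt) * f f^T,      Dl,t = scale * sigma_{l,t} / (chi * Cm)

where chi is the surface-to-volume ratio and Cm the membrane capacitance
per area.  The spatial operator is a conservative finite-volume stencil on
the uniform grid: diagonal-tensor fluxes use harmonic edge averaging,
mixed-derivative fluxes use arithmetic averaging; boundary and lesion
edges carry zero flux (no-flux Neumann conditions).  Lesion nodes are
decoupled and held non-excitable.

Time integration is operator splitting with a shared explicit step for
reaction and diffusion (default dt = 0.05 ms; the declared bounds —
reaction dt <= 0.1 ms and the diffusion CFL dt <= h^2/(4 Dmax) — are
enforced at run time).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp

from . import _kernels as K
from .myocyte import (DT_MAX, ConductanceScaling, ModelError, MyocyteState,
                      ach_prefactor, rate_table)
from .substrate import SubstrateMap

#: Monodomain conversion sigma (S/m) -> D (mm^2/ms) at scale 1:
#: 1/(chi * Cm) with chi = 1400 /cm and Cm = 1 uF/cm^2.
SIGMA_TO_D = 0.71429

#: Default tissue time step (ms).
DT_TISSUE = 0.05

#: Default activation-detection threshold (mV).
ACT_THRESHOLD = -40.0


class ConductionBlock(RuntimeError):
    """Raised when a propagation measurement finds no conducted wave."""


class CalibrationError(RuntimeError):
    """Raised when no diffusion scale in the bracket meets the target."""


@dataclasses.dataclass(frozen=True)
class StimulusEvent:
    """Rectangular depolarizing stimulus on a node set (amplitude in pA/pF)."""

    nodes: np.ndarray
    onset_ms: float
    duration_ms: float = 2.0
    amplitude: float = 40.0

    def __post_init__(self):
        object.__setattr__(self, "nodes",
                           np.asarray(self.nodes, dtype=np.int64).ravel())
        if self.nodes.size == 0:
            raise ModelError("stimulus needs at least one node")
        if not self.duration_ms > 0 or not self.amplitude > 0:
            raise ModelError("stimulus duration and amplitude must be positive")


@dataclasses.dataclass
class SimulationTrace:
    """Recorded tissue run: subsampled Vm frames plus exact activation times."""

    frame_times_ms: np.ndarray
    frames: np.ndarray  # (n_frames, n_nodes), float32, mV
    act_times: np.ndarray  # (n_nodes, max_act), NaN-padded, ms
    act_counts: np.ndarray  # (n_nodes,)
    dt_ms: float
    t_end_ms: float
    meta: dict = dataclasses.field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.frames.shape[1]

    def node_activations(self, node: int) -> np.ndarray:
        return self.act_times[node, : self.act_counts[node]]

    def activations_in(self, t0: float, t1: float) -> list[np.ndarray]:
        out = []
        for k in range(self.n_nodes):
            a = self.node_activations(k)
            out.append(a[(a >= t0) & (a < t1)])
        return out

    def vm(self, node: int) -> np.ndarray:
        return self.frames[:, node].astype(float)

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("frame_times_ms", data=self.frame_times_ms)
            f.create_dataset("frames", data=self.frames, compression="gzip")
            f.create_dataset("act_times", data=self.act_times, compression="gzip")
            f.create_dataset("act_counts", data=self.act_counts)
            f.attrs["dt_ms"] = self.dt_ms
            f.attrs["t_end_ms"] = self.t_end_ms
            for k, v in self.meta.items():
                f.attrs[f"meta_{k}"] = v

    @classmethod
    def load(cls, path) -> "SimulationTrace":
        import h5py

        with h5py.File(path, "r") as f:
            meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")}
            return cls(frame_times_ms=f["frame_times_ms"][:],
                       frames=f["frames"][:], act_times=f["act_times"][:],
                       act_counts=f["act_counts"][:],
                       dt_ms=float(f.attrs["dt_ms"]),
                       t_end_ms=float(f.attrs["t_end_ms"]), meta=meta)


@dataclasses.dataclass
class TissueGrid:
    """Discretized tissue: geometry, diffusion operator, substrate reference."""

    substrate: SubstrateMap
    laplacian: sp.csr_matrix  # 1/ms, at diffusion scale 1
    diffusion_scale: float
    active: np.ndarray  # False at lesion nodes
    d_max: float  # max principal D (mm^2/ms) at scale 1, for CFL checks

    @property
    def n_nodes(self) -> int:
        return self.substrate.mesh.n_nodes

    def with_scale(self, scale: float) -> "TissueGrid":
        return dataclasses.replace(self, diffusion_scale=float(scale))

    def node_at(self, x_mm: float, y_mm: float) -> int:
        mesh = self.substrate.mesh
        ix = int(round(x_mm / mesh.spacing_mm))
        iy = int(round(y_mm / mesh.spacing_mm))
        ix = min(max(ix, 0), mesh.nx - 1)
        iy = min(max(iy, 0), mesh.ny - 1)
        return iy * mesh.nx + ix

    def disc_nodes(self, x_mm: float, y_mm: float, radius_mm: float) -> np.ndarray:
        pts = self.substrate.mesh.points
        d = np.hypot(pts[:, 0] - x_mm, pts[:, 1] - y_mm)
        nodes = np.flatnonzero((d <= radius_mm) & self.active)
        if nodes.size == 0:
            raise ModelError("no active nodes within stimulus disc")
        return nodes


def _edge_entries(nx, ny, h, dxx, dyy, dxy, active):
    """COO entries of the conservative anisotropic Laplacian (1/ms).

    Diagonal-tensor fluxes use harmonic edge averaging on the 5-point
    stencil.  The cross term is assembled as M + M^T where M is the
    conservative discretization of d/dx(Dxy dV/dy) (x-edge fluxes with
    arithmetic Dxy averaging and centered y-derivatives); adding the
    transpose supplies the adjoint term d/dy(Dxy dV/dx), making the full
    operator symmetric while keeping both row and column sums zero.
    """
    rows, cols, vals = [], [], []
    inv_h2 = 1.0 / (h * h)
    m_rows, m_cols, m_vals = [], [], []

    def add(a, b, w):
        if w != 0.0:
            rows.append(a)
            cols.append(b)
            vals.append(w)

    def madd(a, b, w):
        if w != 0.0:
            m_rows.append(a)
            m_cols.append(b)
            m_vals.append(w)

    def harm(a, b):
        if a <= 0.0 or b <= 0.0:
            return 0.0
        return 2.0 * a * b / (a + b)

    def ydiff_terms(node):
        """Centered y-derivative stencil of V at `node` (coeff units 1)."""
        iy = node // nx
        up = node + nx if iy + 1 < ny and active[node + nx] else None
        dn = node - nx if iy - 1 >= 0 and active[node - nx] else None
        if up is None or dn is None:
            return []
        return [(up, 0.5), (dn, -0.5)]

    for iy in range(ny):
        for ix in range(nx):
            a = iy * nx + ix
            if not active[a]:
                continue
            # horizontal edge a -- a+1: diagonal flux + full cross flux
            if ix + 1 < nx and active[a + 1]:
                b = a + 1
                w = harm(dxx[a], dxx[b]) * inv_h2
                add(a, b, w); add(a, a, -w)
                add(b, a, w); add(b, b, -w)
                dxy_e = 0.5 * (dxy[a] + dxy[b])
                if dxy_e != 0.0:
                    for idx, c in ydiff_terms(a) + ydiff_terms(b):
                        w = dxy_e * 0.5 * c * inv_h2
                        madd(a, idx, w)
                        madd(b, idx, -w)
            # vertical edge a -- a+nx: diagonal flux only
            if iy + 1 < ny and active[a + nx]:
                b = a + nx
                w = harm(dyy[a], dyy[b]) * inv_h2
                add(a, b, w); add(a, a, -w)
                add(b, a, w); add(b, b, -w)
    # cross term: M + M^T
    rows += m_rows + m_cols
    cols += m_cols + m_rows
    vals += m_vals + m_vals
    return rows, cols, vals


def build_grid(substrate: SubstrateMap, diffusion_scale: float = 1.0,
               sigma_to_d: float = SIGMA_TO_D) -> TissueGrid:
    """Assemble the anisotropic diffusion operator for a substrate.

    The per-node tensor is D = Dt I + (Dl - Dt) f f^T with
    D{l,t} = sigma_to_d * sigma_{l,t}; lesion nodes are decoupled.  Warns
    (via the returned grid's meta) if the active graph is disconnected.
    """
    mesh = substrate.mesh
    n = mesh.n_nodes
    active = ~np.asarray(substrate.lesion, dtype=bool)
    dl = sigma_to_d * substrate.sigma_l
    dt_ = sigma_to_d * substrate.sigma_t
    fx = substrate.fiber[:, 0]
    fy = substrate.fiber[:, 1]
    dxx = dt_ + (dl - dt_) * fx * fx
    dyy = dt_ + (dl - dt_) * fy * fy
    dxy = (dl - dt_) * fx * fy
    dxx = np.where(active, dxx, 0.0)
    dyy = np.where(active, dyy, 0.0)
    dxy = np.where(active, dxy, 0.0)
    rows, cols, vals = _edge_entries(mesh.nx, mesh.ny, mesh.spacing_mm,
                                     dxx, dyy, dxy, active)
    lap = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    lap.sum_duplicates()
    return TissueGrid(substrate=substrate, laplacian=lap,
                      diffusion_scale=float(diffusion_scale), active=active,
                      d_max=float(np.max(dl)) if n else 0.0)


def lesion_mask_rings(mesh, rings: Sequence[tuple[float, float, float, float]],
                      holes: Sequence[tuple[float, float, float]] = ()) -> np.ndarray:
    """Boolean lesion mask from ring and hole primitives.

    ``rings``: (cx_mm, cy_mm, radius_mm, width_mm) annuli (ablation lines
    around a vein); ``holes``: (cx, cy, radius) filled discs (the vein
    ostia themselves, non-tissue).
    """
    pts = mesh.points
    mask = np.zeros(mesh.n_nodes, dtype=bool)
    for cx, cy, r, wdt in rings:
        d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
        mask |= (d >= r - wdt / 2.0) & (d <= r + wdt / 2.0)
    for cx, cy, r in holes:
        d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
        mask |= d <= r
    return mask


def apply_lesions(grid: TissueGrid,
                  rings: Sequence[tuple[float, float, float, float]] = (),
                  holes: Sequence[tuple[float, float, float]] = ()) -> TissueGrid:
    """Return a new grid with additional ring/hole lesions burned in.

    Lesion nodes are decoupled from the diffusion operator and clamped
    non-excitable.  An empty lesion spec returns an equivalent grid.
    """
    mask = lesion_mask_rings(grid.substrate.mesh, rings, holes)
    new_lesion = grid.substrate.lesion | mask
    if np.all(new_lesion):
        raise ModelError("lesion spec covers all tissue")
    sub = dataclasses.replace(grid.substrate, lesion=new_lesion)
    sub.fibrotic = sub.fibrotic & ~new_lesion
    return build_grid(sub, grid.diffusion_scale)


def build_scaling_field(substrate: SubstrateMap,
                        remodeling: ConductanceScaling | None = None,
                        blockade=None) -> np.ndarray:
    """(13, n_nodes) per-node conductance factors.

    Composes, in any order (multiplicative): the AF-remodeling profile on
    every node, the fibrotic profile on fibrotic nodes, and a drug
    blockade (1 - theta) on every node.
    """
    from .myocyte import CHANNELS
    from .pharmacology import BlockadeVector

    n = substrate.mesh.n_nodes
    base = remodeling.factors if remodeling is not None else np.ones(len(CHANNELS))
    scal = np.tile(base.reshape(-1, 1), (1, n))
    fib = ConductanceScaling.fibrotic().factors
    scal[:, substrate.fibrotic] *= fib.reshape(-1, 1)
    if blockade is not None:
        if isinstance(blockade, BlockadeVector):
            theta = blockade.theta
        else:
            theta = np.asarray(blockade, dtype=float)
        scal *= (1.0 - theta).reshape(-1, 1)
    return np.ascontiguousarray(scal)


def _stim_arrays(stimuli: Sequence[StimulusEvent]):
    n_stim = len(stimuli)
    start = np.array([s.onset_ms for s in stimuli], dtype=float)
    stop = np.array([s.onset_ms + s.duration_ms for s in stimuli], dtype=float)
    amp = np.array([s.amplitude for s in stimuli], dtype=float)
    indptr = np.zeros(n_stim + 1, dtype=np.int64)
    nodes = []
    for i, s in enumerate(stimuli):
        nodes.append(s.nodes)
        indptr[i + 1] = indptr[i] + s.nodes.size
    nodes = (np.concatenate(nodes) if nodes else np.zeros(0, dtype=np.int64))
    return start, stop, amp, indptr, nodes


def run(grid: TissueGrid, scaling_field: np.ndarray | None = None,
        stimuli: Sequence[StimulusEvent] = (), t_end_ms: float = 1000.0,
        dt: float = DT_TISSUE, record_dt_ms: float = 2.0,
        ach_uM: float = 0.0, act_threshold: float = ACT_THRESHOLD,
        max_act: int = 256, quiet_stop_ms: float = 0.0,
        initial_states: np.ndarray | None = None) -> SimulationTrace:
    """Integrate the monodomain system and return the recorded trace.

    Deterministic for a fixed configuration.  Aborts with a diagnostic on
    instability (|Vm| > 200 mV) or NaN.  With ``quiet_stop_ms`` > 0 the
    integration finishes early once the tissue has been quiescent for
    that long after the last stimulus (the remaining window is filled
    with the resting state, which is exact for this autonomous system).
    """
    n = grid.n_nodes
    if not 0 < dt <= DT_MAX:
        raise ModelError(f"dt={dt} ms outside reaction stability bound (0, {DT_MAX}]")
    d_eff = grid.d_max * grid.diffusion_scale
    if d_eff > 0:
        h = grid.substrate.mesh.spacing_mm
        dt_cfl = h * h / (4.0 * d_eff)
        if dt > dt_cfl:
            raise ModelError(
                f"dt={dt} ms violates diffusion CFL bound {dt_cfl:.4f} ms "
                f"(h={h} mm, D={d_eff:.4g} mm^2/ms)")
    if scaling_field is None:
        scaling_field = np.ones((K.N_CHAN, n))
    scal = np.ascontiguousarray(np.asarray(scaling_field, dtype=float).T)
    if initial_states is None:
        states = np.tile(MyocyteState.resting().to_vector().reshape(1, -1),
                         (n, 1))
    else:
        states = initial_states.copy()
    states = np.ascontiguousarray(states)

    lap = (grid.laplacian * grid.diffusion_scale).tocsr()
    n_steps = int(round(t_end_ms / dt))
    rec_every = max(1, int(round(record_dt_ms / dt)))
    n_frames = (n_steps + rec_every - 1) // rec_every
    frames = np.empty((n_frames, n), dtype=np.float32)
    act_times = np.full((n, max_act), np.nan)
    act_counts = np.zeros(n, dtype=np.int64)
    start, stop, amp, indptr, nodes = _stim_arrays(list(stimuli))

    status, step, node = K.integrate(
        states, scal, ach_prefactor(ach_uM), rate_table(dt), dt,
        n_steps, 0.0, 10,
        lap.indptr.astype(np.int64), lap.indices.astype(np.int64), lap.data,
        start, stop, amp, indptr, nodes,
        act_threshold, act_times, act_counts,
        frames, rec_every, grid.active, float(quiet_stop_ms))
    if status != 0:
        kind = "NaN" if status == 2 else "instability (|Vm| > 200 mV)"
        raise ModelError(f"{kind} at t={step * dt:.2f} ms, node {node}")
    return SimulationTrace(
        frame_times_ms=np.arange(n_frames) * rec_every * dt,
        frames=frames, act_times=act_times, act_counts=act_counts,
        dt_ms=dt, t_end_ms=t_end_ms,
        meta={"diffusion_scale": grid.diffusion_scale,
              "record_dt_ms": record_dt_ms})


def measure_cv(grid: TissueGrid, scaling_field: np.ndarray | None = None,
               direction: str = "x", dt: float = DT_TISSUE,
               stim_amplitude: float = 40.0) -> float:
    """Conduction velocity (m/s) of a planar wave along x or y.

    Paces one edge of the sheet and regresses activation time on distance
    over the central half of the domain.  Raises :class:`ConductionBlock`
    if the far half never activates.
    """
    mesh = grid.substrate.mesh
    n = mesh.n_nodes
    ix = np.arange(n) % mesh.nx
    iy = np.arange(n) // mesh.nx
    along = ix if direction == "x" else iy
    n_along = mesh.nx if direction == "x" else mesh.ny
    # pace a ~1-mm-deep edge band so capture does not depend on coupling
    depth = max(1, int(round(1.0 / mesh.spacing_mm)) - 1)
    edge = np.flatnonzero((along <= depth) & grid.active)
    if edge.size == 0:
        raise ModelError("no active nodes on the pacing edge")
    length_ms = 30.0 + (n_along * mesh.spacing_mm) / 0.05  # generous for slow CV
    trace = run(grid, scaling_field,
                [StimulusEvent(edge, 5.0, 2.0, stim_amplitude)],
                t_end_ms=length_ms, dt=dt, record_dt_ms=1e9, max_act=8)
    first = np.where(trace.act_counts > 0, trace.act_times[:, 0], np.nan)
    lo, hi = int(0.25 * n_along), int(0.75 * n_along)
    sel = (along >= lo) & (along < hi) & grid.active & np.isfinite(first)
    n_band = int(np.sum((along >= lo) & (along < hi) & grid.active))
    if sel.sum() < max(8, 0.5 * n_band):
        raise ConductionBlock(
            f"planar wave failed to reach the central band "
            f"({sel.sum()}/{n_band} nodes activated)")
    x = along[sel] * mesh.spacing_mm
    t = first[sel]
    slope = np.polyfit(x, t, 1)[0]  # ms per mm
    if slope <= 0:
        raise ConductionBlock("activation sequence inconsistent with propagation")
    return float(1.0 / slope)  # mm/ms == m/s


def calibrate_diffusion(grid: TissueGrid,
                        target_cv_mps: float | None = None,
                        sustained_check: Callable[[TissueGrid], bool] | None = None,
                        bracket: tuple[float, float] = (0.01, 1.0),
                        tol: float = 0.02, max_iter: int = 30,
                        scaling_field: np.ndarray | None = None,
                        dt: float = DT_TISSUE) -> float:
    """Find a global diffusion scale meeting a calibration target.

    Exactly one target must be given.  For ``target_cv_mps`` a bisection
    on the (monotone) CV-vs-scale relation runs until the relative CV
    error is below ``tol``.  For ``sustained_check`` (a predicate on a
    scaled grid, True when induced AF is still sustained at the end of
    the observation window) a descending bisection-style ladder from the
    upper bracket returns the first sustaining scale.  Raises
    :class:`CalibrationError`, reporting the achieved extremes, when the
    bracket cannot meet the target.
    """
    lo, hi = bracket
    if not (0 < lo < hi):
        raise ModelError("bracket must satisfy 0 < lo < hi")
    if (target_cv_mps is None) == (sustained_check is None):
        raise ModelError("specify exactly one of target_cv_mps / sustained_check")

    if sustained_check is not None:
        scale = hi
        tried = []
        while scale >= lo * (1 - 1e-12):
            ok = sustained_check(grid.with_scale(scale))
            tried.append((scale, ok))
            if ok:
                return float(scale)
            scale *= 0.5
        raise CalibrationError(
            f"no scale in [{lo}, {hi}] sustains AF; tried {tried}")

    def cv_at(s):
        try:
            return measure_cv(grid.with_scale(s), scaling_field, dt=dt)
        except ConductionBlock:
            return 0.0

    cv_lo, cv_hi = cv_at(lo), cv_at(hi)
    if not (min(cv_lo, cv_hi) <= target_cv_mps <= max(cv_lo, cv_hi)):
        raise CalibrationError(
            f"target CV {target_cv_mps} m/s outside achievable range "
            f"[{cv_lo:.3f}, {cv_hi:.3f}] m/s for bracket {bracket}")
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)  # geometric bisection: CV ~ sqrt(scale)
        cv = cv_at(mid)
        if cv > 0 and abs(cv - target_cv_mps) / target_cv_mps < tol:
            return float(mid)
        if (cv < target_cv_mps) == (cv_lo < cv_hi):
            lo = mid
        else:
            hi = mid
    return float(math.sqrt(lo * hi))
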