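"""Synthetic virtual-patient generator.

Stands in for the clinical imaging/EAM inputs: each virtual patient is a
2D atrial sheet with an EAM-like sparse bipolar-voltage point cloud
(>= 500 points, background voltages spanning the 0-1.74 mV fibrosis-active
range with low-voltage patches), a parametric fiber field, and a
vein-hole/PVI-ring lesion template.  Fibrosis heterogeneity arises only
through the voltage cloud and the voltage-to-fibrosis probability chain,
so the full substrate path is exercised.

Everything is reproducible: a patient is a pure function of its spec, and
a cohort is a pure function of (master seed, index).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .myocyte import ConductanceScaling, ModelError
from .protocols import classify_rhythm, find_eas, run_protocol, PacingProtocol
from .substrate import (SheetMesh, SubstrateMap, VoltagePointCloud,
                        build_substrate)
from .tissue import (CalibrationError, StimulusEvent, TissueGrid, build_grid,
                     build_scaling_field, calibrate_diffusion,
                     lesion_mask_rings, run)


@dataclasses.dataclass(frozen=True)
class PatientSpec:
    """Everything that defines one virtual patient (seed fixes it all)."""

    seed: int
    nx: int = 64
    ny: int = 64
    spacing_mm: float = 0.4
    background_voltage_mean_mV: float = 0.9
    background_voltage_sd_mV: float = 0.35
    n_patches: int = 4
    patch_radius_mm: float = 4.0
    patch_voltage_mean_mV: float = 0.15
    patch_voltage_sd_mV: float = 0.1
    n_eam_points: int = 600
    fiber_mode: str = "atlas_like"
    fiber_angle_deg: float = 0.0
    fiber_twist_deg: float = 60.0
    remodeling_profile: str = "chronic_af"
    pace_frac_xy: tuple[float, float] = (0.15, 0.75)

    def __post_init__(self):
        if self.n_eam_points < 1:
            raise ModelError("n_eam_points must be >= 1")
        if min(self.background_voltage_mean_mV, self.patch_voltage_mean_mV) < 0:
            raise ModelError("voltage means must be >= 0")


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Cohort = n patients drawn from parameter ranges under a master seed."""

    n_patients: int = 10
    master_seed: int = 2024
    nx: int = 64
    ny: int = 64
    spacing_mm: float = 0.4
    n_eam_points: int = 600
    background_voltage_mean_range: tuple[float, float] = (0.8, 1.1)
    n_patches_range: tuple[int, int] = (3, 5)
    patch_radius_range_mm: tuple[float, float] = (3.0, 5.0)
    patch_voltage_mean_range_mV: tuple[float, float] = (0.1, 0.3)
    fiber_twist_range_deg: tuple[float, float] = (30.0, 90.0)

    def __post_init__(self):
        if self.n_patients < 1:
            raise ModelError("n_patients must be >= 1")


@dataclasses.dataclass
class PatientBundle:
    """Generated inputs plus the built substrate of one virtual patient."""

    spec: PatientSpec
    mesh: SheetMesh
    cloud: VoltagePointCloud
    patch_centers_mm: np.ndarray
    lesion_rings: tuple
    lesion_holes: tuple
    substrate: SubstrateMap
    pace_xy_mm: tuple[float, float]

    @property
    def patient_id(self) -> str:
        return f"p{self.spec.seed:08d}"


def default_lesion_template(mesh: SheetMesh):
    """Vein-hole / PVI-ring analogue on a sheet: two 'vein' holes near the
    right edge, each encircled by a closed 2-mm-wide antral ablation ring."""
    lx, ly = mesh.extent_mm
    centers = [(0.82 * lx, 0.30 * ly), (0.82 * lx, 0.70 * ly)]
    holes = tuple((cx, cy, 0.8) for cx, cy in centers)
    rings = tuple((cx, cy, 2.0, 2.0) for cx, cy in centers)
    return rings, holes


def make_patient(spec: PatientSpec) -> PatientBundle:
    """Generate one virtual patient, deterministically from its spec.

    EAM points are sampled uniformly in-domain; their voltages are drawn
    from the background Gaussian (truncated at 0) and overridden inside
    low-voltage patches by the patch Gaussian.  Warns when patches cover
    the whole domain.
    """
    rng = np.random.default_rng(spec.seed)
    mesh = SheetMesh(spec.nx, spec.ny, spec.spacing_mm)
    lx, ly = mesh.extent_mm

    pts = rng.uniform([0, 0], [lx, ly], size=(spec.n_eam_points, 2))
    centers = rng.uniform([0, 0], [lx, ly], size=(spec.n_patches, 2))
    vals = rng.normal(spec.background_voltage_mean_mV,
                      spec.background_voltage_sd_mV, spec.n_eam_points)
    in_patch = np.zeros(spec.n_eam_points, dtype=bool)
    for cx, cy in centers:
        in_patch |= np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) <= spec.patch_radius_mm
    if spec.n_patches > 0:
        patch_vals = rng.normal(spec.patch_voltage_mean_mV,
                                spec.patch_voltage_sd_mV, spec.n_eam_points)
        vals = np.where(in_patch, patch_vals, vals)
    if in_patch.all():
        import warnings

        warnings.warn("low-voltage patches cover the entire domain")
    vals = np.clip(vals, 0.0, None)
    cloud = VoltagePointCloud(np.column_stack([pts, np.zeros(len(pts))]), vals)

    rings, holes = default_lesion_template(mesh)
    lesion = lesion_mask_rings(mesh, rings, holes)
    fiber_params = {"angle_deg": spec.fiber_angle_deg,
                    "twist_deg": spec.fiber_twist_deg}
    substrate = build_substrate(
        mesh, cloud, seed=spec.seed + 1, fiber_mode=spec.fiber_mode,
        fiber_params=fiber_params, lesion_mask=lesion)
    pace_xy = (spec.pace_frac_xy[0] * lx, spec.pace_frac_xy[1] * ly)
    return PatientBundle(spec=spec, mesh=mesh, cloud=cloud,
                         patch_centers_mm=centers, lesion_rings=rings,
                         lesion_holes=holes, substrate=substrate,
                         pace_xy_mm=pace_xy)


def make_cohort(spec: CohortSpec) -> tuple[list[PatientBundle], pd.DataFrame]:
    """Generate a cohort and its manifest table.

    Patient i's seed and parameters derive from ``(master_seed, i)``; two
    cohorts with the same master seed are identical.
    """
    bundles = []
    rows = []
    for i in range(spec.n_patients):
        ss = np.random.SeedSequence([spec.master_seed, i])
        rng = np.random.default_rng(ss)
        seed = int(ss.generate_state(1)[0] % (2 ** 31))
        ps = PatientSpec(
            seed=seed, nx=spec.nx, ny=spec.ny, spacing_mm=spec.spacing_mm,
            n_eam_points=spec.n_eam_points,
            background_voltage_mean_mV=float(
                rng.uniform(*spec.background_voltage_mean_range)),
            n_patches=int(rng.integers(spec.n_patches_range[0],
                                       spec.n_patches_range[1] + 1)),
            patch_radius_mm=float(rng.uniform(*spec.patch_radius_range_mm)),
            patch_voltage_mean_mV=float(
                rng.uniform(*spec.patch_voltage_mean_range_mV)),
            fiber_twist_deg=float(rng.uniform(*spec.fiber_twist_range_deg)),
        )
        bundle = make_patient(ps)
        bundles.append(bundle)
        row = {"index": i, "patient_id": bundle.patient_id}
        row.update(dataclasses.asdict(ps))
        row["fibrotic_fraction"] = bundle.substrate.fibrotic_fraction
        rows.append(row)
    return bundles, pd.DataFrame(rows)


@dataclasses.dataclass
class CalibratedPatient:
    """A patient whose diffusion scale sustains drug-free induced AF."""

    bundle: PatientBundle
    grid: TissueGrid
    diffusion_scale: float
    eas_node: int
    baseline_trace: object
    baseline_outcome: object
    calibrated: bool
    detail: str = ""


def tune_for_baseline_af(bundle: PatientBundle,
                         remodeling: ConductanceScaling | None = None,
                         observe_until_ms: float = 10_000.0,
                         beats_per_cl: int = 2,
                         target_cv_mps: float = 0.20,
                         scale_bracket: tuple[float, float] = (0.1, 2.0),
                         scale_multipliers: Sequence[float] = (1.0, 1.4, 0.7),
                         dt: float = 0.1,
                         record_dt_ms: float = 2.0,
                         stim_amplitude: float = 60.0,
                         site_radius_mm: float = 1.5) -> CalibratedPatient:
    """Calibrate a patient's diffusion scale for sustained drug-free AF.

    Two-stage, mirroring the study's baseline tailoring: a cheap
    conduction-velocity pre-calibration brings the scale to a wavelength
    plausible for the sheet size, then the sustained-AF target (induced
    AF/AT still active at the end of the observation window) is verified
    by actual induction runs, probing a short multiplier ladder around
    the pre-calibrated scale (too little coupling fails point-source
    propagation, too much makes the wavelength outgrow the sheet, so the
    search explores both directions).  Patients that cannot be calibrated
    within the bracket are returned with ``calibrated=False`` and the
    achieved behaviour in ``detail``.
    """
    if remodeling is None:
        remodeling = ConductanceScaling.af_remodeling()
    grid0 = build_grid(bundle.substrate)
    field = build_scaling_field(bundle.substrate, remodeling)

    # stage 1: CV pre-calibration on the patient's own (lesioned) sheet
    try:
        s_cv = calibrate_diffusion(grid0, target_cv_mps=target_cv_mps,
                                   bracket=scale_bracket, tol=0.15,
                                   scaling_field=field, dt=dt)
    except CalibrationError as exc:
        return CalibratedPatient(bundle, grid0, np.nan, -1, None, None,
                                 calibrated=False, detail=f"CV stage: {exc}")

    # EAS from one drug-free paced beat at the pre-calibrated scale
    grid_cv = grid0.with_scale(s_cv)
    sinus = grid_cv.disc_nodes(*bundle.pace_xy_mm, radius_mm=site_radius_mm)
    beat = run(grid_cv, field, [StimulusEvent(sinus, 2.0, 2.0, stim_amplitude)],
               t_end_ms=400.0, dt=dt, record_dt_ms=1e9, max_act=4)
    eas = find_eas(beat)

    # stage 2: sustained-AF verification with induction runs
    site = grid_cv.disc_nodes(*grid_cv.substrate.mesh.points[eas, :2],
                              radius_mm=site_radius_mm)
    protocol = PacingProtocol("ramp", site, beats_per_cl=beats_per_cl,
                              stim_amplitude=stim_amplitude)
    last = {}

    def sustained(g: TissueGrid) -> bool:
        trace = run_protocol(g, field, protocol, observe_until_ms,
                             dt=dt, record_dt_ms=record_dt_ms)
        outcome = classify_rhythm(trace, observe_until_ms)
        last["trace"], last["outcome"], last["scale"] = trace, outcome, g.diffusion_scale
        return not outcome.terminated

    tried = []
    for mult in scale_multipliers:
        s = float(np.clip(s_cv * mult, *scale_bracket))
        if any(abs(s - t) / s < 1e-9 for t, _ in tried):
            continue
        ok = sustained(grid0.with_scale(s))
        tried.append((s, ok))
        if ok:
            return CalibratedPatient(bundle, grid0.with_scale(s), s, eas,
                                     last["trace"], last["outcome"],
                                     calibrated=True,
                                     detail=f"cv_scale={s_cv:.4g}")
    return CalibratedPatient(bundle, grid_cv, s_cv, eas,
                             last.get("trace"), last.get("outcome"),
                             calibrated=False,
                             detail=f"no sustaining scale; tried {tried}")
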