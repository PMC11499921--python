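"""Run configuration: validated, hashable, round-trippable.

A :class:`RunConfig` collects every tunable of the pipeline in nested
sections (model, drug, substrate, solver, protocol, biomarkers, cohort).
Unknown keys are rejected; physical quantities carry their units in the
key names.  The configuration hash (sha256 of the canonical JSON dump)
is stamped into every output file so any table can be traced back to the
exact settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .myocyte import CHANNELS


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ModelSection(_Section):
    dt_cell_ms: float = Field(0.02, gt=0, le=0.1)
    ach_uM: float = Field(0.0, ge=0)
    n_prebeats: int = Field(20, ge=1)
    remodeling_profile: dict[str, float] = Field(
        default_factory=lambda: {"ICaL": 0.3, "Ito": 0.5, "IKur": 0.5, "IK1": 2.0})

    @field_validator("remodeling_profile")
    @classmethod
    def _known_channels(cls, v):
        for ch in v:
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r} in remodeling_profile")
        return v


class DrugChannelEntry(_Section):
    ic50_uM: float = Field(gt=0)
    hill_coefficient: float = Field(gt=0)
    source: str = ""


class DrugSection(_Section):
    name: str = "amiodarone"
    table: dict[str, DrugChannelEntry] = Field(default_factory=lambda: {
        "INa": DrugChannelEntry(ic50_uM=3.0, hill_coefficient=1.0),
        "ICaL": DrugChannelEntry(ic50_uM=5.8, hill_coefficient=1.0),
        "Ito": DrugChannelEntry(ic50_uM=20.0, hill_coefficient=1.0),
        "IKur": DrugChannelEntry(ic50_uM=20.0, hill_coefficient=1.0),
        "IKr": DrugChannelEntry(ic50_uM=1.0, hill_coefficient=1.0),
        "IKs": DrugChannelEntry(ic50_uM=20.0, hill_coefficient=1.0),
        "IK1": DrugChannelEntry(ic50_uM=40.0, hill_coefficient=1.0),
    })
    doses_uM: dict[str, float] = Field(default_factory=lambda: {
        "none": 0.0, "low": 1.6, "high": 3.9, "toxic": 8.0})

    @field_validator("table")
    @classmethod
    def _known_channels(cls, v):
        for ch in v:
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r} in drug table")
        return v

    @field_validator("doses_uM")
    @classmethod
    def _nonnegative(cls, v):
        for k, d in v.items():
            if d < 0:
                raise ValueError(f"dose {k!r} must be >= 0, got {d}")
        return v


class SubstrateSection(_Section):
    idw_radius_mm: float = Field(10.0, gt=0)
    idw_power: float = Field(2.0, gt=0)
    conductivity_Spm: dict[str, float] = Field(default_factory=lambda: {
        "nonfibrotic_longitudinal": 0.1264,
        "fibrotic_longitudinal": 0.0546,
        "nonfibrotic_transverse": 0.0252,
        "fibrotic_transverse": 0.0068,
    })


class SolverSection(_Section):
    dt_ms: float = Field(0.1, gt=0, le=0.1)
    record_dt_ms: float = Field(2.0, gt=0)
    sigma_to_d_mm2pms_per_Spm: float = Field(0.71429, gt=0)


class ProtocolSection(_Section):
    constant_cl_ms: float = Field(500.0, gt=0)
    ramp_beats_per_cl: int = Field(2, ge=1)
    observe_until_ms: float = Field(10_000.0, gt=0)
    stim_amplitude_pApF: float = Field(60.0, gt=0)
    site_radius_mm: float = Field(1.5, gt=0)
    target_cv_mps: float = Field(0.20, gt=0)
    scale_bracket: tuple[float, float] = (0.1, 2.0)


class BiomarkerSection(_Section):
    df_window_s: tuple[float, float] = (17.0, 23.0)
    df_band_hz: tuple[float, float] = (1.0, 20.0)
    smax_mode: str = "all"
    compute_biomarkers: bool = True

    @field_validator("smax_mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("all", "last3"):
            raise ValueError("smax_mode must be 'all' or 'last3'")
        return v


class CohortSection(_Section):
    n_patients: int = Field(10, ge=1)
    master_seed: int = 2024
    nx: int = Field(64, ge=8)
    ny: int = Field(64, ge=8)
    spacing_mm: float = Field(0.4, gt=0)
    n_eam_points: int = Field(600, ge=1)
    background_voltage_mean_range: tuple[float, float] = (0.8, 1.1)
    n_patches_range: tuple[int, int] = (3, 5)
    patch_radius_range_mm: tuple[float, float] = (3.0, 5.0)
    patch_voltage_mean_range_mV: tuple[float, float] = (0.1, 0.3)
    fiber_twist_range_deg: tuple[float, float] = (30.0, 90.0)


class RunConfig(_Section):
    model: ModelSection = Field(default_factory=ModelSection)
    drug: DrugSection = Field(default_factory=DrugSection)
    substrate: SubstrateSection = Field(default_factory=SubstrateSection)
    solver: SolverSection = Field(default_factory=SolverSection)
    protocol: ProtocolSection = Field(default_factory=ProtocolSection)
    biomarkers: BiomarkerSection = Field(default_factory=BiomarkerSection)
    cohort: CohortSection = Field(default_factory=CohortSection)

    def config_hash(self) -> str:
        dump = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(dump.encode()).hexdigest()[:16]

    def drug_spec(self):
        from .pharmacology import ChannelAffinity, DrugSpec

        return DrugSpec(self.drug.name, {
            ch: ChannelAffinity(e.ic50_uM, e.hill_coefficient, e.source)
            for ch, e in self.drug.table.items()})

    def remodeling_scaling(self):
        from .myocyte import ConductanceScaling

        return ConductanceScaling.af_remodeling(self.model.remodeling_profile)

    def cohort_spec(self):
        from .cohort import CohortSpec

        c = self.cohort
        return CohortSpec(
            n_patients=c.n_patients, master_seed=c.master_seed, nx=c.nx,
            ny=c.ny, spacing_mm=c.spacing_mm, n_eam_points=c.n_eam_points,
            background_voltage_mean_range=c.background_voltage_mean_range,
            n_patches_range=c.n_patches_range,
            patch_radius_range_mm=c.patch_radius_range_mm,
            patch_voltage_mean_range_mV=c.patch_voltage_mean_range_mV,
            fiber_twist_range_deg=c.fiber_twist_range_deg)


def load_config(path=None) -> RunConfig:
    """Load and validate a YAML config; an empty/missing body gives defaults.

    Validation errors name the offending key and constraint (pydantic).
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return RunConfig()
    return RunConfig.model_validate(data)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(mode="json"),
                                         sort_keys=True))
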