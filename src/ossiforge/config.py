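"""Simulation configuration.

All tunable model parameters live here, grouped by subsystem, with defaults
set to the published values for the mouse distal-metatarsal model.  Units:
lengths in μm, times in days, moduli in kPa, concentrations in pM/μm³.
Diffusion/degradation constants are specified per second (the literature
convention) and converted to per-day internally (86,400 s/day).

A config can be round-tripped through YAML with :func:`load_config` /
:func:`save_config`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = [
    "SECONDS_PER_DAY", "GridConfig", "SolverConfig", "ChemConfig",
    "CycleConfig", "SignalingParams", "FateThresholds", "PropertySchedule",
    "CapsuleSpec", "EventSchedule", "SimulationConfig",
    "load_config", "save_config",
]

SECONDS_PER_DAY = 86_400.0


@dataclass
class GridConfig:
    """Eulerian background grid (shared by mechanics and diffusion)."""
    h_um: float = 50.0            # grid spacing
    padding_cells: int = 3        # margin beyond the particle bounding box


@dataclass
class SolverConfig:
    """Quasi-static equilibrium solve per time increment."""
    tol_energy_rel: float = 1e-8  # relative energy-change tolerance
    tol_force: float = 1e-6       # force residual, units of E_cell·h²
    max_iter: int = 2000


@dataclass
class ChemConfig:
    """Reaction–diffusion of Ihh and PTHrP."""
    D_um2_per_s: float = 1.0      # shared diffusion coefficient
    k_per_s: float = 0.005        # shared first-order degradation rate
    scheme: str = "implicit"      # implicit (backward Euler) | explicit (FTCS)
    substeps: int = 4             # chemistry substeps per mechanics increment
    padding_cells: int = 3        # Dirichlet-0 padding beyond the tissue

    @property
    def D(self) -> float:
        """Diffusion coefficient in μm²/day."""
        return self.D_um2_per_s * SECONDS_PER_DAY

    @property
    def k(self) -> float:
        """Degradation rate in 1/day."""
        return self.k_per_s * SECONDS_PER_DAY


@dataclass
class CycleConfig:
    """Cell cycle and growth-stretch schedules."""
    T_cycle_days: float = 1.0
    R_prolif_per_day: float = 5.0      # rate parameter of the exponential G0
    prolif_volume_multiple: float = 2.0  # det F^g gain per proliferative cycle
    hyp_volume_multiple: float = 8.0     # det F^g gain over hypertrophy
    division_offset_factor: float = 0.5  # offset = factor*(V/2)^(1/3)


@dataclass
class SignalingParams:
    """Production schedules for Ihh and PTHrP."""
    P_ihh_max: float = 1.0        # pM/μm³·s
    P_pthrp_max: float = 1.0      # pM/μm³·s
    Ihh_max: float = 1.5e6        # pM, whole-tissue normalization constant
    T_prehyp_days: float = 0.5
    T_hyp_days: float = 1.0
    T_mat_days: float = 0.5       # SOC maturation time (swept 0.5–16)
    #: whether Ihh_max normalizes the whole-tissue or the octant total
    ihh_total_scope: str = "whole_tissue"   # whole_tissue | octant


@dataclass
class FateThresholds:
    """Ihh/PTHrP concentration thresholds for differentiation (pM/μm³)."""
    C_ihh_prolif: float = 1.0
    C_ihh_prehyp: float = 30.0
    C_pthrp_prehyp: float = 0.5
    C_ihh_bone_collar: float = 10.0


@dataclass
class PropertySchedule:
    """Material-property targets and transition durations."""
    E_cell_kPa: float = 1.0
    E_calcif_kPa: float = 1.0e3
    E_bone_collar_kPa: float = 1.0e2
    nu_cell: float = 0.4
    nu_calcif: float = 0.3
    nu_bone_collar: float = 0.3
    T_apop_days: float = 1.0
    T_calcif_days: float = 1.0
    #: apoptotic points stiffen toward the calcified-matrix modulus (they are
    #: part of the primary spongiosa); override to keep them soft
    E_apoptotic_target_kPa: float | None = None

    def apoptotic_target(self) -> float:
        return (self.E_calcif_kPa if self.E_apoptotic_target_kPa is None
                else self.E_apoptotic_target_kPa)


@dataclass
class CapsuleSpec:
    """One-eighth distal-metatarsal capsule geometry."""
    cylinder_radius_um: float = 300.0
    cylinder_height_um: float = 300.0
    dome_rise_um: float = 340.0       # apex height above the cylinder top
    dome_xy_semiaxis_um: float = 330.0
    dome_z_semiaxis_um: float = 250.0
    spacing_um: float = 10.0
    point_volume_um3: float = 1.0e3
    #: frozen surface density of boundary points (points/μm²); None means
    #: "reproduce the published count of the default octant surface"
    boundary_density_per_um2: float | None = None


@dataclass
class EventSchedule:
    """Developmental event times (days; Day 0 = primary-ossification onset)."""
    poc_day: float = 0.0
    soc_day: float = 2.0
    end_day: float = 5.4
    resting_pthrp_enabled: bool = True
    poc_slab_thickness_um: float = 60.0  # full (mirrored) slab thickness
    soc_seed_radius_um: float = 40.0


@dataclass
class SimulationConfig:
    dt_days: float = 0.02
    seed: int = 0
    grid: GridConfig = field(default_factory=GridConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    chem: ChemConfig = field(default_factory=ChemConfig)
    cycle: CycleConfig = field(default_factory=CycleConfig)
    signaling: SignalingParams = field(default_factory=SignalingParams)
    thresholds: FateThresholds = field(default_factory=FateThresholds)
    properties: PropertySchedule = field(default_factory=PropertySchedule)
    capsule: CapsuleSpec = field(default_factory=CapsuleSpec)
    events: EventSchedule = field(default_factory=EventSchedule)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def _to_dict(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    return obj


def _from_dict(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if f.default_factory is not dataclasses.MISSING:
            proto = f.default_factory()
            if dataclasses.is_dataclass(proto) and isinstance(value, dict):
                value = _from_dict(type(proto), value)
        kwargs[f.name] = value
    return cls(**kwargs)


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(config), fh, sort_keys=False)


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(SimulationConfig, data)
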