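"""Cell differentiation and material-property transitions.

Differentiation is driven by strict concentration thresholds:

    quiescent/resting  → proliferative     C_Ihh  > C_th(Ihh, prolif)
    proliferative      → prehypertrophic   C_Ihh  > C_th(Ihh, prehyp)
                                           and C_PTHrP < C_th(PTHrP, prehyp)
    prehypertrophic    → hypertrophic      t_H > T_prehyp
    hypertrophic       → apoptotic|matrix  t_H > T_prehyp + T_hyp  (½ / ½)
    perichondrial      → bone collar       C_Ihh  > C_th(Ihh, BC)

Apoptotic and matrix points are absorbing (no remodeling).  On terminal
transition the Young's modulus ramps log-linearly (three decades of
stiffness) and the Poisson ratio linearly from the chondrocyte values to the
calcified/bone-collar targets over T_apop/T_calcif; apoptotic points stiffen
to the calcified-matrix modulus because they are part of the primary
spongiosa.

Primary and secondary ossification are initiated by fiat: a slab of cells at
the diaphysis center (Day 0) and a spherical cluster in the epiphysis (SOC
day) are set prehypertrophic.  At SOC onset the quiescent band between the
proliferative zone and the SOC seed becomes the PTHrP-producing resting
zone.
"""

from __future__ import annotations

import warnings

import numpy as np

from .config import FateThresholds, PropertySchedule, SignalingParams
from .points import CellType, GrowthMode, ParticleState

__all__ = ["update_fate", "transition_properties", "apply_property_ramps",
           "initiate_poc", "initiate_soc", "define_resting_zone",
           "EmptyRestingZoneWarning"]


class EmptyRestingZoneWarning(UserWarning):
    pass


def _begin_transition(points, ids, E_target, nu_target):
    points.in_transition[ids] = True
    points.t_transition[ids] = 0.0
    points.E_start[ids] = points.E[ids]
    points.nu_start[ids] = points.nu[ids]
    points.E_target[ids] = E_target
    points.nu_target[ids] = nu_target


def update_fate(points: ParticleState, dt, thresholds: FateThresholds,
                sig: SignalingParams, schedule: PropertySchedule,
                rng: np.random.Generator,
                resting_may_proliferate: bool = True) -> None:
    """Apply one differentiation sweep using per-point sampled fields.

    ``points.C_ihh`` / ``points.C_pthrp`` must hold this step's local
    concentrations.  Maturation clocks t_H advance by ``dt`` first, then
    transitions fire on strict comparisons.
    """
    points.t_H[points.types(CellType.PREHYPERTROPHIC,
                            CellType.HYPERTROPHIC)] += dt
    points.t_transition[points.in_transition] += dt

    C_i, C_p = points.C_ihh, points.C_pthrp

    # quiescent (and optionally resting) → proliferative
    src = points.types(CellType.QUIESCENT)
    if resting_may_proliferate:
        src |= points.types(CellType.RESTING_PTHRP)
    to_prolif = src & (C_i > thresholds.C_ihh_prolif)
    points.cell_type[to_prolif] = CellType.PROLIFERATIVE

    # proliferative → prehypertrophic (PTHrP gate)
    to_prehyp = (points.types(CellType.PROLIFERATIVE)
                 & (C_i > thresholds.C_ihh_prehyp)
                 & (C_p < thresholds.C_pthrp_prehyp))
    if np.any(to_prehyp):
        points.cell_type[to_prehyp] = CellType.PREHYPERTROPHIC
        points.t_H[to_prehyp] = 0.0
        # freeze the columnar growth episode; an in-flight cycle continues
        # for division bookkeeping only, a cell resting in G0 never cycles
        points.Fg0[to_prehyp] = points.Fg[to_prehyp]
        points.theta[to_prehyp] = 1.0
        points.growth_mode[to_prehyp] = GrowthMode.NONE
        points.cycle_locked[to_prehyp & ~points.cycling] = True

    # prehypertrophic → hypertrophic
    to_hyp = (points.types(CellType.PREHYPERTROPHIC)
              & (points.t_H > sig.T_prehyp_days))
    if np.any(to_hyp):
        points.cell_type[to_hyp] = CellType.HYPERTROPHIC
        points.Fg0[to_hyp] = points.Fg[to_hyp]
        points.theta[to_hyp] = 1.0
        points.growth_mode[to_hyp] = GrowthMode.ISOTROPIC

    # hypertrophic → apoptotic | matrix, equal probability
    terminal = (points.types(CellType.HYPERTROPHIC)
                & (points.t_H > sig.T_prehyp_days + sig.T_hyp_days))
    ids = np.flatnonzero(terminal)
    if ids.size:
        to_matrix = rng.random(ids.size) < 0.5
        m_ids, a_ids = ids[to_matrix], ids[~to_matrix]
        points.cell_type[m_ids] = CellType.MATRIX
        points.cell_type[a_ids] = CellType.APOPTOTIC
        points.growth_mode[ids] = GrowthMode.NONE
        _begin_transition(points, m_ids, schedule.E_calcif_kPa,
                          schedule.nu_calcif)
        _begin_transition(points, a_ids, schedule.apoptotic_target(),
                          schedule.nu_calcif)

    # perichondrial types → bone collar
    to_bc = (points.types(CellType.PERICHONDRIUM,
                          CellType.PERIARTICULAR_PTHRP)
             & (C_i > thresholds.C_ihh_bone_collar))
    ids = np.flatnonzero(to_bc)
    if ids.size:
        points.cell_type[ids] = CellType.BONE_COLLAR
        _begin_transition(points, ids, schedule.E_bone_collar_kPa,
                          schedule.nu_bone_collar)

    apply_property_ramps(points, schedule)


def transition_properties(E_start, nu_start, E_target, nu_target, elapsed,
                          duration):
    """Interpolated (E, ν) during a property transition.

    E ramps log-linearly (geometric) across the stiffness decades, ν
    linearly; both land exactly on the targets at ``elapsed ≥ duration``.
    """
    elapsed = np.asarray(elapsed, dtype=float)
    if np.any(elapsed < 0):
        raise ValueError("elapsed time must be non-negative")
    f = np.clip(elapsed / duration, 0.0, 1.0)
    E = np.exp(np.log(E_start) * (1.0 - f) + np.log(E_target) * f)
    nu = nu_start * (1.0 - f) + nu_target * f
    return E, nu


def apply_property_ramps(points: ParticleState,
                         schedule: PropertySchedule) -> None:
    """Advance all in-progress (E, ν) transitions to their current clock."""
    mask = points.in_transition
    if not np.any(mask):
        return
    ids = np.flatnonzero(mask)
    dur = np.where(points.cell_type[ids] == CellType.APOPTOTIC,
                   schedule.T_apop_days, schedule.T_calcif_days)
    E, nu = transition_properties(points.E_start[ids], points.nu_start[ids],
                                  points.E_target[ids], points.nu_target[ids],
                                  points.t_transition[ids], dur)
    points.E[ids] = E
    points.nu[ids] = nu
    finished = points.t_transition[ids] >= dur
    points.in_transition[ids[finished]] = False


# ----------------------------------------------------------------------
# ossification-center initiation
# ----------------------------------------------------------------------
def initiate_poc(points: ParticleState, z_center=0.0, thickness=10.0):
    """Set the diaphyseal slab |z − z_center| ≤ thickness/2 prehypertrophic.

    Returns the ids converted (idempotent: already-prehypertrophic points are
    left untouched).  Raises if the slab contains no points.
    """
    slab = np.abs(points.x[:, 2] - z_center) <= thickness / 2.0 + 1e-9
    if not np.any(slab):
        raise ValueError("POC slab contains no material points")
    ids = np.flatnonzero(slab)
    fresh = slab & ~points.types(CellType.PREHYPERTROPHIC)
    points.cell_type[fresh] = CellType.PREHYPERTROPHIC
    points.t_H[fresh] = 0.0
    points.growth_mode[fresh] = GrowthMode.NONE
    return ids


def initiate_soc(points: ParticleState, center, radius):
    """Set the spherical epiphyseal cluster prehypertrophic (t_SOC = 0).

    Returns the seed ids.  Raises if the seed is empty.
    """
    if radius <= 0:
        raise ValueError("SOC seed radius must be positive")
    d = np.linalg.norm(points.x - np.asarray(center, dtype=float), axis=1)
    seed = d <= radius + 1e-9
    if not np.any(seed):
        raise ValueError("SOC seed contains no material points")
    fresh = seed & ~points.types(CellType.PREHYPERTROPHIC)
    points.cell_type[fresh] = CellType.PREHYPERTROPHIC
    points.t_H[fresh] = 0.0
    points.growth_mode[fresh] = GrowthMode.NONE
    return np.flatnonzero(seed)


def define_resting_zone(points: ParticleState, z_low, z_high,
                        radial_extent=None):
    """Tag quiescent points with z ∈ (z_low, z_high) as resting-zone PTHrP.

    ``z_low`` is the top of the proliferative zone, ``z_high`` the bottom of
    the SOC seed; ``radial_extent`` optionally restricts to the growth
    plate's radial footprint.  Returns the tagged ids; warns (and returns an
    empty array) if the band holds no quiescent cells.
    """
    band = (points.x[:, 2] > z_low) & (points.x[:, 2] < z_high)
    if radial_extent is not None:
        r = np.linalg.norm(points.x[:, :2], axis=1)
        band &= r <= radial_extent + 1e-9
    band &= points.types(CellType.QUIESCENT)
    ids = np.flatnonzero(band)
    if ids.size == 0:
        warnings.warn("resting zone is empty; simulation proceeds without "
                      "resting-zone PTHrP", EmptyRestingZoneWarning)
        return ids
    points.cell_type[ids] = CellType.RESTING_PTHRP
    return ids
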