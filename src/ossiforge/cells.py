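"""Cell cycle, growth stretch and division.

Each material point is one chondrocyte.  Proliferative cells run a cell
cycle of fixed length T_cycle (S → G2 → M → G1), divide exactly once at the
mid-cycle instant, then rest in G0 for an exponentially distributed duration
with rate R_prolif before the next cycle.  Growth happens in S, G2 and G1:
proliferative cells stretch unidirectionally along their division axis so
that the growth determinant gains a configurable multiple (default ×2 —
volume-neutral per generation after the 50/50 split) per cycle;
hypertrophic cells swell isotropically toward a configurable volume
multiple (default ×8) across the hypertrophic period.  The division axis
follows the local Ihh concentration gradient, which points up the columnar
axis of the growth plate.

Prehypertrophic cells that had already entered S phase when they
differentiated complete that one cycle (dividing once); cells that
differentiate in G0 never cycle again.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import CycleConfig, SignalingParams
from .points import CellType, GrowthMode, ParticleState

__all__ = ["DivisionEvent", "apply_growth_tensor", "sample_g0_duration",
           "division_direction", "split_points", "advance_cycles",
           "update_growth_tensors"]


@dataclass(frozen=True)
class DivisionEvent:
    """Record of one mitosis."""
    day: float
    parent: int
    child_a: int
    child_b: int
    axis: tuple
    offset_um: float


# ----------------------------------------------------------------------
def apply_growth_tensor(Fg0, theta, mode, n_s=None):
    """Growth tensor from the stretch θ and the episode-onset tensor Fᵍ₀.

    Isotropic:       Fᵍ = θ Fᵍ₀
    Unidirectional:  Fᵍ = (I + (θ−1) n_s ⊗ n_s) Fᵍ₀
    Works on stacked inputs; ``theta`` may be a scalar or (n,) array.
    """
    Fg0 = np.asarray(Fg0, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 1.0):
        raise ValueError("growth stretch θ must be ≥ 1")
    if mode == GrowthMode.ISOTROPIC:
        return theta[..., None, None] * Fg0
    if mode == GrowthMode.UNIDIRECTIONAL:
        if n_s is None:
            raise ValueError("unidirectional growth requires a division axis")
        n = np.asarray(n_s, dtype=float)
        if not np.allclose(np.linalg.norm(n, axis=-1), 1.0, atol=1e-8):
            raise ValueError("division axis must be unit length")
        outer = n[..., :, None] * n[..., None, :]
        A = np.eye(3) + (theta[..., None, None] - 1.0) * outer
        return A @ Fg0
    if mode == GrowthMode.NONE:
        return Fg0.copy()
    raise ValueError(f"unknown growth mode {mode!r}")


def sample_g0_duration(R_prolif, r):
    """Quiescence duration T_G0 = −log(1−r)/R from a uniform draw r∈[0,1)."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 1)):
        raise ValueError("uniform draw must lie in [0, 1)")
    if R_prolif <= 0:
        raise ValueError("R_prolif must be positive")
    return -np.log(1.0 - r) / R_prolif


def division_direction(field, x, axes=(0, 1, 2), prev_ns=None, rng=None,
                       eps=1e-12):
    """Division axes from the Ihh gradient, unit 3-vectors.

    ``field`` is a :class:`~ossiforge.signaling.ChemicalField` spanning the
    world coordinates listed in ``axes``; positions ``x`` are (P, 3).  Where
    the gradient magnitude falls below ``eps`` the cell's previous axis is
    reused, or a seeded random unit vector drawn.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    g_low = field.gradient(x[:, list(axes)], which="ihh")
    g = np.zeros((x.shape[0], 3))
    g[:, list(axes)] = g_low
    norm = np.linalg.norm(g, axis=1)
    ok = norm > eps
    n_s = np.zeros_like(g)
    n_s[ok] = g[ok] / norm[ok, None]
    for i in np.flatnonzero(~ok):
        if prev_ns is not None and np.linalg.norm(prev_ns[i]) > 0.5:
            n_s[i] = prev_ns[i] / np.linalg.norm(prev_ns[i])
        else:
            v = (rng.standard_normal(3) if rng is not None
                 else np.array([0.0, 0.0, 1.0]))
            n_s[i] = v / np.linalg.norm(v)
    return n_s


# ----------------------------------------------------------------------
def update_growth_tensors(points: ParticleState, cfg: CycleConfig,
                          sig: SignalingParams) -> None:
    """Advance θ per schedule and recompute Fᵍ for all growing points.

    Proliferative (and cycling prehypertrophic) cells: θ ramps linearly from
    1 to the unidirectional multiple over the cycle, frozen in G0/M.
    Hypertrophic cells: θ ramps from 1 to hyp_multiple^(1/3) across T_hyp.
    """
    uni = points.cycling & (points.growth_mode == GrowthMode.UNIDIRECTIONAL)
    if np.any(uni):
        mult = cfg.prolif_volume_multiple
        theta = 1.0 + (mult - 1.0) * np.clip(
            points.t_cycle[uni] / cfg.T_cycle_days, 0.0, 1.0)
        points.theta[uni] = theta
        points.Fg[uni] = apply_growth_tensor(
            points.Fg0[uni], theta, GrowthMode.UNIDIRECTIONAL,
            points.n_s[uni])
    iso = points.types(CellType.HYPERTROPHIC) & \
        (points.growth_mode == GrowthMode.ISOTROPIC)
    if np.any(iso):
        theta_end = cfg.hyp_volume_multiple ** (1.0 / 3.0)
        frac = np.clip((points.t_H[iso] - sig.T_prehyp_days)
                       / sig.T_hyp_days, 0.0, 1.0)
        theta = 1.0 + (theta_end - 1.0) * frac
        points.theta[iso] = theta
        points.Fg[iso] = apply_growth_tensor(points.Fg0[iso], theta,
                                             GrowthMode.ISOTROPIC)


def advance_cycles(points: ParticleState, dt, cfg: CycleConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Advance cycle clocks by ``dt`` days; return ids due to divide now.

    Crossing the mid-cycle instant emits the id exactly once.  At cycle end
    the growth episode is committed (Fᵍ₀ ← Fᵍ, θ ← 1) and the cell enters G0
    with a freshly sampled duration; prehypertrophic cells finishing an
    in-flight cycle are locked out of further cycling.  Quiescent-phase
    timers tick down and eligible cells re-enter S phase.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    eligible_new = points.types(CellType.PROLIFERATIVE) & ~points.cycle_locked

    # G0 countdown and cycle re-entry
    in_g0 = ~points.cycling & (points.T_G0_left > 0)
    points.T_G0_left[in_g0] -= dt
    reenter = eligible_new & ~points.cycling & (points.T_G0_left <= 0)
    if np.any(reenter):
        points.cycling[reenter] = True
        points.t_cycle[reenter] = 0.0
        points.divided_this_cycle[reenter] = False
        points.Fg0[reenter] = points.Fg[reenter]
        points.theta[reenter] = 1.0
        points.growth_mode[reenter] = GrowthMode.UNIDIRECTIONAL

    # advance in-flight cycles (proliferative or cycling prehypertrophic)
    active = points.cycling
    t_old = points.t_cycle[active]
    points.t_cycle[active] = t_old + dt

    half = 0.5 * cfg.T_cycle_days
    cross = active.copy()
    cross[active] = (t_old < half) & (points.t_cycle[active] >= half)
    divide_ids = np.flatnonzero(cross & ~points.divided_this_cycle)

    done = active.copy()
    done[active] = points.t_cycle[active] >= cfg.T_cycle_days
    if np.any(done):
        points.cycling[done] = False
        points.t_cycle[done] = 0.0
        points.Fg0[done] = points.Fg[done]
        points.theta[done] = 1.0
        points.growth_mode[done] = GrowthMode.NONE
        # completed in-flight cycle of a differentiated cell: never again
        prehyp_done = done & points.types(CellType.PREHYPERTROPHIC,
                                          CellType.HYPERTROPHIC)
        points.cycle_locked[prehyp_done] = True
        draws = rng.random(int(done.sum()))
        points.T_G0_left[done] = sample_g0_duration(cfg.R_prolif_per_day,
                                                    draws)
    return divide_ids


def split_points(points: ParticleState, parent_ids, n_s, day,
                 cfg: CycleConfig) -> list[DivisionEvent]:
    """Divide each parent into two half-volume children along ±n_s.

    The parent slot becomes child a (position − offset·n_s); child b is
    appended.  Children inherit F, Fᵍ, Fᵍ₀, cell type and the in-flight
    cycle state (G2 onward).  Total volume is conserved exactly.
    """
    parent_ids = np.asarray(parent_ids, dtype=int)
    if parent_ids.size == 0:
        return []
    n_s = np.atleast_2d(np.asarray(n_s, dtype=float))
    norms = np.linalg.norm(n_s, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("division axis not set")
    n_s = n_s / norms[:, None]

    half_V = points.V[parent_ids] / 2.0
    offset = cfg.division_offset_factor * half_V ** (1.0 / 3.0)

    clone = ParticleState(points.x[parent_ids], half_V)
    for name in ("F", "Fg", "Fg0", "n_s"):
        setattr(clone, name, getattr(points, name)[parent_ids].copy())
    for name in (ParticleState._SCALARS + ParticleState._INTS
                 + ParticleState._BOOLS):
        setattr(clone, name, getattr(points, name)[parent_ids].copy())
    clone.V = half_V.copy()
    clone.x = points.x[parent_ids] + offset[:, None] * n_s
    clone.divided_this_cycle[:] = True

    points.V[parent_ids] = half_V
    points.x[parent_ids] -= offset[:, None] * n_s
    points.divided_this_cycle[parent_ids] = True
    points.n_s[parent_ids] = n_s
    points.has_ns[parent_ids] = True

    child_ids = points.append(clone)
    return [DivisionEvent(day, int(p), int(p), int(c),
                          tuple(np.round(ax, 6)), float(off))
            for p, c, ax, off in zip(parent_ids, child_ids, n_s, offset)]
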