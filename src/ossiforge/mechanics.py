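"""Quasi-static growth mechanics.

The tissue is a compressible neo-Hookean solid whose deformation gradient
carries a multiplicative elastic/growth split F = Fᵉ Fᵍ.  Per time increment
the committed growth tensors are equilibrated by minimizing total elastic
energy over the background-grid node displacements (the biology operates far
below inertial time scales, so a damped quasi-static solve replaces any
dynamic update).  Energy density, per reference volume:

    ψ = Jᵍ ( λ/8 · ln²I₃ + μ/2 · (I₁ − 3 − ln I₃) ),

with Jᵍ = det Fᵍ, Cᵉ = FᵉᵀFᵉ, I₁ = tr Cᵉ, I₃ = det Cᵉ.  ψ vanishes with
zero gradient exactly at Cᵉ = I, so spatially uniform growth relaxes to a
stress-free state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .config import SolverConfig
from .grid import BackgroundGrid
from .points import ParticleState

__all__ = ["LameParameters", "lame_from_moduli", "strain_energy_density",
           "first_pk_stress", "solve_equilibrium", "update_points",
           "EquilibriumResult"]


@dataclass(frozen=True)
class LameParameters:
    """Lamé constants (kPa)."""
    lam: float
    mu: float


def lame_from_moduli(E, nu):
    """Convert Young's modulus / Poisson ratio to Lamé constants.

    λ = Eν/((1+ν)(1−2ν)), μ = E/(2(1+ν)).  Accepts scalars or arrays.
    """
    E = np.asarray(E, dtype=float)
    nu = np.asarray(nu, dtype=float)
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    return lam, mu


def _invariants(F, Fg):
    """Elastic invariants (I₁, I₃) and Jᵍ for stacked 3×3 tensors."""
    Fg_inv = np.linalg.inv(Fg)
    Fe = F @ Fg_inv
    Ce = np.swapaxes(Fe, -1, -2) @ Fe
    I1 = np.trace(Ce, axis1=-2, axis2=-1)
    I3 = np.linalg.det(Ce)
    Jg = np.linalg.det(Fg)
    return I1, I3, Jg, Fg_inv


def strain_energy_density(F, Fg, lame):
    """Neo-Hookean energy density ψ (kPa) under the growth split.

    Parameters may be single 3×3 tensors or stacks (..., 3, 3); ``lame`` is a
    :class:`LameParameters` or a (λ, μ) pair of scalars/arrays.
    """
    F = np.asarray(F, dtype=float)
    Fg = np.asarray(Fg, dtype=float)
    if np.any(np.linalg.det(F) <= 0) or np.any(np.linalg.det(Fg) <= 0):
        raise ValueError("deformation/growth tensor with non-positive determinant")
    lam, mu = (lame.lam, lame.mu) if isinstance(lame, LameParameters) else lame
    I1, I3, Jg, _ = _invariants(F, Fg)
    lnI3 = np.log(I3)
    return Jg * (lam / 8.0 * lnI3 ** 2 + mu / 2.0 * (I1 - 3.0 - lnI3))


def first_pk_stress(F, Fg, lam, mu):
    """First Piola–Kirchhoff stress P = ∂ψ/∂F for stacked tensors.

    P = Jᵍ [ (λ/2) ln I₃ · F⁻ᵀ + μ (F Fᵍ⁻¹ Fᵍ⁻ᵀ − F⁻ᵀ) ].
    """
    F = np.asarray(F, dtype=float)
    Fg = np.asarray(Fg, dtype=float)
    _, I3, Jg, Fg_inv = _invariants(F, Fg)
    F_invT = np.swapaxes(np.linalg.inv(F), -1, -2)
    GGt = Fg_inv @ np.swapaxes(Fg_inv, -1, -2)
    lnI3 = np.log(I3)
    lam = np.asarray(lam, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return (Jg[..., None, None]
            * (0.5 * (lam * lnI3)[..., None, None] * F_invT
               + mu[..., None, None] * (F @ GGt - F_invT)))


@dataclass
class EquilibriumResult:
    energy: float
    grad_norm: float
    n_iter: int
    converged: bool


class SolverError(RuntimeError):
    """Equilibrium minimization failed to converge."""


def solve_equilibrium(points: ParticleState, grid: BackgroundGrid,
                      solver: SolverConfig | None = None) -> EquilibriumResult:
    """Minimize total elastic energy over grid node displacements.

    The trial deformation of point p under grid displacement field u is
    F_trial = (I + ∇u(x_p)) F_p; the objective is Σ_p ψ(F_trial, Fᵍ_p) V_p,ref
    subject to zero normal displacement on tagged slip planes.  On return
    ``grid.u`` holds the minimizer.
    """
    solver = solver or SolverConfig()
    nodes, _, grads = grid.stencil(points.x)   # geometry frozen during solve
    F0 = points.F
    Fg = points.Fg
    V_ref = points.V_ref
    lam, mu = lame_from_moduli(points.E, points.nu)
    free = ~grid.fixed.ravel()
    n_dof = int(free.sum())
    if n_dof == 0 or points.n == 0:
        return EquilibriumResult(0.0, 0.0, 0, True)

    eye = np.eye(3)

    def unpack(q):
        u = np.zeros(grid.n_nodes * 3)
        u[free] = q
        return u.reshape(grid.n_nodes, 3)

    def energy_grad(q):
        u = unpack(q)
        grad_u = np.einsum("pki,pkj->pij", u[nodes], grads)
        F_trial = (eye + grad_u) @ F0
        detF = np.linalg.det(F_trial)
        if np.any(detF <= 0):
            # inverted trial state: return a large penalized energy with the
            # previous descent direction left to the optimizer's line search
            return 1e30, np.zeros_like(q)
        psi = strain_energy_density(F_trial, Fg, (lam, mu))
        P = first_pk_stress(F_trial, Fg, lam, mu)
        # dE/du_g = Σ_p V_ref (P F₀ᵀ) ∇N_g(x_p)
        PFt = P @ np.swapaxes(F0, -1, -2)
        contrib = np.einsum("p,pij,pkj->pki", V_ref, PFt, grads)
        g = np.zeros((grid.n_nodes, 3))
        np.add.at(g, nodes.ravel(), contrib.reshape(-1, 3))
        return float(np.sum(psi * V_ref)), g.ravel()[free]

    E_scale = float(np.max(points.E))
    gtol = solver.tol_force * E_scale * grid.h ** 2
    x0 = grid.u.ravel()[free]
    res = minimize(energy_grad, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": solver.max_iter, "gtol": gtol,
                            "ftol": solver.tol_energy_rel})
    grid.u = unpack(res.x)
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    converged = bool(res.success) or grad_norm <= 10 * gtol
    if not converged:
        raise SolverError(
            f"equilibrium solve did not converge: {res.message} "
            f"(|g|max={grad_norm:.3e}, tol={gtol:.3e}, iters={res.nit})")
    return EquilibriumResult(float(res.fun), grad_norm, int(res.nit), True)


def update_points(points: ParticleState, grid: BackgroundGrid) -> None:
    """Advect points through the solved displacement field.

    x ← x + u(x);  F ← (I + ∇u) F;  V ← V · det(I + ∇u).  Raises on point
    inversion (det F ≤ 0 after the update).
    """
    nodes, weights, grads = grid.stencil(points.x)
    u = np.einsum("pk,pki->pi", weights, grid.u[nodes])
    grad_u = np.einsum("pki,pkj->pij", grid.u[nodes], grads)
    J_inc = np.linalg.det(np.eye(3) + grad_u)
    if np.any(J_inc <= 0):
        raise ValueError("point inversion during update (det(I+∇u) ≤ 0)")
    points.x = points.x + u
    points.F = (np.eye(3) + grad_u) @ points.F
    points.V = points.V * J_inc
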