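"""Ihh / PTHrP production and reaction–diffusion transport.

Two diffusible factors couple cell behavior across the tissue.  Indian
hedgehog (Ihh) is secreted by prehypertrophic and early hypertrophic
chondrocytes on a hat-shaped schedule over a cell's maturation clock t_H;
parathyroid hormone-related protein (PTHrP) is produced by periarticular
cells in proportion to the instantaneous whole-tissue Ihh content, and — once
the secondary ossification center (SOC) exists — by resting-zone cells with
an additional linear maturation ramp t_SOC/T_mat that saturates at the
periarticular level.

Both factors obey ∂C/∂t = D∇²C + P − kC with shared D and k, zero-flux
(mirror) conditions on the model's symmetry planes and C = 0 far from the
tissue.  The default integrator is an unconditionally stable backward-Euler
solve of the discrete screened diffusion operator (the explicit FTCS scheme
is retained for cross-checks); the degradation time 1/k ≈ 200 s is far below
the 0.02-day mechanics increment, so fields are quasi-steady per step.

Concentrations are in the source literature's unit pM/μm³, production in
pM/μm³·s; these units are carried opaquely and only ratios matter.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .config import SECONDS_PER_DAY, SignalingParams
from .grid import bspline_grad_1d, bspline_weight_1d

__all__ = ["ihh_production", "pthrp_production_periarticular",
           "pthrp_production_resting", "ChemicalField"]


# ----------------------------------------------------------------------
# production schedules
# ----------------------------------------------------------------------
def ihh_production(t_H, params: SignalingParams):
    """Ihh production (pM/μm³·s) of a maturing (pre)hypertrophic cell.

    Linear rise 0 → P_max over the prehypertrophic period, linear fall back
    to 0 over the first half of hypertrophy, 0 afterward.  Vectorized over
    ``t_H`` (days since prehypertrophic differentiation).
    """
    t = np.asarray(t_H, dtype=float)
    Tp, Th = params.T_prehyp_days, params.T_hyp_days
    up = np.clip(t / Tp, 0.0, 1.0)
    down = np.clip((t - Tp) / (0.5 * Th), 0.0, 1.0)
    return params.P_ihh_max * (up - down)


def pthrp_production_periarticular(ihh_total, params: SignalingParams):
    """Periarticular PTHrP production, proportional to total tissue Ihh."""
    return params.P_pthrp_max * np.asarray(ihh_total, dtype=float) / params.Ihh_max


def pthrp_production_resting(ihh_total, t_soc, params: SignalingParams):
    """Resting-zone PTHrP production with the SOC maturation ramp.

    Rises as (t_SOC/T_mat) × the periarticular level and saturates exactly at
    the periarticular level once t_SOC ≥ T_mat.  Raises if called before SOC
    onset (t_soc < 0).
    """
    t = np.asarray(t_soc, dtype=float)
    if np.any(t < 0):
        raise ValueError("resting-zone production queried before SOC onset")
    ramp = np.clip(t / params.T_mat_days, 0.0, 1.0)
    return pthrp_production_periarticular(ihh_total, params) * ramp


# ----------------------------------------------------------------------
# grid transport
# ----------------------------------------------------------------------
class ChemicalField:
    """Ihh and PTHrP concentrations on a regular node lattice.

    Works in any spatial dimension d (the growth-plate column driver uses
    d = 1, the capsule model d = 3).  Nodes sit at ``(origin_index + i) * h``
    per axis.  The low side of each axis is either a symmetry plane
    (zero-flux, mirror stencil) or an open far-field boundary; the high side
    and non-symmetric low sides hold the Dirichlet condition C = 0 just
    outside the lattice.

    Parameters
    ----------
    origin_index, shape : lattice description (d ints each)
    h : node spacing, μm
    D_per_day, k_per_day : transport constants, μm²/day and 1/day
    symmetry_axes : d bools — zero-flux at world coordinate 0 of that axis
    cross_section_um2 : tissue cross-section represented by each node in
        reduced dimensions (node volume = h^d × cross_section); 1.0 in 3-D.
    """

    def __init__(self, origin_index, shape, h, D_per_day, k_per_day,
                 symmetry_axes=None, cross_section_um2=1.0):
        self.origin_index = np.asarray(origin_index, dtype=int)
        self.shape = tuple(int(s) for s in shape)
        self.d = len(self.shape)
        self.h = float(h)
        self.D = float(D_per_day)
        self.k = float(k_per_day)
        self.symmetry_axes = (tuple(symmetry_axes) if symmetry_axes is not None
                              else (True,) * self.d)
        self.cross_section = float(cross_section_um2)
        self.n_nodes = int(np.prod(self.shape))
        self.C_ihh = np.zeros(self.n_nodes)
        self.C_pthrp = np.zeros(self.n_nodes)
        self._laplacian = self._build_laplacian()
        self._lu_cache = {}

    # -- discrete operator ---------------------------------------------
    def _build_laplacian(self) -> sp.csr_matrix:
        n = self.n_nodes
        shape = np.array(self.shape)
        idx = np.arange(n)
        coords = np.stack(np.unravel_index(idx, self.shape), axis=1)
        rows, cols, vals = [], [], []
        inv_h2 = 1.0 / self.h ** 2
        strides = np.array(
            [int(np.prod(self.shape[a + 1:])) for a in range(self.d)])
        for a in range(self.d):
            c = coords[:, a]
            diag = np.full(n, -2.0 * inv_h2)
            rows.append(idx); cols.append(idx); vals.append(diag)
            up = c + 1 < shape[a]
            rows.append(idx[up]); cols.append(idx[up] + strides[a])
            vals.append(np.full(up.sum(), inv_h2))
            low = c - 1 >= 0
            rows.append(idx[low]); cols.append(idx[low] - strides[a])
            vals.append(np.full(low.sum(), inv_h2))
            if self.symmetry_axes[a]:
                # node on the symmetry plane: mirror ghost C_{-1} = C_{+1}
                on_plane = (c == 0) & (coords[:, a] + self.origin_index[a] == 0)
                sel = on_plane & up
                rows.append(idx[sel]); cols.append(idx[sel] + strides[a])
                vals.append(np.full(sel.sum(), inv_h2))
        L = sp.coo_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(n, n))
        return L.tocsr()

    @property
    def node_volume(self) -> float:
        """Tissue volume represented by one node (μm³)."""
        return self.h ** self.d * self.cross_section

    @property
    def node_coords(self):
        coords = np.stack(np.unravel_index(np.arange(self.n_nodes),
                                           self.shape), axis=1)
        return (coords + self.origin_index) * self.h

    # -- point/field exchange ------------------------------------------
    def _stencil(self, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        xi = x / self.h - self.origin_index
        base = np.floor(xi - 0.5).astype(int)
        offs = np.arange(3)
        node_ax = base[:, None, :] + offs[None, :, None]   # (P, 3, d)
        node_ax = np.clip(node_ax, 0, np.array(self.shape) - 1)
        r = xi[:, None, :] - node_ax
        w1 = bspline_weight_1d(r)                          # (P, 3, d)
        # tensor-product combination over d axes
        weights = w1[:, :, 0]
        nodes = node_ax[:, :, 0]
        strides = [int(np.prod(self.shape[a + 1:])) for a in range(self.d)]
        nodes = nodes * strides[0]
        for a in range(1, self.d):
            weights = (weights[:, :, None] * w1[:, None, :, a]).reshape(
                weights.shape[0], -1)
            nodes = (nodes[:, :, None]
                     + node_ax[:, None, :, a] * strides[a]).reshape(
                nodes.shape[0], -1)
        # renormalize: clipping at the lattice edge breaks partition of unity
        weights = weights / weights.sum(axis=1, keepdims=True)
        return nodes, weights

    def deposit(self, x, production):
        """Spread per-point production (pM/μm³·s × V_p) onto node sources.

        ``production`` is the per-point volumetric rate times point volume
        (pM·/s); the result is a per-node source density in pM/μm³·s.
        """
        nodes, weights = self._stencil(x)
        src = np.zeros(self.n_nodes)
        np.add.at(src, nodes.ravel(),
                  (weights * np.asarray(production)[:, None]).ravel())
        return src / self.node_volume

    def sample(self, x, which="ihh"):
        """Interpolate a concentration field at point positions."""
        nodes, weights = self._stencil(x)
        C = self.C_ihh if which == "ihh" else self.C_pthrp
        return np.einsum("pk,pk->p", weights, C[nodes])

    def gradient(self, x, which="ihh"):
        """∇C at point positions, shape (P, d), units pM/μm³ per μm."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        xi = x / self.h - self.origin_index
        base = np.floor(xi - 0.5).astype(int)
        offs = np.arange(3)
        node_ax = base[:, None, :] + offs[None, :, None]
        node_ax = np.clip(node_ax, 0, np.array(self.shape) - 1)
        r = xi[:, None, :] - node_ax
        w1 = bspline_weight_1d(r)
        g1 = bspline_grad_1d(r) / self.h
        strides = [int(np.prod(self.shape[a + 1:])) for a in range(self.d)]
        C = (self.C_ihh if which == "ihh" else self.C_pthrp)
        # accumulate tensor products axis by axis for each gradient component
        P = x.shape[0]
        grad = np.zeros((P, self.d))
        for comp in range(self.d):
            w = np.ones((P, 1))
            nodes = np.zeros((P, 1), dtype=int)
            for a in range(self.d):
                fa = g1[:, :, a] if a == comp else w1[:, :, a]
                w = (w[:, :, None] * fa[:, None, :]).reshape(P, -1)
                nodes = (nodes[:, :, None]
                         + node_ax[:, None, :, a] * strides[a]).reshape(P, -1)
            grad[:, comp] = np.einsum("pk,pk->p", w, C[nodes])
        return grad

    # -- integrators ----------------------------------------------------
    def total(self, which="ihh", mask=None, multiplicity=1) -> float:
        """Total amount (pM) of a factor over ``mask`` nodes × multiplicity."""
        C = self.C_ihh if which == "ihh" else self.C_pthrp
        if mask is not None:
            C = C[mask]
        return float(C.sum() * self.node_volume * multiplicity)

    def step(self, dt_days, src_ihh=None, src_pthrp=None, scheme="implicit"):
        """Advance both fields by ``dt_days``.

        Sources are per-node production densities in pM/μm³·s (converted to
        per-day internally).  Backward Euler solves
        (1 + kΔt)C' − ΔtD L C' = C + ΔtP and is unconditionally stable and
        positivity-preserving; FTCS enforces its Δt ≤ h²/(2dD) bound.
        """
        dt = float(dt_days)
        zero = np.zeros(self.n_nodes)
        srcs = [zero if src_ihh is None else src_ihh * SECONDS_PER_DAY,
                zero if src_pthrp is None else src_pthrp * SECONDS_PER_DAY]
        fields = [self.C_ihh, self.C_pthrp]
        if scheme == "implicit":
            key = round(dt, 15)
            if key not in self._lu_cache:
                A = ((1.0 + self.k * dt) * sp.identity(self.n_nodes)
                     - dt * self.D * self._laplacian)
                self._lu_cache[key] = splu(A.tocsc())
            lu = self._lu_cache[key]
            out = [lu.solve(C + dt * P) for C, P in zip(fields, srcs)]
        elif scheme == "explicit":
            bound = self.h ** 2 / (2.0 * self.d * self.D)
            if dt > bound:
                raise ValueError(
                    f"explicit step {dt} exceeds stability bound {bound}")
            out = [C + dt * (self.D * (self._laplacian @ C) + P - self.k * C)
                   for C, P in zip(fields, srcs)]
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        for C in out:
            if np.any(C < -1e-9):
                raise RuntimeError("negative concentration produced")
        self.C_ihh = np.maximum(out[0], 0.0)
        self.C_pthrp = np.maximum(out[1], 0.0)
        return self
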