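"""Eulerian background grid and quadratic B-spline interpolation.

The hybrid particle/grid discretization stores the tissue state on Lagrangian
material points and solves for displacement increments on a regular Eulerian
node lattice.  Quadratic B-splines give C¹-continuous weights with a 3-node
support per dimension (27 nodes in 3-D); the grid is always rebuilt with
enough padding that every particle sees a complete spline stencil, which is
the boundary-extension policy used here (interior basis everywhere, domain
enlarged instead of edge-modified splines).

Nodes lie at integer multiples of the spacing ``h`` in world coordinates, so
the symmetry planes x=0, y=0, z=0 contain grid nodes and slip conditions are
plain per-axis DOF constraints.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BackgroundGrid", "bspline_weight_1d", "bspline_grad_1d"]


def bspline_weight_1d(r):
    """Quadratic B-spline value at signed node offset ``r`` (units of h).

    Piecewise: 3/4 − r² for |r| < 1/2, (3/2 − |r|)²/2 for 1/2 ≤ |r| < 3/2,
    0 beyond.  Partition of unity and linear reproduction hold wherever the
    3-node stencil is complete.
    """
    r = np.abs(np.asarray(r, dtype=float))
    w = np.zeros_like(r)
    inner = r < 0.5
    outer = (r >= 0.5) & (r < 1.5)
    w[inner] = 0.75 - r[inner] ** 2
    w[outer] = 0.5 * (1.5 - r[outer]) ** 2
    return w


def bspline_grad_1d(r):
    """d/dr of the quadratic B-spline (per unit of h)."""
    r = np.asarray(r, dtype=float)
    a = np.abs(r)
    g = np.zeros_like(r)
    inner = a < 0.5
    outer = (a >= 0.5) & (a < 1.5)
    g[inner] = -2.0 * r[inner]
    g[outer] = (a[outer] - 1.5) * np.sign(r[outer])
    return g


class DomainError(ValueError):
    """A query position lies outside the grid's complete-stencil interior."""


class BackgroundGrid:
    """Regular node lattice with per-node displacements and BC tags.

    Parameters
    ----------
    origin_index : (3,) int array
        World index of the first node (node coords = index * h).
    shape : (3,) int tuple
        Number of nodes per axis.
    h : float
        Grid spacing (μm).
    slip_planes : 3-tuple of bool
        Whether the world planes x=0 / y=0 / z=0 carry slip (zero normal
        displacement) conditions.
    """

    def __init__(self, origin_index, shape, h, slip_planes=(True, True, True)):
        self.origin_index = np.asarray(origin_index, dtype=int)
        self.shape = tuple(int(s) for s in shape)
        self.h = float(h)
        self.slip_planes = tuple(slip_planes)
        self.n_nodes = int(np.prod(self.shape))
        self.u = np.zeros((self.n_nodes, 3))
        self.fixed = np.zeros((self.n_nodes, 3), dtype=bool)
        self._tag_slip()

    # ------------------------------------------------------------------
    @classmethod
    def covering(cls, positions, h, padding_cells=3,
                 slip_planes=(True, True, True)):
        """Build a grid covering ``positions`` plus spline support margin."""
        positions = np.atleast_2d(positions)
        lo = np.floor(positions.min(axis=0) / h).astype(int) - padding_cells
        hi = np.ceil(positions.max(axis=0) / h).astype(int) + padding_cells
        for ax, slip in enumerate(slip_planes):
            if slip:
                lo[ax] = min(lo[ax], -padding_cells)
        return cls(lo, tuple(hi - lo + 1), h, slip_planes)

    def _tag_slip(self):
        idx = np.stack(np.unravel_index(np.arange(self.n_nodes), self.shape),
                       axis=1) + self.origin_index
        for ax, slip in enumerate(self.slip_planes):
            if slip:
                self.fixed[idx[:, ax] == 0, ax] = True

    # ------------------------------------------------------------------
    @property
    def node_coords(self):
        """(n_nodes, 3) node positions in μm."""
        idx = np.stack(np.unravel_index(np.arange(self.n_nodes), self.shape),
                       axis=1) + self.origin_index
        return idx * self.h

    def stencil(self, x):
        """B-spline stencil for query positions.

        Returns ``(nodes, weights, grads)`` with shapes (P, 27), (P, 27) and
        (P, 27, 3); ``grads`` are spatial gradients (1/μm).  Raises
        :class:`DomainError` if any stencil node falls outside the grid.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        xi = x / self.h - self.origin_index        # local node units
        base = np.floor(xi - 0.5).astype(int)      # (P, 3)
        offs = np.arange(3)
        node_ax = base[:, None, :] + offs[None, :, None]        # (P, 3off, 3ax)
        if np.any(node_ax < 0) or np.any(
                node_ax >= np.array(self.shape)[None, None, :]):
            raise DomainError("query position outside grid interior")
        r = xi[:, None, :] - node_ax                             # signed offset
        w1 = bspline_weight_1d(r)                                # (P, 3, 3)
        g1 = bspline_grad_1d(r) / self.h
        ii, jj, kk = np.meshgrid(offs, offs, offs, indexing="ij")
        ii, jj, kk = ii.ravel(), jj.ravel(), kk.ravel()          # (27,)
        wx, wy, wz = w1[:, ii, 0], w1[:, jj, 1], w1[:, kk, 2]
        weights = wx * wy * wz                                   # (P, 27)
        grads = np.empty(weights.shape + (3,))
        grads[..., 0] = g1[:, ii, 0] * wy * wz
        grads[..., 1] = wx * g1[:, jj, 1] * wz
        grads[..., 2] = wx * wy * g1[:, kk, 2]
        nx, ny, nz = self.shape
        nodes = ((node_ax[:, ii, 0] * ny) + node_ax[:, jj, 1]) * nz \
            + node_ax[:, kk, 2]
        return nodes, weights, grads

    # ------------------------------------------------------------------
    def interpolate_displacement(self, x):
        """u(x) = Σ_g u_g N_g(x) for one or more positions (μm)."""
        nodes, weights, _ = self.stencil(x)
        return np.einsum("pk,pki->pi", weights, self.u[nodes])

    def displacement_gradient(self, x):
        """∇u(x) = Σ_g u_g ⊗ ∇N_g(x); shape (P, 3, 3)."""
        nodes, _, grads = self.stencil(x)
        return np.einsum("pki,pkj->pij", self.u[nodes], grads)
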